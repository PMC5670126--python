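"""Synthetic study generator with known ground truth.

Produces a complete, parseable input bundle for the pipeline — per-dataset
protein and CDS FASTA, top-hit annotation tables, all-vs-all similarity
tables for unannotated proteins, exon counts for genome-backed datasets, a
small is_a ontology, Pfam domain tables and QC hit tables — together with the
generating truth (family memberships, presence patterns, contaminant labels),
so that every downstream step can be scored against a known answer.

The generative model is deliberately the simplest one producing realistic
presence patterns: families originate at tree nodes (a fixed count at the
root plus Poisson-distributed gains per branch) and are lost independently
per family per branch with a fixed probability; a family's presence set is
the leaves where it survives. Protein sequences are random amino-acid strings
sharing a family core (so identity-based redundancy removal has meaningful
input) and are not intended to model sequence evolution.

Defaults mirror the data profile of a multi-clade transcriptome/genome study:
seven lineages (six ingroup clades A-F plus outgroup P) with 3/7/7/2/1/2/2
datasets each, ~40% of families matched in the reference database, a small
KO-bearing fraction, and a minority of single-lineage bacterial contaminants.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .classify import DEFAULT_TOPOLOGY, Cladogram, parse_cladogram
from .types import ProteinRecord

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# synonymous codons per amino acid (standard code), for biased back-translation
_SYNONYMOUS: Dict[str, List[str]] = {}
from Bio.Data.CodonTable import standard_dna_table as _SDT  # noqa: E402

for _codon, _aa in _SDT.forward_table.items():
    _SYNONYMOUS.setdefault(_aa, []).append(_codon)
for _aa in _SYNONYMOUS:
    _SYNONYMOUS[_aa].sort()

DEFAULT_DATASETS_PER_LINEAGE = {"A": 3, "B": 7, "C": 7, "D": 2, "E": 1, "F": 2, "P": 2}
DEFAULT_GENOME_BACKED = ("A1", "B1", "F1")


@dataclass
class SimulationParams:
    """Study conditions for the synthetic generator.

    Rates are per branch; probabilities are per family (annotation) or per
    CDS (multi-exon). ``dropout`` is the per-dataset probability that a family
    present in the dataset's lineage is nevertheless not observed there
    (0 = noise-free). ``noise_edge_rate`` adds spurious between-family
    similarity edges with E-values above the clustering cutoff.
    """

    tree: str = DEFAULT_TOPOLOGY
    n_root_families: int = 200
    gain_rate: float = 25.0
    loss_prob: float = 0.2
    datasets_per_lineage: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DATASETS_PER_LINEAGE)
    )
    p_annotated: float = 0.4
    p_ko: float = 0.12
    n_contaminants: int = 20
    p_multiexon: float = 0.8
    seed: int = 0
    dropout: float = 0.0
    p_redundant: float = 0.1
    p_full_length: float = 0.9
    p_pfam: float = 0.5
    noise_edge_rate: float = 0.0
    genome_backed_datasets: Tuple[str, ...] = DEFAULT_GENOME_BACKED
    contaminant_lineages: int = 1
    contaminant_multiexon: bool = False
    core_set_size: int = 458

    def __post_init__(self) -> None:
        for name in ("loss_prob", "p_annotated", "p_ko", "p_multiexon", "dropout",
                     "p_redundant", "p_full_length", "p_pfam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.gain_rate < 0 or self.noise_edge_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_root_families < 0 or self.n_contaminants < 0:
            raise ValueError("counts must be >= 0")

    def dataset_ids(self) -> List[str]:
        out = []
        for lin in sorted(self.datasets_per_lineage):
            out.extend(f"{lin}{i + 1}" for i in range(self.datasets_per_lineage[lin]))
        return out

    def lineage_of_dataset(self, dataset_id: str) -> str:
        return dataset_id.rstrip("0123456789")


@dataclass
class FamilyTruth:
    family_id: str
    origin_node: str
    presence: FrozenSet[str]
    is_contaminant: bool = False
    annotated: bool = False
    anchor_accession: Optional[str] = None
    anchor_db: str = "sprot"
    ko_term: Optional[str] = None
    go_terms: FrozenSet[str] = frozenset()
    pfam_domains: FrozenSet[str] = frozenset()
    emitted_datasets: FrozenSet[str] = frozenset()  # filled by emit_study_inputs


@dataclass
class GroundTruth:
    families: Dict[str, FamilyTruth]
    protein_to_family: Dict[str, str] = field(default_factory=dict)

    def presence_patterns(self) -> Dict[str, FrozenSet[str]]:
        return {f.family_id: f.presence for f in self.families.values()}

    def contaminant_ids(self) -> Set[str]:
        return {f.family_id for f in self.families.values() if f.is_contaminant}


def simulate_families_on_tree(params: SimulationParams) -> GroundTruth:
    """Birth/loss simulation of family presence patterns on the cladogram.

    Families originate at the root (``n_root_families``) and at every
    non-root node (Poisson(``gain_rate``) per branch). From its origin a
    family descends towards the leaves, being lost on each branch with
    probability ``loss_prob`` independently. Families lost everywhere are
    dropped. Same seed, same truth.
    """
    tree = parse_cladogram(params.tree)
    rng = np.random.default_rng(params.seed)

    origins: List[str] = ["N1"] * params.n_root_families
    for node in _preorder_nodes(tree):
        if node == tree.root:
            continue
        origins.extend([node] * int(rng.poisson(params.gain_rate)))

    families: Dict[str, FamilyTruth] = {}
    width = max(5, len(str(len(origins))))
    for i, origin in enumerate(origins):
        presence = _descend(tree, origin, params.loss_prob, rng)
        if not presence:
            continue
        fid = f"F{i + 1:0{width}d}"
        families[fid] = FamilyTruth(family_id=fid, origin_node=origin, presence=presence)

    _assign_annotations(families, params, rng)
    return GroundTruth(families=families)


def _preorder_nodes(tree: Cladogram) -> List[str]:
    out: List[str] = []

    def visit(node: str) -> None:
        out.append(node)
        for child in tree.children[node]:
            visit(child)

    visit(tree.root)
    return out


def _descend(tree: Cladogram, origin: str, loss_prob: float, rng) -> FrozenSet[str]:
    present: Set[str] = set()

    def visit(node: str) -> None:
        if not tree.children[node]:
            present.add(node)
            return
        for child in tree.children[node]:
            if rng.random() >= loss_prob:
                visit(child)

    visit(origin)
    return frozenset(present)


def make_go_dag_edges() -> List[Tuple[str, str]]:
    """Deterministic synthetic ontology: 3 roots, 4 levels, is_a only, with a
    handful of multi-parent terms so propagation over a DAG (not a tree) is
    exercised."""
    edges: List[Tuple[str, str]] = []
    term_no = 0

    def new_term() -> str:
        nonlocal term_no
        term_no += 1
        return f"GO:{term_no:07d}"

    roots = [new_term() for _ in range(3)]
    level1 = []
    for r in roots:
        for _ in range(3):
            t = new_term()
            edges.append((t, r))
            level1.append(t)
    level2 = []
    for i, p in enumerate(level1):
        for _ in range(2):
            t = new_term()
            edges.append((t, p))
            if i % 3 == 0:  # second parent within the same root subtree
                edges.append((t, level1[(i + 1) % len(level1)]))
            level2.append(t)
    leaves = []
    for p in level2:
        t = new_term()
        edges.append((t, p))
        leaves.append(t)
    return edges


def go_leaf_terms(edges: Sequence[Tuple[str, str]]) -> List[str]:
    parents = {p for _, p in edges}
    children = {c for c, _ in edges}
    return sorted(children - parents)


def _assign_annotations(
    families: Dict[str, FamilyTruth], params: SimulationParams, rng
) -> None:
    leaf_terms = go_leaf_terms(make_go_dag_edges())
    for i, fid in enumerate(sorted(families)):
        fam = families[fid]
        fam.annotated = bool(rng.random() < params.p_annotated)
        if fam.annotated:
            fam.anchor_accession = f"ACC{i + 1:05d}"
            fam.anchor_db = "sprot" if rng.random() < 0.6 else "trembl"
            if rng.random() < params.p_ko:
                fam.ko_term = f"K{i + 1:05d}"
            n_go = int(rng.integers(1, 4))
            fam.go_terms = frozenset(rng.choice(leaf_terms, size=n_go, replace=False))
        if rng.random() < params.p_pfam:
            n_dom = int(rng.integers(1, 3))
            fam.pfam_domains = frozenset(
                f"PF{int(d) + 1:05d}" for d in rng.integers(0, 40, size=n_dom)
            )


def inject_contaminants(truth: GroundTruth, params: SimulationParams) -> GroundTruth:
    """Mark ``n_contaminants`` families as bacterial contaminants.

    Contaminants get a bacterial-flagged anchor (they are by construction
    annotated), presence restricted to ``contaminant_lineages`` lineage(s)
    (default 1, the profile of a true contaminant), and — unless
    ``contaminant_multiexon`` — single-exon CDS in genome-backed datasets.
    Returns the same truth object, modified in place; ``n_contaminants = 0``
    is the identity.
    """
    if params.n_contaminants == 0:
        return truth
    if params.n_contaminants > len(truth.families):
        raise ValueError(
            f"n_contaminants={params.n_contaminants} exceeds {len(truth.families)} families"
        )
    rng = np.random.default_rng(params.seed + 1)
    chosen = rng.choice(sorted(truth.families), size=params.n_contaminants, replace=False)
    for j, fid in enumerate(chosen):
        fam = truth.families[fid]
        lineages = sorted(fam.presence)
        n_keep = min(params.contaminant_lineages, len(lineages))
        keep = rng.choice(lineages, size=n_keep, replace=False)
        fam.presence = frozenset(keep)
        fam.is_contaminant = True
        fam.annotated = True
        fam.anchor_accession = f"BACT{j + 1:04d}"
        fam.anchor_db = "sprot"
        fam.ko_term = None
        fam.go_terms = frozenset()
    return truth


@dataclass
class StudyBundle:
    """In-memory study inputs plus the generating truth."""

    params: SimulationParams
    truth: GroundTruth
    proteins: Dict[str, ProteinRecord]
    tophits: pd.DataFrame
    allvsall: pd.DataFrame
    exon_counts: Dict[str, int]
    pfam: pd.DataFrame
    go_edges: List[Tuple[str, str]]
    completeness_hits: Dict[str, pd.DataFrame]
    bacterial_hits: Dict[str, pd.DataFrame]

    @property
    def tree(self) -> str:
        return self.params.tree

    def write(self, out_dir) -> None:
        from . import io as fio

        fio.write_bundle(self, Path(out_dir))


def emit_study_inputs(truth: GroundTruth, params: SimulationParams) -> StudyBundle:
    """Materialise the study inputs implied by a ground truth.

    For every family and every dataset of each present lineage (subject to
    dropout, with at least one dataset retained per present lineage so the
    truth's presence pattern stays realisable), one member protein is
    emitted. Annotated families yield identical anchor accessions across all
    members; unannotated families yield within-family all-vs-all edges with
    E-values in [1e-30, 1e-15] and, optionally, noise edges above the
    clustering cutoff. Fragment duplicates (``p_redundant``) exercise the
    redundancy-removal step.
    """
    rng = np.random.default_rng(params.seed + 2)
    lineage_datasets: Dict[str, List[str]] = {}
    for ds in params.dataset_ids():
        lineage_datasets.setdefault(params.lineage_of_dataset(ds), []).append(ds)
    missing = {l for f in truth.families.values() for l in f.presence} - set(lineage_datasets)
    if missing:
        raise ValueError(f"tree lineages without datasets: {sorted(missing)}")

    genome_backed = set(params.genome_backed_datasets)
    # per-lineage third-position bias, emulating narrow within-clade spread
    samplers = {
        lin: _codon_sampler(float(rng.uniform(0.55, 0.75)))
        for lin in sorted(lineage_datasets)
    }
    proteins: Dict[str, ProteinRecord] = {}
    exon_counts: Dict[str, int] = {}
    tophit_rows: List[dict] = []
    edge_rows: List[dict] = []
    pfam_rows: List[dict] = []
    truth.protein_to_family = {}

    for fid in sorted(truth.families):
        fam = truth.families[fid]
        length = max(60, int(rng.lognormal(mean=np.log(300.0), sigma=0.3)))
        n_core = int(0.6 * length)
        core = "".join(rng.choice(AA_ALPHABET, size=n_core))
        members: List[str] = []
        fam_members: List[str] = []  # members plus fragment duplicates
        emitted_ds: Set[str] = set()
        for lineage in sorted(fam.presence):
            datasets = lineage_datasets[lineage]
            use = [ds for ds in datasets if rng.random() >= params.dropout]
            if not use:
                use = [datasets[int(rng.integers(0, len(datasets)))]]
            for ds in use:
                pid = f"{ds}|{fid}"
                tail = "".join(rng.choice(AA_ALPHABET, size=length - n_core))
                aa = core + tail
                cds = _back_translate(
                    aa, rng, samplers[lineage],
                    full_length=rng.random() < params.p_full_length,
                )
                exon = None
                if ds in genome_backed:
                    if fam.is_contaminant:
                        exon = 2 + int(rng.poisson(2.0)) if params.contaminant_multiexon else 1
                    else:
                        exon = 2 + int(rng.poisson(2.0)) if rng.random() < params.p_multiexon else 1
                rec = ProteinRecord(pid, ds, lineage, aa, cds, exon)
                proteins[pid] = rec
                if exon is not None:
                    exon_counts[pid] = exon
                truth.protein_to_family[pid] = fid
                members.append(pid)
                fam_members.append(pid)
                emitted_ds.add(ds)
                if rng.random() < params.p_redundant:
                    dup_id = pid + "|r"
                    frac = 0.7 + 0.25 * rng.random()
                    dup_aa = aa[: max(30, int(frac * len(aa)))]
                    dup = ProteinRecord(dup_id, ds, lineage, dup_aa, None, exon)
                    proteins[dup_id] = dup
                    truth.protein_to_family[dup_id] = fid
                    fam_members.append(dup_id)
        fam.emitted_datasets = frozenset(emitted_ds)
        if fam.annotated:
            for pid in fam_members:
                tophit_rows.append(
                    {
                        "protein_id": pid,
                        "accession": fam.anchor_accession,
                        "db": fam.anchor_db,
                        "evalue": 10.0 ** rng.uniform(-50, -15),
                        "bitscore": float(np.round(rng.uniform(100, 400), 1)),
                        "ko": fam.ko_term or "",
                        "go_terms": ";".join(sorted(fam.go_terms)),
                        "is_bacterial": fam.is_contaminant,
                    }
                )
        else:
            for i, q in enumerate(members):
                for s in members[i + 1 :]:
                    e1 = 10.0 ** rng.uniform(-30, -15)
                    e2 = 10.0 ** rng.uniform(-30, -15)
                    edge_rows.append(_outfmt6_row(q, s, e1, rng))
                    edge_rows.append(_outfmt6_row(s, q, e2, rng))
        for pid in fam_members:
            for dom in sorted(fam.pfam_domains):
                pfam_rows.append(
                    {"protein_id": pid, "domain": dom, "evalue": 10.0 ** rng.uniform(-20, -4)}
                )

    if params.noise_edge_rate > 0 and edge_rows:
        unannotated = [
            p for p, f in sorted(truth.protein_to_family.items())
            if not truth.families[f].annotated
        ]
        n_noise = int(rng.poisson(params.noise_edge_rate * len(unannotated)))
        for _ in range(n_noise):
            q, s = rng.choice(unannotated, size=2, replace=False)
            if truth.protein_to_family[q] == truth.protein_to_family[s]:
                continue
            edge_rows.append(_outfmt6_row(str(q), str(s), 10.0 ** rng.uniform(-8, -2), rng))

    tophits = pd.DataFrame(
        tophit_rows,
        columns=["protein_id", "accession", "db", "evalue", "bitscore", "ko", "go_terms", "is_bacterial"],
    )
    allvsall = pd.DataFrame(edge_rows, columns=OUTFMT6_COLUMNS)
    pfam = pd.DataFrame(pfam_rows, columns=["protein_id", "domain", "evalue"])
    completeness, bacterial = _qc_tables(params, proteins, rng)
    return StudyBundle(
        params=params,
        truth=truth,
        proteins=proteins,
        tophits=tophits,
        allvsall=allvsall,
        exon_counts=exon_counts,
        pfam=pfam,
        go_edges=make_go_dag_edges(),
        completeness_hits=completeness,
        bacterial_hits=bacterial,
    )


OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _outfmt6_row(q: str, s: str, evalue: float, rng) -> dict:
    length = int(rng.integers(80, 300))
    pident = float(np.round(rng.uniform(30, 95), 2))
    return {
        "qseqid": q, "sseqid": s, "pident": pident, "length": length,
        "mismatch": int(length * (100 - pident) / 100), "gapopen": int(rng.integers(0, 5)),
        "qstart": 1, "qend": length, "sstart": 1, "send": length,
        "evalue": evalue, "bitscore": float(np.round(rng.uniform(50, 300), 1)),
    }


def _codon_sampler(gc3_bias: float) -> Dict[str, Tuple[List[str], np.ndarray]]:
    """Per amino acid: synonymous codons and cumulative weights, with
    G/C-ending codons favoured at ``gc3_bias``."""
    out = {}
    for aa, options in _SYNONYMOUS.items():
        w = np.array([gc3_bias if c[2] in "GC" else 1.0 - gc3_bias for c in options])
        out[aa] = (options, np.cumsum(w / w.sum()))
    return out


def _back_translate(aa: str, rng, sampler, full_length: bool = True) -> str:
    """Back-translate with synonymous codons drawn per site from ``sampler``,
    giving each lineage a distinct third-position composition and a moderate
    codon-usage bias."""
    draws = rng.random(len(aa))
    codons = []
    for a, r in zip(aa, draws):
        options, cum = sampler[a]
        codons.append(options[int(np.searchsorted(cum, r))])
    body = "".join(codons)
    if not body.startswith("ATG"):
        body = "ATG" + body
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
    if full_length:
        return body + stop
    return body[:-1]  # truncated: not a full-length CDS


def _qc_tables(
    params: SimulationParams, proteins: Mapping[str, ProteinRecord], rng
) -> Tuple[Dict[str, pd.DataFrame], Dict[str, pd.DataFrame]]:
    """Small completeness (core-gene) and bacterial-screen hit tables per
    dataset, emulating ~89% core-gene recovery and <3% bacterial hits."""
    core_ids = [f"CEG{i + 1:04d}" for i in range(params.core_set_size)]
    by_ds: Dict[str, List[str]] = {}
    for pid, rec in proteins.items():
        by_ds.setdefault(rec.dataset_id, []).append(pid)
    completeness: Dict[str, pd.DataFrame] = {}
    bacterial: Dict[str, pd.DataFrame] = {}
    for ds in params.dataset_ids():
        n_hit = int(rng.binomial(params.core_set_size, 0.89))
        hit_ids = rng.choice(core_ids, size=n_hit, replace=False)
        completeness[ds] = pd.DataFrame(
            {"core_gene_id": sorted(hit_ids), "evalue": 10.0 ** rng.uniform(-40, -11, size=n_hit)}
        )
        seqs = by_ds.get(ds, [])
        n_bact = int(rng.binomial(len(seqs), 0.02)) if seqs else 0
        chosen = rng.choice(seqs, size=n_bact, replace=False) if n_bact else []
        bacterial[ds] = pd.DataFrame(
            {"query": sorted(chosen), "evalue": 10.0 ** rng.uniform(-30, -11, size=n_bact)}
        )
    return completeness, bacterial


def simulate_study(params: SimulationParams) -> StudyBundle:
    """Convenience: truth + contaminants + emitted inputs in one call."""
    truth = simulate_families_on_tree(params)
    truth = inject_contaminants(truth, params)
    return emit_study_inputs(truth, params)


def expected_retained_families(truth: GroundTruth, params: SimulationParams) -> Dict[str, Set[str]]:
    """Truth-side prediction of which families the pipeline retains, by
    category — the oracle for end-to-end parameter recovery.

    Annotated families are retained (KO if they carry a KO term, else UP)
    unless they are contaminants matching the discard profile (bacterial hits
    confined to one lineage with no multi-exon evidence). Unannotated
    families are retained as OM when emitted to >= 2 datasets.
    """
    out: Dict[str, Set[str]] = {"KO": set(), "UP": set(), "OM": set(), "discarded": set(), "unclustered": set()}
    genome_backed = set(params.genome_backed_datasets)
    for fid, fam in truth.families.items():
        if fam.annotated:
            if fam.is_contaminant:
                multiexon = params.contaminant_multiexon and bool(fam.emitted_datasets & genome_backed)
                if len(fam.presence) >= 2 or multiexon:
                    out["KO" if fam.ko_term else "UP"].add(fid)
                else:
                    out["discarded"].add(fid)
            else:
                out["KO" if fam.ko_term else "UP"].add(fid)
        else:
            if len(fam.emitted_datasets) >= 2:
                out["OM"].add(fid)
            else:
                out["unclustered"].add(fid)
    return out
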