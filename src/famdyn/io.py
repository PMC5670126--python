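"""File-level interfaces for study bundles.

Everything is plain text: per-dataset FASTA (proteins and CDS), TSV tables
(top hits, exon counts, Pfam, QC hit tables), BLAST tabular outfmt-6 for the
all-vs-all similarity search, OBO for the ontology, Newick for the tree, and
a ground-truth TSV when the bundle is synthetic.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import OUTFMT6_COLUMNS, SimulationParams, StudyBundle, GroundTruth, FamilyTruth
from .types import ProteinRecord

TOPHIT_COLUMNS = ["protein_id", "accession", "db", "evalue", "bitscore", "ko", "go_terms", "is_bacterial"]


def write_fasta(records: List[Tuple[str, str]], path: Path) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: Path) -> List[Tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_obo(edges: List[Tuple[str, str]], path: Path) -> None:
    """Minimal OBO writer (id, name, is_a), readable by obonet."""
    terms: Dict[str, List[str]] = {}
    for child, parent in edges:
        terms.setdefault(child, []).append(parent)
        terms.setdefault(parent, [])
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n\n")
        for term in sorted(terms):
            fh.write(f"[Term]\nid: {term}\nname: synthetic term {term}\n")
            for parent in sorted(terms[term]):
                fh.write(f"is_a: {parent} ! synthetic term {parent}\n")
            fh.write("\n")


def write_bundle(bundle: StudyBundle, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    (out_dir / "datasets").mkdir(parents=True, exist_ok=True)
    (out_dir / "qc").mkdir(exist_ok=True)

    by_ds: Dict[str, List[ProteinRecord]] = {}
    for rec in bundle.proteins.values():
        by_ds.setdefault(rec.dataset_id, []).append(rec)
    for ds in sorted(by_ds):
        recs = sorted(by_ds[ds], key=lambda r: r.protein_id)
        write_fasta([(r.protein_id, r.aa_seq) for r in recs], out_dir / "datasets" / f"{ds}.faa")
        cds = [(r.protein_id, r.cds_seq) for r in recs if r.cds_seq]
        if cds:
            write_fasta(cds, out_dir / "datasets" / f"{ds}.fna")

    meta = pd.DataFrame(
        [
            {"protein_id": r.protein_id, "dataset_id": r.dataset_id, "lineage": r.lineage}
            for r in sorted(bundle.proteins.values(), key=lambda r: r.protein_id)
        ]
    )
    meta.to_csv(out_dir / "proteins.tsv", sep="\t", index=False)
    bundle.tophits.sort_values(["protein_id", "accession"]).to_csv(
        out_dir / "tophits.tsv", sep="\t", index=False
    )
    bundle.allvsall.sort_values(["qseqid", "sseqid"]).to_csv(
        out_dir / "allvsall.tsv", sep="\t", index=False, header=False
    )
    pd.DataFrame(
        sorted(bundle.exon_counts.items()), columns=["protein_id", "exon_count"]
    ).to_csv(out_dir / "exons.tsv", sep="\t", index=False)
    bundle.pfam.sort_values(["protein_id", "domain"]).to_csv(
        out_dir / "pfam.tsv", sep="\t", index=False
    )
    write_obo(bundle.go_edges, out_dir / "go.obo")
    (out_dir / "tree.nwk").write_text(bundle.params.tree + "\n")
    for ds, df in sorted(bundle.completeness_hits.items()):
        df.to_csv(out_dir / "qc" / f"completeness_{ds}.tsv", sep="\t", index=False)
    for ds, df in sorted(bundle.bacterial_hits.items()):
        df.to_csv(out_dir / "qc" / f"bacterial_{ds}.tsv", sep="\t", index=False)

    truth_rows = []
    for fid in sorted(bundle.truth.families):
        fam = bundle.truth.families[fid]
        truth_rows.append(
            {
                "family_id": fid,
                "origin_node": fam.origin_node,
                "presence": ";".join(sorted(fam.presence)),
                "is_contaminant": fam.is_contaminant,
                "annotated": fam.annotated,
                "anchor_accession": fam.anchor_accession or "",
                "anchor_db": fam.anchor_db,
                "ko_term": fam.ko_term or "",
                "go_terms": ";".join(sorted(fam.go_terms)),
                "pfam_domains": ";".join(sorted(fam.pfam_domains)),
                "emitted_datasets": ";".join(sorted(fam.emitted_datasets)),
            }
        )
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    mapping = pd.DataFrame(
        sorted(bundle.truth.protein_to_family.items()), columns=["protein_id", "family_id"]
    )
    mapping.to_csv(out_dir / "protein_families.tsv", sep="\t", index=False)
    with open(out_dir / "params.json", "w") as fh:
        params = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(bundle.params).items()
        }
        json.dump(params, fh, indent=2, sort_keys=True)


def write_groups(groups, path: Path) -> None:
    rows = [
        {
            "group_id": g.group_id,
            "category": g.category,
            "anchor": g.anchor or "",
            "n_members": g.size,
            "members": ";".join(sorted(g.member_protein_ids)),
        }
        for g in sorted(groups, key=lambda g: g.group_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_groups(path: Path, proteins: Dict[str, ProteinRecord]):
    """Re-load homolog groups from a families TSV; lineage/dataset metadata
    is rebuilt from ``proteins``."""
    from .types import HomologGroup

    df = pd.read_csv(path, sep="\t").fillna({"anchor": ""})
    out = []
    for row in df.itertuples(index=False):
        members = frozenset(str(row.members).split(";"))
        out.append(
            HomologGroup(
                group_id=row.group_id,
                category=row.category,
                anchor=row.anchor or None,
                member_protein_ids=members,
                lineages=frozenset(proteins[m].lineage for m in members),
                dataset_ids=frozenset(proteins[m].dataset_id for m in members),
            )
        )
    return out


def read_bundle(bundle_dir: Path) -> StudyBundle:
    """Re-load a written bundle (truth included when present)."""
    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / "params.json") as fh:
        raw = json.load(fh)
    raw["genome_backed_datasets"] = tuple(raw.get("genome_backed_datasets", ()))
    params = SimulationParams(**raw)

    meta = pd.read_csv(bundle_dir / "proteins.tsv", sep="\t")
    exons_df = pd.read_csv(bundle_dir / "exons.tsv", sep="\t")
    exon_counts = dict(zip(exons_df["protein_id"], exons_df["exon_count"].astype(int)))

    proteins: Dict[str, ProteinRecord] = {}
    info = {r.protein_id: (r.dataset_id, r.lineage) for r in meta.itertuples(index=False)}
    for faa in sorted((bundle_dir / "datasets").glob("*.faa")):
        cds_path = faa.with_suffix(".fna")
        cds_map = dict(read_fasta(cds_path)) if cds_path.exists() else {}
        for pid, aa in read_fasta(faa):
            ds, lin = info[pid]
            proteins[pid] = ProteinRecord(
                pid, ds, lin, aa, cds_map.get(pid), exon_counts.get(pid)
            )

    tophits = pd.read_csv(bundle_dir / "tophits.tsv", sep="\t").fillna({"ko": "", "go_terms": ""})
    allvsall_path = bundle_dir / "allvsall.tsv"
    if allvsall_path.stat().st_size > 0:
        allvsall = pd.read_csv(allvsall_path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    else:
        allvsall = pd.DataFrame(columns=OUTFMT6_COLUMNS)
    pfam = pd.read_csv(bundle_dir / "pfam.tsv", sep="\t")

    completeness = {
        p.stem.replace("completeness_", ""): pd.read_csv(p, sep="\t")
        for p in sorted((bundle_dir / "qc").glob("completeness_*.tsv"))
    }
    bacterial = {
        p.stem.replace("bacterial_", ""): pd.read_csv(p, sep="\t")
        for p in sorted((bundle_dir / "qc").glob("bacterial_*.tsv"))
    }

    truth = GroundTruth(families={})
    truth_path = bundle_dir / "truth.tsv"
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, sep="\t").fillna("")
        for row in tdf.itertuples(index=False):
            split = lambda s: frozenset(x for x in str(s).split(";") if x)
            truth.families[row.family_id] = FamilyTruth(
                family_id=row.family_id,
                origin_node=row.origin_node,
                presence=split(row.presence),
                is_contaminant=bool(row.is_contaminant),
                annotated=bool(row.annotated),
                anchor_accession=row.anchor_accession or None,
                anchor_db=row.anchor_db,
                ko_term=row.ko_term or None,
                go_terms=split(row.go_terms),
                pfam_domains=split(row.pfam_domains),
                emitted_datasets=split(row.emitted_datasets),
            )
        pf = pd.read_csv(bundle_dir / "protein_families.tsv", sep="\t")
        truth.protein_to_family = dict(zip(pf["protein_id"], pf["family_id"]))

    import obonet

    edges: List[Tuple[str, str]] = []
    multi = obonet.read_obo(str(bundle_dir / "go.obo"))
    for u, v, key in multi.edges(keys=True):
        if key == "is_a":
            edges.append((u, v))

    params.tree = (bundle_dir / "tree.nwk").read_text().strip()
    return StudyBundle(
        params=params,
        truth=truth,
        proteins=proteins,
        tophits=tophits,
        allvsall=allvsall,
        exon_counts=exon_counts,
        pfam=pfam,
        go_edges=sorted(edges),
        completeness_hits=completeness,
        bacterial_hits=bacterial,
    )
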