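"""Dataset-level QC and clade pooling.

Covers the preparatory steps of the analysis: restriction to full-length CDS,
codon-usage statistics (overall GC, GC3 and Wright's effective number of
codons), completeness against a core-gene set, the bacterial-hit fraction of
raw sequences, and CD-HIT-like greedy redundancy removal within clade pools.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table

from .types import ProteinRecord

log = logging.getLogger(__name__)

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
START_CODON = "ATG"

# Wright's synonymous-family structure for the standard code. Met and Trp are
# single-codon and contribute the constant 2; stop codons are excluded.
_DEGENERACY: Dict[str, int] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _DEGENERACY[aa] = _DEGENERACY.get(aa, 0) + 1
_CODON_AA = dict(standard_dna_table.forward_table)
DEGENERACY_CLASSES: Dict[int, Tuple[str, ...]] = {
    k: tuple(sorted(a for a, d in _DEGENERACY.items() if d == k)) for k in (2, 3, 4, 6)
}
_CLASS_WEIGHT = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}


@dataclass(frozen=True)
class CodonUsageSummary:
    dataset_id: str
    gc_overall: float  # percent
    gc3: float  # percent
    enc: float
    n_full_length: int


def is_full_length_cds(cds: str) -> bool:
    """True iff the CDS starts with ATG, ends with a stop codon, has length a
    multiple of 3, and contains no internal stop codon."""
    cds = cds.upper()
    if len(cds) < 6 or len(cds) % 3 != 0:
        return False
    if not cds.startswith(START_CODON):
        return False
    if cds[-3:] not in STOP_CODONS:
        return False
    for i in range(3, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return False
    return True


def filter_full_length_cds(records: Iterable[ProteinRecord]) -> List[ProteinRecord]:
    """Retain records whose CDS is full-length; records without a CDS are
    skipped (count logged)."""
    kept: List[ProteinRecord] = []
    n_no_cds = 0
    for rec in records:
        if rec.cds_seq is None:
            n_no_cds += 1
            continue
        if is_full_length_cds(rec.cds_seq):
            kept.append(rec)
    if n_no_cds:
        log.info("filter_full_length_cds: skipped %d records without CDS", n_no_cds)
    return kept


def gc_metrics(cds_seqs: Sequence[str], include_stop: bool = True) -> Tuple[float, float]:
    """(overall GC %, third-position GC %) over a set of full-length CDS.

    Third positions of *all* codons are counted, including start and stop,
    unless ``include_stop`` is False (then the final codon is dropped).
    Returns (nan, nan) on empty input.
    """
    if not cds_seqs:
        log.warning("gc_metrics: empty input, metrics undefined")
        return float("nan"), float("nan")
    gc = at = gc3 = n3 = 0
    for seq in cds_seqs:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
        body = s if include_stop else s[:-3]
        thirds = body[2::3]
        gc3 += thirds.count("G") + thirds.count("C")
        n3 += len(thirds)
    total = gc + at
    return 100.0 * gc / total if total else float("nan"), 100.0 * gc3 / n3 if n3 else float("nan")


def codon_counts(cds_seqs: Iterable[str]) -> Dict[str, int]:
    """Sense-codon counts over full-length CDS (stop codons excluded)."""
    counts: Dict[str, int] = {}
    for seq in cds_seqs:
        s = seq.upper()
        for i in range(0, len(s) - 2, 3):
            codon = s[i : i + 3]
            if codon in _CODON_AA:
                counts[codon] = counts.get(codon, 0) + 1
    return counts


def effective_number_of_codons(cds_seqs: Sequence[str], min_codons: int = 100) -> float:
    """Wright's Nc from pooled codon usage of full-length CDS.

    Per amino acid with k synonyms and n >= 2 observed codons, the codon
    homozygosity is F = (n * sum(p_i^2) - 1) / (n - 1); class means over the
    2-, 3-, 4- and 6-fold families enter Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.
    Amino acids with n < 2 or F <= 0 are excluded from their class mean; a
    missing 3-fold class (Ile) is imputed as the mean of F2 and F4. The result
    is clamped to [20, 61]. Fewer than ``min_codons`` sense codons logs a
    low-confidence warning; nan is returned when no class mean is defined.
    """
    counts = codon_counts(cds_seqs)
    total = sum(counts.values())
    if total < min_codons:
        log.warning(
            "effective_number_of_codons: only %d sense codons (<%d), low confidence",
            total,
            min_codons,
        )
    if total == 0:
        return float("nan")

    per_aa_counts: Dict[str, List[int]] = {}
    for codon, n in counts.items():
        per_aa_counts.setdefault(_CODON_AA[codon], []).append(n)

    fbar: Dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = []
        for aa in aas:
            ns = per_aa_counts.get(aa, [])
            n = sum(ns)
            if n < 2:
                continue
            p2 = sum((ni / n) ** 2 for ni in ns)
            f = (n * p2 - 1.0) / (n - 1.0)
            if f > 0:
                fs.append(f)
        if fs:
            fbar[k] = float(np.mean(fs))

    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if not fbar:
        return float("nan")
    fallback = float(np.mean(list(fbar.values())))
    nc = 2.0
    for k, w in _CLASS_WEIGHT.items():
        nc += w / fbar.get(k, fallback)
    return float(min(61.0, max(20.0, nc)))


def codon_usage_summary(
    records: Iterable[ProteinRecord], dataset_id: str
) -> CodonUsageSummary:
    """QC summary for one dataset: full-length count, GC, GC3 and Nc."""
    full = filter_full_length_cds(records)
    seqs = [r.cds_seq for r in full]
    gc, gc3 = gc_metrics(seqs)
    return CodonUsageSummary(
        dataset_id=dataset_id,
        gc_overall=gc,
        gc3=gc3,
        enc=effective_number_of_codons(seqs),
        n_full_length=len(full),
    )


def dataset_completeness(
    hits: pd.DataFrame, core_set_size: int, evalue_cutoff: float = 1e-10
) -> float:
    """Fraction of core genes with >= 1 hit at E <= cutoff.

    ``hits`` needs columns ``core_gene_id`` and ``evalue``; duplicate hits to
    one core gene count once.
    """
    if core_set_size <= 0:
        raise ValueError("core_set_size must be positive")
    if hits.empty:
        return 0.0
    qualifying = hits.loc[hits["evalue"] <= evalue_cutoff, "core_gene_id"].nunique()
    return qualifying / core_set_size


def bacterial_fraction(
    hits: pd.DataFrame, n_sequences: int, evalue_cutoff: float = 1e-10
) -> float:
    """Proportion of query sequences with >= 1 bacterial-genome hit at
    E <= cutoff; duplicate hits for one query count once."""
    if n_sequences <= 0:
        raise ValueError("n_sequences must be positive")
    if hits.empty:
        return 0.0
    n_hit = hits.loc[hits["evalue"] <= evalue_cutoff, "query"].nunique()
    return n_hit / n_sequences


# ---------------------------------------------------------------------------
# Greedy CD-HIT-like redundancy removal


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: identical aligned columns / shorter length."""
    if not a or not b:
        return 0.0
    aln = _ALIGNER.align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


def _kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def dedupe(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.90,
    prescreen_k: int = 6,
    prescreen_frac: float = 0.3,
) -> List[ProteinRecord]:
    """Greedy clustering at ``identity_threshold``; the longest sequence of
    each cluster (ties: lexicographically smaller id) is the representative.

    Sequences are visited longest-first; each joins the first earlier
    representative it matches at >= threshold, else founds a new cluster. A
    shared-k-mer prescreen skips alignments between clearly unrelated pairs
    (a pair can only reach 90% identity if it shares a large fraction of
    k-mers over the shorter sequence).
    """
    order = sorted(records, key=lambda r: (-r.length_aa, r.protein_id))
    reps: List[ProteinRecord] = []
    rep_kmers: List[set] = []
    for rec in order:
        km = _kmers(rec.aa_seq, prescreen_k)
        placed = False
        for rep, rkm in zip(reps, rep_kmers):
            if km and rkm:
                denom = min(len(km), len(rkm))
                if len(km & rkm) / denom < prescreen_frac:
                    continue
            if pairwise_identity(rec.aa_seq, rep.aa_seq) >= identity_threshold:
                placed = True
                break
        if not placed:
            reps.append(rec)
            rep_kmers.append(km)
    return reps


def pool_and_dedupe(
    records: Iterable[ProteinRecord], identity_threshold: float = 0.90
) -> Dict[str, List[ProteinRecord]]:
    """Pool records by lineage and remove redundancy within each pool."""
    pools: Dict[str, List[ProteinRecord]] = {}
    for rec in records:
        pools.setdefault(rec.lineage, []).append(rec)
    out: Dict[str, List[ProteinRecord]] = {}
    for lineage in sorted(pools):
        out[lineage] = dedupe(pools[lineage], identity_threshold)
        if not out[lineage]:
            log.info("pool_and_dedupe: lineage %s pool is empty", lineage)
    return out
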