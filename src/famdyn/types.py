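"""Shared domain types.

The atomic unit is a protein (with optional CDS and exon count); proteins are
grouped into homolog groups ("gene families"), which are the unit of every
downstream count and test.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein, optionally backed by a CDS and exon count.

    ``lineage`` is a clade label or the outgroup label; ``exon_count`` is only
    meaningful for genome-backed datasets.
    """

    protein_id: str
    dataset_id: str
    lineage: str
    aa_seq: str
    cds_seq: Optional[str] = None
    exon_count: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.aa_seq) == 0:
            raise ValueError(f"empty amino-acid sequence for {self.protein_id}")
        if self.cds_seq is not None and len(self.cds_seq) < 3:
            raise ValueError(f"CDS shorter than one codon for {self.protein_id}")
        if self.exon_count is not None and self.exon_count < 1:
            raise ValueError(f"exon_count must be >= 1 for {self.protein_id}")

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)


@dataclass(frozen=True)
class TopHitAnnotation:
    """A protein's best database match.

    ``db`` records which pool the hit came from (curated pool searched first).
    ``ko_term`` is absent for matches without an orthology assignment;
    ``is_bacterial`` marks top matches against bacterial entries and drives the
    contamination schema.
    """

    protein_id: str
    accession: str
    db: str  # "sprot" | "trembl"
    evalue: float
    bitscore: float
    ko_term: Optional[str] = None
    go_terms: frozenset = field(default_factory=frozenset)
    is_bacterial: bool = False


# Homolog-group categories
KO = "KO"
UP = "UP"
OM = "OM"


@dataclass(frozen=True)
class HomologGroup:
    """A gene family: a set of proteins grouped by shared annotation (KO/UP)
    or by similarity-graph clustering (OM).

    ``anchor`` is the KO term for KO groups, the shared accession for UP
    groups, and ``None`` for OM groups.
    """

    group_id: str
    category: str  # KO | UP | OM
    anchor: Optional[str]
    member_protein_ids: frozenset
    lineages: frozenset
    dataset_ids: frozenset

    def __post_init__(self) -> None:
        if self.category not in (KO, UP, OM):
            raise ValueError(f"unknown category {self.category!r}")
        if not self.member_protein_ids:
            raise ValueError(f"group {self.group_id} has no members")
        if self.category == OM and len(self.member_protein_ids) < 2:
            raise ValueError("OM groups require >= 2 members")

    @property
    def size(self) -> int:
        return len(self.member_protein_ids)


@dataclass(frozen=True)
class FilterDecision:
    """Verdict of the contamination schema for one homolog group."""

    group_id: str
    verdict: str  # keep | discard
    reason: str  # no_bacterial_hit | multiexon_evidence | multilineage_bacterial | bacterial_contaminant
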