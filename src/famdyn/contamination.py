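"""Contamination filtering of annotated homolog groups.

Dinoflagellate sequence data routinely carry bacterial contaminants, yet some
genuine genes resemble bacterial ones (including lateral-transfer candidates).
The schema keeps a group when any of three lines of evidence argues for a
eukaryote origin, and discards it otherwise:

1. no member has a bacterial top match -> keep;
2. any bacterial-hit member has a multi-exonic CDS (genome-backed evidence of
   eukaryote gene structure) -> keep;
3. the bacterial-hit members span two or more lineages (a contaminant is
   expected in one dataset/lineage; recurrent presence suggests a real,
   possibly laterally acquired, gene) -> keep;
4. otherwise -> discard as putative bacterial contamination.

Only annotated (KO/UP) groups are evaluated: OM groups have no database match
and hence no bacterial flag.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Set

import pandas as pd

from .types import FilterDecision, HomologGroup, TopHitAnnotation

KEEP = "keep"
DISCARD = "discard"

R_NO_BACT = "no_bacterial_hit"
R_MULTIEXON = "multiexon_evidence"
R_MULTILINEAGE = "multilineage_bacterial"
R_CONTAMINANT = "bacterial_contaminant"


def flag_bacterial_members(
    group: HomologGroup, annotations: Mapping[str, TopHitAnnotation]
) -> Set[str]:
    """Members of ``group`` whose top match is bacterial.

    Every member of an annotated group must have an annotation; a missing one
    is a contract violation upstream and raises.
    """
    flagged: Set[str] = set()
    for pid in group.member_protein_ids:
        if pid not in annotations:
            raise KeyError(
                f"protein {pid} in annotated group {group.group_id} has no top-hit annotation"
            )
        if annotations[pid].is_bacterial:
            flagged.add(pid)
    return flagged


def apply_filter_schema(
    groups: Iterable[HomologGroup],
    annotations: Mapping[str, TopHitAnnotation],
    exon_counts: Mapping[str, int],
    lineage_of: Mapping[str, str],
) -> List[FilterDecision]:
    """One verdict per group, following the decision tree in module order.

    ``exon_counts`` holds exon counts for genome-backed proteins only;
    absence of a protein from the map means no gene-structure evidence.
    """
    decisions: List[FilterDecision] = []
    for group in groups:
        bacterial = flag_bacterial_members(group, annotations)
        if not bacterial:
            decisions.append(FilterDecision(group.group_id, KEEP, R_NO_BACT))
        elif any(exon_counts.get(pid, 1) >= 2 for pid in bacterial):
            decisions.append(FilterDecision(group.group_id, KEEP, R_MULTIEXON))
        elif len({lineage_of[pid] for pid in bacterial}) >= 2:
            decisions.append(FilterDecision(group.group_id, KEEP, R_MULTILINEAGE))
        else:
            decisions.append(FilterDecision(group.group_id, DISCARD, R_CONTAMINANT))
    return decisions


def decisions_table(decisions: Iterable[FilterDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group_id": d.group_id, "verdict": d.verdict, "reason": d.reason} for d in decisions]
    )


def summarize_decisions(decisions: Iterable[FilterDecision]) -> Dict[str, int]:
    """Counts per reason plus keep/discard totals."""
    out: Dict[str, int] = {KEEP: 0, DISCARD: 0}
    for d in decisions:
        out[d.verdict] += 1
        out[d.reason] = out.get(d.reason, 0) + 1
    return out


def kept_groups(
    groups: Iterable[HomologGroup], decisions: Iterable[FilterDecision]
) -> List[HomologGroup]:
    verdict = {d.group_id: d.verdict for d in decisions}
    return [g for g in groups if verdict.get(g.group_id, KEEP) == KEEP]
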