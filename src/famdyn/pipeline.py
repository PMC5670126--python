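"""End-to-end orchestration: QC -> pooling -> delineation -> contamination
filter -> classification -> enrichment, with per-stage count bookkeeping.

Stages run single-threaded and deterministically; all outputs are sorted by
id before writing so reruns are byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import pandas as pd

from . import classify as fc
from . import contamination as cf
from . import enrichment as en
from . import hogs
from . import preprocess as pp
from .synthetic import StudyBundle
from .types import KO, OM, UP, HomologGroup, ProteinRecord

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Cutoffs and options for a full run (defaults are the study's)."""

    uniprot_e: float = 1e-10
    graph_e: float = 1e-10
    pfam_e: float = 1e-3
    identity: float = 0.90
    inflation: float = 1.2
    elim_alpha: float = 0.01
    min_om_datasets: int = 2
    outgroup: str = "P"
    core_set_size: int = 458
    run_qc: bool = True
    run_enrichment: bool = True

    def __post_init__(self) -> None:
        for name in ("uniprot_e", "graph_e", "pfam_e", "identity", "inflation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


@dataclass
class RunSummary:
    """Per-stage counts; the conservation identities across stages are
    asserted by the caller's tests, not here."""

    counts: Dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.counts, fh, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    summary: RunSummary
    pools: Dict[str, List[ProteinRecord]]
    delineation: hogs.DelineationResult
    decisions: List
    retained_groups: List[HomologGroup]
    matrix: pd.DataFrame
    report: fc.CategoryReport
    qc: Optional[pd.DataFrame] = None
    enrichment_go: Optional[pd.DataFrame] = None
    enrichment_pfam: Optional[pd.DataFrame] = None


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, the convention used for reported ratios."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    if denominator == 0:
        raise ValueError("denominator is zero")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def summarize_family_counts(groups_by_category: Mapping[str, Sequence]) -> Dict[str, int]:
    """Totals per category plus the grand total.

    ``groups_by_category`` maps category -> groups (or -> a bare count).
    Categories with overlapping member sets are a contract violation.
    """
    counts: Dict[str, int] = {}
    seen: Set[str] = set()
    for cat in sorted(groups_by_category):
        val = groups_by_category[cat]
        if isinstance(val, int):
            counts[cat] = val
            continue
        members: Set[str] = set()
        for g in val:
            members |= set(g.member_protein_ids)
        if members & seen:
            raise ValueError(f"category {cat} shares members with another category")
        seen |= members
        counts[cat] = len(val)
    counts["total"] = sum(v for k, v in counts.items() if k != "total")
    return counts


def lineage_presence_counts(
    matrix: pd.DataFrame, groups: Sequence[HomologGroup]
) -> pd.DataFrame:
    """Per-lineage family counts split into annotated (KO/UP) and OM."""
    category = {g.group_id: g.category for g in groups}
    rows = []
    for lin in matrix.columns:
        fams = matrix.index[matrix[lin]]
        n_ann = sum(1 for f in fams if category.get(f) in (KO, UP))
        n_om = sum(1 for f in fams if category.get(f) == OM)
        rows.append({"lineage": lin, "total": len(fams), "ko_up": n_ann, "om": n_om})
    return pd.DataFrame(rows)


def run_pipeline(
    bundle: StudyBundle,
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[Path] = None,
) -> PipelineResult:
    """Run every stage on an in-memory study bundle.

    When ``out_dir`` is given, all intermediate tables are persisted there
    (sorted, so reruns are byte-identical).
    """
    config = config or PipelineConfig()
    summary = RunSummary()

    # --- QC ---------------------------------------------------------------
    qc_df = None
    if config.run_qc:
        qc_rows = []
        by_ds: Dict[str, List[ProteinRecord]] = {}
        for rec in bundle.proteins.values():
            by_ds.setdefault(rec.dataset_id, []).append(rec)
        for ds in sorted(by_ds):
            recs = sorted(by_ds[ds], key=lambda r: r.protein_id)
            cu = pp.codon_usage_summary(recs, ds)
            row = dataclasses.asdict(cu)
            comp = bundle.completeness_hits.get(ds)
            row["completeness"] = (
                pp.dataset_completeness(comp, config.core_set_size) if comp is not None else float("nan")
            )
            bact = bundle.bacterial_hits.get(ds)
            row["bacterial_fraction"] = (
                pp.bacterial_fraction(bact, len(recs)) if bact is not None else float("nan")
            )
            qc_rows.append(row)
        qc_df = pd.DataFrame(qc_rows)
    summary.counts["proteins_in"] = len(bundle.proteins)

    # --- Pool + dedupe ----------------------------------------------------
    pools = pp.pool_and_dedupe(bundle.proteins.values(), config.identity)
    representatives = {r.protein_id: r for pool in pools.values() for r in pool}
    summary.counts["representatives"] = len(representatives)

    # --- Delineation ------------------------------------------------------
    delineation = hogs.delineate(
        representatives,
        bundle.tophits,
        bundle.allvsall,
        evalue_cutoff=config.uniprot_e,
        graph_cutoff=config.graph_e,
        inflation=config.inflation,
        min_datasets=config.min_om_datasets,
    )
    by_cat = delineation.by_category()
    summary.counts["proteins_matched"] = len(delineation.annotations)
    summary.counts["proteins_unmatched"] = len(delineation.unmatched)
    summary.counts["ko_hogs"] = len(by_cat[KO])
    summary.counts["up_hogs"] = len(by_cat[UP])
    summary.counts["om_clusters"] = delineation.om_clusters_total
    summary.counts["om_hogs_initial"] = delineation.om_clusters_multi
    summary.counts["om_hogs_retained"] = len(by_cat[OM])

    # --- Contamination filter (annotated groups only) ---------------------
    annotated_groups = by_cat[KO] + by_cat[UP]
    lineage_of = {pid: rec.lineage for pid, rec in representatives.items()}
    decisions = cf.apply_filter_schema(
        annotated_groups, delineation.annotations, bundle.exon_counts, lineage_of
    )
    kept_annotated = cf.kept_groups(annotated_groups, decisions)
    summary.counts["annotated_groups_evaluated"] = len(annotated_groups)
    summary.counts["annotated_groups_kept"] = len(kept_annotated)
    summary.counts["annotated_groups_discarded"] = len(annotated_groups) - len(kept_annotated)

    retained = sorted(kept_annotated + by_cat[OM], key=lambda g: g.group_id)
    summary.counts["families_retained"] = len(retained)
    summary.counts["ko_hogs_retained"] = sum(1 for g in retained if g.category == KO)
    summary.counts["up_hogs_retained"] = sum(1 for g in retained if g.category == UP)

    # --- Classification ---------------------------------------------------
    tree = fc.parse_cladogram(bundle.tree)
    matrix = fc.build_presence_matrix(retained, lineages=list(tree.leaves))
    report = fc.classify(matrix, tree, outgroup=config.outgroup)
    summary.counts["n1_total"] = len(report.node[tree.root][0])
    summary.counts["sues_core"] = len(report.sues_core)
    summary.counts["sym_core"] = len(report.sym_core)
    summary.counts["sym_core_specific"] = len(report.sym_core_specific)

    # --- Enrichment -------------------------------------------------------
    go_df = pfam_df = None
    if config.run_enrichment and len(retained) > 0:
        dag = en.GoDag.from_edges(bundle.go_edges)
        protein_go = {
            pid: set(ann.go_terms) for pid, ann in delineation.annotations.items()
        }
        fam_ann = en.annotate_families(retained, protein_go, bundle.pfam, dag, config.pfam_e)
        background = {g.group_id for g in retained}
        study = report.sym_core_specific
        if study:
            go_df = en.go_elim_enrichment(study, background, fam_ann, dag, config.elim_alpha)
            pfam_df = en.pfam_enrichment(study, background, fam_ann)
        summary.counts["families_with_pfam"] = sum(
            1 for f in background if fam_ann.pfam.get(f)
        )

    result = PipelineResult(
        summary=summary,
        pools=pools,
        delineation=delineation,
        decisions=decisions,
        retained_groups=retained,
        matrix=matrix,
        report=report,
        qc=qc_df,
        enrichment_go=go_df,
        enrichment_pfam=pfam_df,
    )
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if result.qc is not None:
        result.qc.to_csv(out_dir / "qc_summary.tsv", sep="\t", index=False)
    rows = [
        {
            "group_id": g.group_id,
            "category": g.category,
            "anchor": g.anchor or "",
            "n_members": g.size,
            "members": ";".join(sorted(g.member_protein_ids)),
        }
        for g in sorted(result.retained_groups, key=lambda g: g.group_id)
    ]
    pd.DataFrame(rows).to_csv(out_dir / "families.tsv", sep="\t", index=False)
    cf.decisions_table(result.decisions).sort_values("group_id").to_csv(
        out_dir / "filter_decisions.tsv", sep="\t", index=False
    )
    result.matrix.sort_index().to_csv(out_dir / "presence_matrix.tsv", sep="\t")
    result.report.node_counts().to_csv(out_dir / "node_counts.tsv", sep="\t", index=False)
    result.report.lineage_counts().to_csv(out_dir / "lineage_counts.tsv", sep="\t", index=False)
    lineage_presence_counts(result.matrix, result.retained_groups).to_csv(
        out_dir / "lineage_presence_counts.tsv", sep="\t", index=False
    )
    result.report.intersection_counts().to_csv(
        out_dir / "intersection_counts.tsv", sep="\t", index=False
    )
    if result.enrichment_go is not None:
        result.enrichment_go.to_csv(out_dir / "enrichment_go.tsv", sep="\t", index=False)
    if result.enrichment_pfam is not None:
        result.enrichment_pfam.to_csv(out_dir / "enrichment_pfam.tsv", sep="\t", index=False)
    result.summary.to_json(out_dir / "run_summary.json")
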