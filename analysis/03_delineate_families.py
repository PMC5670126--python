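#!/usr/bin/env python
"""Delineate gene families and filter contaminants.

Pools datasets by lineage, removes redundancy (>= 90% identity), assigns
database top hits, builds KO/UP groups, clusters the unmatched remainder with
MCL, applies the contamination schema, and scores everything against the
generator's truth. Writes results/families.tsv, results/filter_decisions.tsv
and results/delineation_summary.json.
"""
import json
from pathlib import Path

from famdyn import contamination as cf
from famdyn import hogs
from famdyn import io as fio
from famdyn import pipeline as pl
from famdyn import preprocess as pp
from famdyn import synthetic as syn

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = fio.read_bundle(ROOT / "bundle")
    pools = pp.pool_and_dedupe(bundle.proteins.values())
    reps = {r.protein_id: r for pool in pools.values() for r in pool}
    print(f"{len(bundle.proteins)} proteins -> {len(reps)} representatives after dedup")

    res = hogs.delineate(reps, bundle.tophits, bundle.allvsall)
    by_cat = res.by_category()
    print(f"matched {len(res.annotations)} / unmatched {len(res.unmatched)}; "
          f"{len(by_cat['KO'])} KO, {len(by_cat['UP'])} UP groups; "
          f"{res.om_clusters_multi} OM clusters, {len(by_cat['OM'])} retained (>=2 datasets)")

    annotated = by_cat["KO"] + by_cat["UP"]
    lineage_of = {p: r.lineage for p, r in reps.items()}
    decisions = cf.apply_filter_schema(annotated, res.annotations, bundle.exon_counts, lineage_of)
    summary = cf.summarize_decisions(decisions)
    reasons = {k: v for k, v in summary.items() if k not in (cf.KEEP, cf.DISCARD)}
    print(f"contamination schema: {summary[cf.KEEP]} kept, {summary[cf.DISCARD]} discarded "
          f"(reasons: {reasons})")
    kept = cf.kept_groups(annotated, decisions) + by_cat["OM"]

    truth = bundle.truth
    expected = syn.expected_retained_families(truth, bundle.params)
    got = {truth.protein_to_family[next(iter(g.member_protein_ids))] for g in kept}
    exp = expected["KO"] | expected["UP"] | expected["OM"]
    print(f"retained {len(kept)} families; truth-expected {len(exp)}; "
          f"agreement {100.0 * len(got & exp) / len(exp):.1f}%")

    fio.write_groups(kept, ROOT / "families.tsv")
    cf.decisions_table(decisions).sort_values("group_id").to_csv(
        ROOT / "filter_decisions.tsv", sep="\t", index=False
    )
    counts = pl.summarize_family_counts(
        {"KO": [g for g in kept if g.category == "KO"],
         "UP": [g for g in kept if g.category == "UP"],
         "OM": [g for g in kept if g.category == "OM"]}
    )
    with open(ROOT / "delineation_summary.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    print(f"category counts: {counts}")


if __name__ == "__main__":
    main()
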