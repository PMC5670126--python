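#!/usr/bin/env python
"""Functional enrichment of the ingroup-exclusive core families.

Tests GO terms (Fisher + elimination over the ontology DAG) and Pfam domains
(one-sided Fisher both directions, BH-adjusted) in the SymCore-specific set
against the full family catalogue (root-node background). Writes tables to
results/enrichment/.
"""
from pathlib import Path

from famdyn import classify as fc
from famdyn import enrichment as en
from famdyn import hogs
from famdyn import io as fio
from famdyn import preprocess as pp

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = fio.read_bundle(ROOT / "bundle")
    groups = fio.read_groups(ROOT / "families.tsv", bundle.proteins)
    tree = fc.parse_cladogram(bundle.tree)
    matrix = fc.build_presence_matrix(groups, lineages=list(tree.leaves))
    report = fc.classify(matrix, tree, outgroup="P")

    dag = en.GoDag.from_edges(bundle.go_edges)
    annotations = hogs.assign_top_hits(bundle.tophits)
    protein_go = {p: set(a.go_terms) for p, a in annotations.items()}
    fam_ann = en.annotate_families(groups, protein_go, bundle.pfam, dag)

    background = {g.group_id for g in groups}
    study = report.sym_core_specific
    print(f"study set: {len(study)} SymCore-specific families; "
          f"background: {len(background)} families")
    out = ROOT / "enrichment"
    out.mkdir(exist_ok=True)
    if not study:
        print("no SymCore-specific families in this run; nothing to test")
        return

    go = en.go_elim_enrichment(study, background, fam_ann, dag, elim_alpha=0.01)
    pfam = en.pfam_enrichment(study, background, fam_ann)
    go.to_csv(out / "go_symcore_specific.tsv", sep="\t", index=False)
    pfam.to_csv(out / "pfam_symcore_specific.tsv", sep="\t", index=False)

    print(f"\ntested {len(go)} GO terms (elim); {len(go[go['p_raw'] < 0.05])} at raw p < 0.05")
    print(go.head(5).to_string(index=False))
    n_sig = int((pfam["p_adjusted"] < 0.05).sum())
    print(f"\ntested {pfam['term'].nunique()} Pfam domains both directions; "
          f"{n_sig} direction-tests at BH-adjusted p < 0.05")
    print(pfam.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
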