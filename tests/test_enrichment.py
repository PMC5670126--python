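"""Ontology handling, exact tests, BH adjustment and the elim procedure."""
import math

import numpy as np
import pandas as pd
import pytest

from famdyn import enrichment as en
from famdyn.types import UP, HomologGroup


def _dag_chain():
    return en.GoDag.from_edges([("mid", "root"), ("leaf", "mid")])


# --- DAG --------------------------------------------------------------------

def test_chain_depths():
    dag = _dag_chain()
    assert dag.depth == {"root": 0, "mid": 1, "leaf": 2}
    assert dag.roots == frozenset({"root"})


def test_multi_parent_ancestors_retained():
    dag = en.GoDag.from_edges([("c", "p1"), ("c", "p2"), ("p1", "r"), ("p2", "r")])
    assert dag.ancestors("c") == frozenset({"p1", "p2", "r"})


def test_cyclic_ontology_rejected():
    with pytest.raises(ValueError):
        en.GoDag.from_edges([("a", "b"), ("b", "a")])


def test_synthetic_dag_ancestors_match_transitive_closure():
    from famdyn.synthetic import make_go_dag_edges

    edges = make_go_dag_edges()
    dag = en.GoDag.from_edges(edges)
    # independent closure by iterated parent expansion
    parents = {}
    for c, p in edges:
        parents.setdefault(c, set()).add(p)
    for term in dag.terms:
        closure = set()
        frontier = set(parents.get(term, ()))
        while frontier:
            closure |= frontier
            frontier = set().union(*(parents.get(t, set()) for t in frontier)) - closure
        assert dag.ancestors(term) == frozenset(closure)


def test_obo_roundtrip(tmp_path):
    from famdyn.io import write_obo
    from famdyn.synthetic import make_go_dag_edges

    edges = make_go_dag_edges()
    path = tmp_path / "go.obo"
    write_obo(edges, path)
    dag = en.load_go_dag(str(path))
    assert dag.terms == en.GoDag.from_edges(edges).terms
    assert dag.depth == en.GoDag.from_edges(edges).depth


# --- family annotation ------------------------------------------------------

def _fam_group(gid, members):
    return HomologGroup(gid, UP, "x", frozenset(members), frozenset({"A"}), frozenset({"d"}))


def test_family_go_union_is_propagated():
    dag = _dag_chain()
    groups = [_fam_group("f1", ["p1", "p2"])]
    ann = en.annotate_families(groups, {"p1": {"leaf"}, "p2": set()}, pd.DataFrame(), dag)
    assert ann.go["f1"] == frozenset({"leaf", "mid", "root"})


def test_pfam_cutoff_excludes_weak_hits():
    dag = _dag_chain()
    pfam = pd.DataFrame(
        {"protein_id": ["p1", "p1"], "domain": ["PF1", "PF2"], "evalue": [1e-5, 0.01]}
    )
    ann = en.annotate_families([_fam_group("f1", ["p1"])], {}, pfam, dag)
    assert ann.pfam["f1"] == frozenset({"PF1"})


# --- Fisher one-sided -------------------------------------------------------

def test_fisher_worked_example():
    # C(4,3)C(4,1) + C(4,4)C(4,0) over C(8,4) = (16+1)/70
    assert en.fisher_exact_one_sided(3, 4, 4, 8, "over") == pytest.approx(17 / 70)


def test_fisher_under_boundary():
    # k=0, n+K<=M: p = C(M-K, n)/C(M, n)
    p = en.fisher_exact_one_sided(0, 3, 4, 10, "under")
    assert p == pytest.approx(math.comb(6, 3) / math.comb(10, 3))


def test_fisher_invalid_counts_rejected():
    with pytest.raises(ValueError):
        en.fisher_exact_one_sided(5, 4, 4, 8, "over")
    with pytest.raises(ValueError):
        en.fisher_exact_one_sided(1, 2, 3, 8, "sideways")


def _hypergeom_tail_oracle(k, n, K, M, direction):
    """Exhaustive enumeration of the hypergeometric tail."""
    denom = math.comb(M, n)
    lo, hi = max(0, n + K - M), min(n, K)
    if direction == "over":
        ks = range(k, hi + 1)
    else:
        ks = range(lo, k + 1)
    return sum(math.comb(K, j) * math.comb(M - K, n - j) for j in ks) / denom


def test_fisher_matches_enumeration_for_small_backgrounds():
    rng = np.random.default_rng(9)
    for _ in range(200):
        M = int(rng.integers(2, 61))
        n = int(rng.integers(1, M + 1))
        K = int(rng.integers(0, M + 1))
        lo, hi = max(0, n + K - M), min(n, K)
        k = int(rng.integers(lo, hi + 1))
        for direction in ("over", "under"):
            assert en.fisher_exact_one_sided(k, n, K, M, direction) == pytest.approx(
                _hypergeom_tail_oracle(k, n, K, M, direction), rel=1e-10, abs=1e-12
            )


# --- BH ---------------------------------------------------------------------

def _bh_oracle(p):
    """Direct step-up: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, m * p[i] / rank)
        q[i] = best
    return q


def test_bh_examples():
    assert en.bh_adjust([0.03]) == pytest.approx([0.03])
    assert en.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
    assert en.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_matches_step_up_oracle():
    rng = np.random.default_rng(12)
    p = rng.random(50)
    adj = en.bh_adjust(p)
    assert adj == pytest.approx(_bh_oracle(list(p)), abs=1e-12)
    # monotone in rank and never below raw
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
    assert (adj >= p - 1e-12).all()


def test_bh_rejects_nan():
    with pytest.raises(ValueError):
        en.bh_adjust([0.1, float("nan")])


# --- elim enrichment --------------------------------------------------------

def _fixture_annotations(dag, fam_terms):
    ann = en.FamilyAnnotation()
    for fam, terms in fam_terms.items():
        ann.go[fam] = dag.propagate(terms)
    return ann


def test_elim_zero_alpha_equals_classic_fisher():
    dag = _dag_chain()
    fams = {f"f{i}": ({"leaf"} if i < 8 else set()) for i in range(20)}
    ann = _fixture_annotations(dag, fams)
    background = set(fams)
    study = {f"f{i}" for i in range(6)}
    elim0 = en.go_elim_enrichment(study, background, ann, dag, elim_alpha=0.0)
    for row in elim0.itertuples(index=False):
        classic = en.fisher_exact_one_sided(
            row.study_count, row.study_size, row.background_count, row.background_size, "over"
        )
        assert row.p_raw == pytest.approx(classic)


def test_elim_removes_leaf_signal_from_ancestors():
    """Signal concentrated at the leaf: the root inherits all leaf families by
    propagation, but after elimination it is tested without them and shows no
    enrichment."""
    dag = _dag_chain()
    fams = {}
    for i in range(20):
        if i < 6:
            fams[f"f{i}"] = {"leaf"}
        elif i < 10:
            fams[f"f{i}"] = {"root"}
        else:
            fams[f"f{i}"] = set()
    ann = _fixture_annotations(dag, fams)
    background = set(fams)
    study = {f"f{i}" for i in range(6)}  # exactly the leaf families
    table = en.go_elim_enrichment(study, background, ann, dag, elim_alpha=0.05)
    by_term = table.set_index("term")
    assert by_term.loc["leaf", "p_raw"] < 0.05
    # root retains only its own 4 direct families, none in the study set
    assert by_term.loc["root", "study_count"] == 0
    assert by_term.loc["root", "p_raw"] == pytest.approx(1.0)
    # without elimination the root would appear enriched
    classic = en.go_elim_enrichment(study, background, ann, dag, elim_alpha=0.0)
    assert classic.set_index("term").loc["root", "p_raw"] < 0.05


def test_planted_midlevel_enrichment_attains_minimum_p_among_ancestors():
    rng = np.random.default_rng(13)
    from famdyn.synthetic import make_go_dag_edges

    dag = en.GoDag.from_edges(make_go_dag_edges())
    target = sorted(t for t in dag.terms if dag.depth[t] == 2)[0]
    background = [f"f{i}" for i in range(300)]
    other_leaves = sorted(
        t for t in dag.terms if dag.depth[t] == 3 and target not in dag.ancestors(t)
    )
    fam_terms = {}
    for fam in background:
        if rng.random() < 0.2:  # directly annotated at the mid-level target
            fam_terms[fam] = {target}
        else:
            fam_terms[fam] = {other_leaves[int(rng.integers(0, len(other_leaves)))]}
    # study: planted ~5-fold enrichment of target-annotated families
    annotated = [f for f in background if target in fam_terms[f]]
    others = [f for f in background if f not in set(annotated)]
    study = set(annotated[:20]) | set(others[:20])
    ann = _fixture_annotations(dag, fam_terms)
    table = en.go_elim_enrichment(study, set(background), ann, dag, elim_alpha=0.01)
    by_term = table.set_index("term")
    anc_ps = [by_term.loc[a, "p_raw"] for a in dag.ancestors(target) if a in by_term.index]
    assert by_term.loc[target, "p_raw"] <= min(anc_ps)


def test_study_must_be_subset_of_background():
    dag = _dag_chain()
    ann = _fixture_annotations(dag, {"f1": {"leaf"}})
    with pytest.raises(ValueError):
        en.go_elim_enrichment({"zz"}, {"f1"}, ann, dag)


# --- Pfam enrichment --------------------------------------------------------

def test_pfam_absent_domain_not_tested():
    ann = en.FamilyAnnotation(pfam={"f1": frozenset({"PF1"}), "f2": frozenset()})
    table = en.pfam_enrichment({"f1"}, {"f1", "f2"}, ann)
    assert set(table["term"]) == {"PF1"}


def test_planted_pfam_overrepresentation_detected():
    rng = np.random.default_rng(21)
    detected = 0
    n_trials = 100
    for _ in range(n_trials):
        background = [f"f{i}" for i in range(400)]
        pfam = {}
        # baseline: domain in 5% of background; study: 50% (10x)
        study = set(background[:60])
        for f in background:
            rate = 0.5 if f in study else 0.05
            doms = {"PFX"} if rng.random() < rate else set()
            if rng.random() < 0.3:
                doms.add(f"PF{int(rng.integers(0, 20))}")
            pfam[f] = frozenset(doms)
        ann = en.FamilyAnnotation(pfam=pfam)
        table = en.pfam_enrichment(study, set(background), ann)
        row = table[(table["term"] == "PFX") & (table["direction"] == "over")]
        if float(row["p_adjusted"].iloc[0]) < 0.05:
            detected += 1
    assert detected >= 95
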