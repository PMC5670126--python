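"""Top-hit assignment, KO/UP grouping, similarity graph and MCL."""
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from famdyn import hogs
from famdyn.types import KO, OM, UP, ProteinRecord


def _hits(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "accession", "db", "evalue", "bitscore", "ko"]
    )


def _protein(pid, lineage="A", ds="A1"):
    return ProteinRecord(pid, ds, lineage, "M" * 10)


# --- top-hit assignment -----------------------------------------------------

def test_bitscore_takes_precedence_over_evalue():
    hits = _hits([
        ("p1", "acc1", "sprot", 1e-20, 200.0, ""),
        ("p1", "acc2", "sprot", 1e-30, 180.0, ""),
    ])
    ann = hogs.assign_top_hits(hits)
    assert ann["p1"].accession == "acc1"


def test_sprot_precedence_over_stronger_trembl():
    hits = _hits([
        ("p1", "t1", "trembl", 1e-40, 500.0, ""),
        ("p1", "s1", "sprot", 1e-12, 60.0, ""),
    ])
    assert hogs.assign_top_hits(hits)["p1"].accession == "s1"


def test_trembl_used_when_no_sprot_hit():
    hits = _hits([("p1", "t1", "trembl", 1e-20, 100.0, "")])
    ann = hogs.assign_top_hits(hits)
    assert ann["p1"].accession == "t1" and ann["p1"].db == "trembl"


def test_hits_above_cutoff_leave_protein_unmatched():
    hits = _hits([("p1", "a", "sprot", 1e-5, 100.0, "")])
    assert hogs.assign_top_hits(hits) == {}


def test_tied_hits_majority_ko_then_lexicographic():
    hits = _hits([
        ("p1", "a1", "sprot", 1e-20, 100.0, "K2"),
        ("p1", "a2", "sprot", 1e-20, 100.0, "K1"),
        ("p1", "a3", "sprot", 1e-20, 100.0, "K2"),
    ])
    assert hogs.assign_top_hits(hits)["p1"].ko_term == "K2"
    hits2 = _hits([
        ("p1", "a1", "sprot", 1e-20, 100.0, "K2"),
        ("p1", "a2", "sprot", 1e-20, 100.0, "K1"),
    ])
    assert hogs.assign_top_hits(hits2)["p1"].ko_term == "K1"


# --- KO / UP grouping -------------------------------------------------------

def test_ko_and_up_grouping_by_anchor():
    hits = _hits(
        [(f"p{i}", "X", "sprot", 1e-20, 100.0, "K00001") for i in range(4)]
        + [("q1", "Y", "sprot", 1e-20, 100.0, ""), ("q2", "Y", "sprot", 1e-20, 100.0, "")]
    )
    proteins = {p: _protein(p) for p in ["p0", "p1", "p2", "p3", "q1", "q2"]}
    groups = hogs.build_ko_up_hogs(hogs.assign_top_hits(hits), proteins)
    by_cat = {(g.category, g.anchor): g for g in groups}
    assert by_cat[(KO, "K00001")].size == 4
    assert by_cat[(UP, "Y")].size == 2
    assert len(groups) == 2


def test_distinct_accessions_same_ko_merge():
    hits = _hits([
        ("p1", "X", "sprot", 1e-20, 100.0, "K00002"),
        ("p2", "Y", "sprot", 1e-20, 100.0, "K00002"),
    ])
    proteins = {p: _protein(p) for p in ["p1", "p2"]}
    groups = hogs.build_ko_up_hogs(hogs.assign_top_hits(hits), proteins)
    assert len(groups) == 1
    assert groups[0].member_protein_ids == frozenset({"p1", "p2"})


def test_no_matched_proteins_yields_no_groups():
    assert hogs.build_ko_up_hogs({}, {}) == []


# --- similarity graph -------------------------------------------------------

def _ava(rows):
    data = []
    for q, s, e in rows:
        data.append({c: 0 for c in hogs_cols()} | {"qseqid": q, "sseqid": s, "evalue": e})
    return pd.DataFrame(data, columns=hogs_cols())


def hogs_cols():
    from famdyn.synthetic import OUTFMT6_COLUMNS

    return OUTFMT6_COLUMNS


def test_edge_weight_is_mean_of_directional_log_evalues():
    g = hogs.build_similarity_graph(_ava([("a", "b", 1e-20), ("b", "a", 1e-30)]))
    assert g["a"]["b"]["weight"] == pytest.approx(25.0)


def test_pair_above_cutoff_gets_no_edge():
    g = hogs.build_similarity_graph(_ava([("a", "b", 1e-8)]))
    assert g.number_of_edges() == 0


def test_zero_evalue_capped():
    g = hogs.build_similarity_graph(_ava([("a", "b", 0.0)]))
    assert g["a"]["b"]["weight"] == pytest.approx(200.0)


def test_single_direction_uses_present_value():
    g = hogs.build_similarity_graph(_ava([("a", "b", 1e-20)]))
    assert g["a"]["b"]["weight"] == pytest.approx(20.0)


# --- MCL --------------------------------------------------------------------

def _clique_graph(cliques, weight=30.0, bridges=()):
    g = nx.Graph()
    for nodes in cliques:
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                g.add_edge(a, b, weight=weight)
    for a, b, w in bridges:
        g.add_edge(a, b, weight=w)
    return g


def _mcl_oracle(graph, inflation=1.2, max_iter=300):
    """Independent dense-matrix MCL coded from the algorithm definition with
    explicit loops; no pruning (fine at <= 50 nodes)."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = [[0.0] * n for _ in range(n)]
    for a, b, d in graph.edges(data=True):
        m[idx[a]][idx[b]] = m[idx[b]][idx[a]] = d["weight"]
    for i in range(n):
        m[i][i] = max(m[i]) if max(m[i]) > 0 else 1.0
    def normalise(mat):
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            for i in range(n):
                mat[i][j] /= s
    normalise(m)
    for _ in range(max_iter):
        sq = [[sum(m[i][k] * m[k][j] for k in range(n)) for j in range(n)] for i in range(n)]
        infl = [[sq[i][j] ** inflation for j in range(n)] for i in range(n)]
        normalise(infl)
        delta = max(abs(infl[i][j] - m[i][j]) for i in range(n) for j in range(n))
        m = infl
        if delta < 1e-10:
            break
    # clusters: connected components over nonzero structure of the limit matrix
    g2 = nx.Graph()
    g2.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if m[i][j] > 1e-6:
                g2.add_edge(i, j)
    return {frozenset(nodes[i] for i in comp) for comp in nx.connected_components(g2)}


def test_two_disjoint_cliques_give_two_clusters():
    g = _clique_graph([list("abcd"), list("efgh")])
    res = hogs.mcl_cluster(g)
    assert {frozenset(c) for c in res.clusters} == {frozenset("abcd"), frozenset("efgh")}
    assert res.converged


def test_single_edge_is_one_cluster():
    g = nx.Graph()
    g.add_edge("A", "B", weight=15.0)
    res = hogs.mcl_cluster(g)
    assert res.clusters == [frozenset({"A", "B"})]


def test_barbell_splits_at_weak_bridge_matching_oracle():
    c1 = [f"x{i}" for i in range(5)]
    c2 = [f"y{i}" for i in range(5)]
    g = _clique_graph([c1, c2], weight=30.0, bridges=[("x0", "y0", 1.0)])
    res = hogs.mcl_cluster(g, inflation=1.2)
    got = {frozenset(c) for c in res.clusters}
    assert got == {frozenset(c1), frozenset(c2)}
    assert got == _mcl_oracle(g)


def test_mcl_matches_oracle_on_random_sparse_graphs():
    rng = np.random.default_rng(17)
    for trial in range(5):
        g = nx.Graph()
        n_cliques = int(rng.integers(2, 5))
        start = 0
        cliques = []
        for _ in range(n_cliques):
            size = int(rng.integers(2, 6))
            nodes = [f"n{start + i}" for i in range(size)]
            start += size
            cliques.append(nodes)
        g = _clique_graph(cliques, weight=float(rng.uniform(20, 40)))
        assert {frozenset(c) for c in hogs.mcl_cluster(g).clusters} == _mcl_oracle(g)


def test_mcl_deterministic_across_reruns():
    g = _clique_graph([list("abcde"), list("fghij")], bridges=[("a", "f", 2.0)])
    r1 = hogs.mcl_cluster(g)
    r2 = hogs.mcl_cluster(g)
    assert r1.clusters == r2.clusters


def test_mcl_empty_graph_rejected():
    with pytest.raises(ValueError):
        hogs.mcl_cluster(nx.Graph())


# --- OM filter --------------------------------------------------------------

def test_om_filter_requires_two_datasets():
    proteins = {
        "a": _protein("a", ds="d1"),
        "b": _protein("b", ds="d2", lineage="B"),
        "c": _protein("c", ds="d1"),
        "d": _protein("d", ds="d1"),
    }
    kept = hogs.filter_om_hogs([frozenset({"a", "b"}), frozenset({"c", "d"})], proteins)
    assert len(kept) == 1
    assert kept[0].member_protein_ids == frozenset({"a", "b"})
    assert kept[0].category == OM


def test_delineation_partitions_proteins(study_bundle, study_result):
    """Every representative lands in exactly one group or is an unclustered
    singleton / unmatched leftover."""
    res = study_result.delineation
    reps = {r.protein_id for pool in study_result.pools.values() for r in pool}
    in_groups = [pid for g in res.groups for pid in g.member_protein_ids]
    assert len(in_groups) == len(set(in_groups))  # disjoint groups
    assert set(in_groups) | set(res.unclustered) <= reps
    assert len(res.annotations) + len(res.unmatched) == len(reps)
    for g in res.groups:
        if g.category == UP:
            accs = {res.annotations[m].accession for m in g.member_protein_ids}
            assert len(accs) == 1
        elif g.category == KO:
            kos = {res.annotations[m].ko_term for m in g.member_protein_ids}
            assert len(kos) == 1
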