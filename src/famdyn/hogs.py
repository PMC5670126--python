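"""Gene-family (homolog-group) delineation.

Three routes, mirroring how annotation coverage partitions the proteins:

* KO groups — proteins whose database top match carries a KEGG Orthology
  term, keyed by that term;
* UP groups — remaining matched proteins, keyed by the shared top-match
  accession;
* OM groups — database-unmatched proteins, clustered by Markov clustering
  (MCL) of the all-vs-all similarity graph, retained only when members come
  from two or more source datasets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .types import KO, OM, UP, HomologGroup, ProteinRecord, TopHitAnnotation

log = logging.getLogger(__name__)

DEFAULT_EVALUE_CUTOFF = 1e-10
DEFAULT_WEIGHT_CAP = 200.0


def assign_top_hits(
    hits: pd.DataFrame, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> Dict[str, TopHitAnnotation]:
    """Pick one top hit per protein from a raw hit table.

    Columns required: protein_id, accession, db (sprot|trembl), evalue,
    bitscore; optional: ko, go_terms (semicolon-joined), is_bacterial.
    Hits above the E-value cutoff are dropped. Curated-pool (sprot) hits take
    precedence over trembl; within a pool ties are broken by higher bitscore,
    then lower E-value, then lexicographic accession. When several hits tie
    exactly on (bitscore, evalue) and disagree on the KO term, the majority KO
    wins, then the lexicographically smallest.

    Proteins with no qualifying hit simply do not appear in the result (they
    are routed to OM clustering by the caller).
    """
    out: Dict[str, TopHitAnnotation] = {}
    qualifying = hits[hits["evalue"] <= evalue_cutoff]
    for protein_id, sub in qualifying.groupby("protein_id", sort=True):
        pool = sub[sub["db"] == "sprot"]
        if pool.empty:
            pool = sub
        ranked = pool.sort_values(
            ["bitscore", "evalue", "accession"], ascending=[False, True, True]
        )
        best = ranked.iloc[0]
        tied = ranked[
            (ranked["bitscore"] == best["bitscore"]) & (ranked["evalue"] == best["evalue"])
        ]
        ko = _resolve_ko(tied)
        go_raw = best.get("go_terms", "")
        go = frozenset(t for t in str(go_raw).split(";") if t and t != "nan") if pd.notna(go_raw) else frozenset()
        out[str(protein_id)] = TopHitAnnotation(
            protein_id=str(protein_id),
            accession=str(best["accession"]),
            db=str(best["db"]),
            evalue=float(best["evalue"]),
            bitscore=float(best["bitscore"]),
            ko_term=ko,
            go_terms=go,
            is_bacterial=bool(best.get("is_bacterial", False)),
        )
    return out


def _resolve_ko(tied: pd.DataFrame) -> Optional[str]:
    if "ko" not in tied.columns:
        return None
    kos = [str(k) for k in tied["ko"] if pd.notna(k) and str(k) not in ("", "nan")]
    if not kos:
        return None
    counts: Dict[str, int] = {}
    for k in kos:
        counts[k] = counts.get(k, 0) + 1
    best_n = max(counts.values())
    return min(k for k, n in counts.items() if n == best_n)


def build_ko_up_hogs(
    annotations: Mapping[str, TopHitAnnotation],
    proteins: Mapping[str, ProteinRecord],
) -> List[HomologGroup]:
    """Group annotated proteins into KO groups (by shared KO term) and UP
    groups (by shared accession, for top matches without a KO term).

    Singleton KO/UP groups are permitted. ``proteins`` supplies lineage and
    dataset labels for the group metadata.
    """
    by_ko: Dict[str, Set[str]] = {}
    by_acc: Dict[str, Set[str]] = {}
    for pid, ann in annotations.items():
        if ann.ko_term is not None:
            by_ko.setdefault(ann.ko_term, set()).add(pid)
        else:
            by_acc.setdefault(ann.accession, set()).add(pid)

    groups: List[HomologGroup] = []
    for ko_term in sorted(by_ko):
        groups.append(_make_group(f"KO:{ko_term}", KO, ko_term, by_ko[ko_term], proteins))
    for acc in sorted(by_acc):
        groups.append(_make_group(f"UP:{acc}", UP, acc, by_acc[acc], proteins))
    return groups


def _make_group(
    group_id: str,
    category: str,
    anchor: Optional[str],
    members: Set[str],
    proteins: Mapping[str, ProteinRecord],
) -> HomologGroup:
    lineages = frozenset(proteins[m].lineage for m in members)
    datasets = frozenset(proteins[m].dataset_id for m in members)
    return HomologGroup(
        group_id=group_id,
        category=category,
        anchor=anchor,
        member_protein_ids=frozenset(members),
        lineages=lineages,
        dataset_ids=datasets,
    )


def build_similarity_graph(
    hits: pd.DataFrame,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    weight_cap: float = DEFAULT_WEIGHT_CAP,
    restrict_to: Optional[Iterable[str]] = None,
) -> nx.Graph:
    """Undirected similarity graph from BLAST-tabular all-vs-all hits.

    For each ordered pair the best (minimum) E-value is kept; a pair gets an
    edge when its best E-value over available directions is <= cutoff. The
    edge weight is the mean of -log10(best E) per direction (a missing
    direction contributes nothing to the mean); E = 0 maps to ``weight_cap``.
    Self-hits are ignored; malformed rows are skipped with a logged count.
    """
    allowed = set(restrict_to) if restrict_to is not None else None
    best: Dict[Tuple[str, str], float] = {}
    n_bad = 0
    for row in hits.itertuples(index=False):
        try:
            q, s, e = str(row.qseqid), str(row.sseqid), float(row.evalue)
            if e < 0:
                raise ValueError
        except (ValueError, AttributeError):
            n_bad += 1
            continue
        if q == s:
            continue
        if allowed is not None and (q not in allowed or s not in allowed):
            continue
        key = (q, s)
        if key not in best or e < best[key]:
            best[key] = e
    if n_bad:
        log.info("build_similarity_graph: skipped %d malformed rows", n_bad)

    def to_weight(e: float) -> float:
        if e <= 0.0:
            return weight_cap
        return min(weight_cap, -np.log10(e))

    graph = nx.Graph()
    seen = set()
    for (q, s), e_fwd in best.items():
        if (s, q) in seen:
            continue
        seen.add((q, s))
        e_rev = best.get((s, q))
        es = [e_fwd] + ([e_rev] if e_rev is not None else [])
        if min(es) > evalue_cutoff:
            continue
        weight = float(np.mean([to_weight(e) for e in es]))
        graph.add_edge(q, s, weight=weight)
    return graph


@dataclass
class MclResult:
    clusters: List[FrozenSet[str]]
    converged: bool
    n_iterations: int


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 1.2,
    prune: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MclResult:
    """Deterministic Markov clustering.

    Per connected component: add self-loops (weight = max incident edge
    weight), column-normalise, then iterate expansion (matrix square),
    inflation (elementwise power, column renormalise) and pruning (drop
    entries < ``prune``, renormalise) until the largest entrywise change is
    below ``tol`` or ``max_iter`` is reached. Clusters are the connected
    components induced by attractor rows of the limit matrix. Singleton
    clusters are returned (the OM filter discards them later).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    clusters: List[FrozenSet[str]] = []
    converged = True
    iters_max = 0
    for comp in nx.connected_components(graph):
        if len(comp) == 1:
            clusters.append(frozenset(comp))
            continue
        nodes = sorted(comp)
        sub, ok, it = _mcl_component(graph, nodes, inflation, prune, max_iter, tol)
        clusters.extend(sub)
        converged &= ok
        iters_max = max(iters_max, it)
    if not converged:
        log.warning("mcl_cluster: not converged within %d iterations", max_iter)
    clusters.sort(key=lambda c: sorted(c)[0])
    return MclResult(clusters=clusters, converged=converged, n_iterations=iters_max)


def _mcl_component(
    graph: nx.Graph,
    nodes: Sequence[str],
    inflation: float,
    prune: float,
    max_iter: int,
    tol: float,
) -> Tuple[List[FrozenSet[str]], bool, int]:
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    np.fill_diagonal(a, a.max(axis=1))  # self-loop = max incident weight
    m = a / a.sum(axis=0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        m2 = m @ m
        np.power(m2, inflation, out=m2)
        m2 /= m2.sum(axis=0)
        m2[m2 < prune] = 0.0
        colsum = m2.sum(axis=0)
        dead = colsum == 0.0
        if dead.any():  # fully pruned column: park the node on itself
            m2[np.where(dead)[0], np.where(dead)[0]] = 1.0
            colsum = m2.sum(axis=0)
        m2 /= colsum
        delta = np.abs(m2 - m).max()
        m = m2
        if delta < tol:
            converged = True
            break

    eps = max(prune, tol)
    attractors = [i for i in range(len(nodes)) if m[i, i] > eps]
    uf = list(range(len(nodes)))

    def find(x: int) -> int:
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    def union(x: int, y: int) -> None:
        uf[find(x)] = find(y)

    for i in attractors:
        for j in np.nonzero(m[i] > eps)[0]:
            union(int(j), i)
    # nodes not reached by any attractor row: attach to the row holding most
    # of their column mass (degenerate non-converged case)
    attractor_set = set(find(i) for i in attractors)
    for j in range(len(nodes)):
        if find(j) not in attractor_set and attractors:
            union(j, int(np.argmax(m[:, j])))

    by_root: Dict[int, Set[str]] = {}
    for j in range(len(nodes)):
        by_root.setdefault(find(j), set()).add(nodes[j])
    return [frozenset(c) for c in by_root.values()], converged, it


def filter_om_hogs(
    clusters: Iterable[FrozenSet[str]],
    proteins: Mapping[str, ProteinRecord],
    min_datasets: int = 2,
) -> List[HomologGroup]:
    """Assemble OM groups from MCL clusters, retaining only clusters whose
    members come from >= ``min_datasets`` distinct source datasets (singleton
    clusters are thereby discarded)."""
    groups: List[HomologGroup] = []
    idx = 0
    for cluster in sorted(clusters, key=lambda c: sorted(c)[0]):
        datasets = {proteins[m].dataset_id for m in cluster}
        if len(datasets) < min_datasets or len(cluster) < 2:
            continue
        idx += 1
        groups.append(_make_group(f"OM:{idx:05d}", OM, None, set(cluster), proteins))
    return groups


@dataclass
class DelineationResult:
    """Outcome of the full delineation step."""

    groups: List[HomologGroup]
    annotations: Dict[str, TopHitAnnotation]
    unmatched: List[str]  # proteins with no qualifying database hit
    unclustered: List[str]  # unmatched proteins in no retained OM group
    om_clusters_total: int = 0  # all MCL clusters, incl. singletons
    om_clusters_multi: int = 0  # clusters with >= 2 members (OM groups before the dataset filter)

    def by_category(self) -> Dict[str, List[HomologGroup]]:
        out: Dict[str, List[HomologGroup]] = {KO: [], UP: [], OM: []}
        for g in self.groups:
            out[g.category].append(g)
        return out


def delineate(
    proteins: Mapping[str, ProteinRecord],
    tophits: pd.DataFrame,
    allvsall: pd.DataFrame,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    graph_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    inflation: float = 1.2,
    min_datasets: int = 2,
) -> DelineationResult:
    """End-to-end delineation over a protein set: top-hit assignment, KO/UP
    grouping, similarity-graph MCL of the unmatched remainder, OM filtering.
    """
    annotations = {
        pid: ann
        for pid, ann in assign_top_hits(tophits, evalue_cutoff).items()
        if pid in proteins
    }
    matched = set(annotations)
    unmatched = sorted(set(proteins) - matched)
    groups = build_ko_up_hogs(annotations, proteins)

    om_total = om_multi = 0
    if not allvsall.empty and unmatched:
        graph = build_similarity_graph(
            allvsall, evalue_cutoff=graph_cutoff, restrict_to=unmatched
        )
        if graph.number_of_nodes() > 0:
            result = mcl_cluster(graph, inflation=inflation)
            om_total = len(result.clusters)
            om_multi = sum(1 for c in result.clusters if len(c) >= 2)
            groups.extend(filter_om_hogs(result.clusters, proteins, min_datasets))

    clustered = set().union(*(g.member_protein_ids for g in groups)) if groups else set()
    unclustered = sorted(set(unmatched) - clustered)
    return DelineationResult(
        groups=groups,
        annotations=annotations,
        unmatched=unmatched,
        unclustered=unclustered,
        om_clusters_total=om_total,
        om_clusters_multi=om_multi,
    )
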