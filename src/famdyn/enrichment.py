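"""Family-level functional enrichment.

The unit of analysis is the gene family, not the protein: a family is
"annotated" with a GO term or a Pfam domain when any member protein carries
it. GO annotations are propagated to ancestors along is_a edges (true-path
rule) before testing.

Two tests are provided, both against a reference background (typically the
full family catalogue at the root node):

* GO terms: one-sided Fisher's exact test with the elimination procedure —
  terms are visited leaves-first; when a term is significant, its annotated
  families are removed from all strict ancestors before those are tested,
  decorrelating the DAG. Raw elim p-values are reported.
* Pfam domains: one-sided Fisher's exact tests for over- and
  under-representation, Benjamini-Hochberg adjusted per direction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import HomologGroup, TopHitAnnotation

log = logging.getLogger(__name__)

OVER = "over"
UNDER = "under"


class GoDag:
    """Minimal is_a ontology: term ids, names, parent edges, depths.

    Depth is the longest is_a path from a root (roots have depth 0).
    """

    def __init__(self, graph: nx.DiGraph):
        # edges point child -> parent
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph is cyclic")
        self.graph = graph
        self.roots = frozenset(n for n in graph if graph.out_degree(n) == 0)
        for n in graph:
            if n not in self.roots and not nx.descendants(graph, n) & self.roots:
                raise ValueError(f"term {n} cannot reach a root")
        self._ancestors: Dict[str, FrozenSet[str]] = {}
        self.depth: Dict[str, int] = {}
        for n in nx.topological_sort(graph.reverse(copy=False)):
            parents = list(graph.successors(n))
            self.depth[n] = 0 if not parents else 1 + max(self.depth[p] for p in parents)

    @property
    def terms(self) -> Set[str]:
        return set(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def parents(self, term: str) -> Set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> FrozenSet[str]:
        """Strict ancestors (term excluded)."""
        if term not in self._ancestors:
            self._ancestors[term] = frozenset(nx.descendants(self.graph, term))
        return self._ancestors[term]

    def propagate(self, terms: Iterable[str]) -> FrozenSet[str]:
        """Close a term set under ancestry (true-path rule); unknown terms are
        dropped with a warning."""
        out: Set[str] = set()
        for t in terms:
            if t not in self.graph:
                log.warning("GO term %s not in ontology, skipped", t)
                continue
            out.add(t)
            out |= self.ancestors(t)
        return frozenset(out)

    @classmethod
    def from_obo(cls, path_or_handle, include_part_of: bool = False) -> "GoDag":
        """Load from an OBO file; obsolete terms are dropped by the reader.

        Only is_a edges are used unless ``include_part_of`` is set.
        """
        multi = obonet.read_obo(path_or_handle)
        g = nx.DiGraph()
        g.add_nodes_from((n, {"name": d.get("name", n)}) for n, d in multi.nodes(data=True))
        for u, v, key in multi.edges(keys=True):
            if key == "is_a" or (include_part_of and key == "part_of"):
                g.add_edge(u, v)
        return cls(g)

    @classmethod
    def from_edges(
        cls, child_parent: Iterable[Tuple[str, str]], names: Optional[Mapping[str, str]] = None
    ) -> "GoDag":
        g = nx.DiGraph()
        for c, p in child_parent:
            g.add_edge(c, p)
        if names:
            nx.set_node_attributes(g, {t: {"name": n} for t, n in names.items()})
        return cls(g)


def load_go_dag(path) -> GoDag:
    return GoDag.from_obo(path)


@dataclass
class FamilyAnnotation:
    """Per-family GO-term sets (ancestry-closed) and Pfam-domain sets."""

    go: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    pfam: Dict[str, FrozenSet[str]] = field(default_factory=dict)


def annotate_families(
    groups: Iterable[HomologGroup],
    protein_go: Mapping[str, Iterable[str]],
    pfam_table: pd.DataFrame,
    dag: GoDag,
    pfam_cutoff: float = 1e-3,
) -> FamilyAnnotation:
    """Family annotation = union over member proteins, GO propagated to
    ancestors; Pfam rows above the E-value cutoff are excluded.

    ``pfam_table`` needs columns protein_id, domain, evalue.
    """
    pfam_by_protein: Dict[str, Set[str]] = {}
    if not pfam_table.empty:
        ok = pfam_table[pfam_table["evalue"] <= pfam_cutoff]
        for row in ok.itertuples(index=False):
            pfam_by_protein.setdefault(str(row.protein_id), set()).add(str(row.domain))

    ann = FamilyAnnotation()
    for g in groups:
        go_raw: Set[str] = set()
        domains: Set[str] = set()
        for pid in g.member_protein_ids:
            go_raw.update(protein_go.get(pid, ()))
            domains.update(pfam_by_protein.get(pid, ()))
        ann.go[g.group_id] = dag.propagate(go_raw)
        ann.pfam[g.group_id] = frozenset(domains)
    return ann


def fisher_exact_one_sided(k: int, n: int, K: int, M: int, direction: str) -> float:
    """One-sided Fisher's exact / hypergeometric tail.

    A study set of ``n`` families drawn from ``M`` background families of
    which ``K`` are annotated; ``k`` annotated families observed in the study
    set. ``over``: P(X >= k); ``under``: P(X <= k).
    """
    if not (0 <= k <= n <= M and k <= K <= M):
        raise ValueError(f"invalid counts k={k} n={n} K={K} M={M}")
    if direction == OVER:
        return float(hypergeom.sf(k - 1, M, K, n))
    if direction == UNDER:
        return float(hypergeom.cdf(k, M, K, n))
    raise ValueError(f"unknown direction {direction!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    return multipletests(p, method="fdr_bh")[1]


_TABLE_COLS = [
    "term",
    "name",
    "study_count",
    "study_size",
    "background_count",
    "background_size",
    "direction",
    "p_raw",
    "p_adjusted",
    "method",
]


def go_elim_enrichment(
    study: Set[str],
    background: Set[str],
    annotations: FamilyAnnotation,
    dag: GoDag,
    elim_alpha: float = 0.01,
    direction: str = OVER,
) -> pd.DataFrame:
    """GO enrichment with the elimination procedure.

    Terms are processed in decreasing depth (ties broken by term id). Each is
    tested one-sided on its current annotated-family sets; when the raw p is
    below ``elim_alpha``, the term's currently annotated families are removed
    from every strict ancestor's sets before those are tested. With
    ``elim_alpha = 0`` no term is ever eliminated and the result equals the
    classic per-term Fisher test. Raw elim p-values are reported without FDR
    adjustment (the procedure itself accounts for DAG dependence).
    """
    if not study <= background:
        raise ValueError("study families must be a subset of the background")
    fam_terms = annotations.go
    term_fams: Dict[str, Set[str]] = {}
    for fam in background:
        for t in fam_terms.get(fam, ()):
            if t not in dag.graph:
                log.warning("annotation term %s missing from DAG, skipped", t)
                continue
            term_fams.setdefault(t, set()).add(fam)

    eliminated: Dict[str, Set[str]] = {}
    rows = []
    order = sorted(term_fams, key=lambda t: (-dag.depth[t], t))
    m_total = len(background)
    n_study = len(study)
    for term in order:
        fams = term_fams[term] - eliminated.get(term, set())
        big_k = len(fams)
        if big_k == 0:
            continue
        k = len(fams & study)
        p = fisher_exact_one_sided(k, n_study, big_k, m_total, direction)
        rows.append(
            {
                "term": term,
                "name": dag.name(term),
                "study_count": k,
                "study_size": n_study,
                "background_count": big_k,
                "background_size": m_total,
                "direction": direction,
                "p_raw": p,
                "p_adjusted": np.nan,
                "method": "fisher_elim",
            }
        )
        if p < elim_alpha:
            for anc in dag.ancestors(term):
                eliminated.setdefault(anc, set()).update(fams)
    out = pd.DataFrame(rows, columns=_TABLE_COLS)
    return out.sort_values(["p_raw", "term"]).reset_index(drop=True)


def pfam_enrichment(
    study: Set[str],
    background: Set[str],
    annotations: FamilyAnnotation,
    directions: Sequence[str] = (OVER, UNDER),
) -> pd.DataFrame:
    """Per-domain one-sided Fisher tests, BH-adjusted separately per
    direction. Domains with zero background count are not tested."""
    if not study <= background:
        raise ValueError("study families must be a subset of the background")
    dom_fams: Dict[str, Set[str]] = {}
    for fam in background:
        for d in annotations.pfam.get(fam, ()):
            dom_fams.setdefault(d, set()).add(fam)

    m_total = len(background)
    n_study = len(study)
    frames = []
    for direction in directions:
        rows = []
        for dom in sorted(dom_fams):
            fams = dom_fams[dom]
            k = len(fams & study)
            p = fisher_exact_one_sided(k, n_study, len(fams), m_total, direction)
            rows.append(
                {
                    "term": dom,
                    "name": dom,
                    "study_count": k,
                    "study_size": n_study,
                    "background_count": len(fams),
                    "background_size": m_total,
                    "direction": direction,
                    "p_raw": p,
                    "p_adjusted": np.nan,
                    "method": "fisher",
                }
            )
        frame = pd.DataFrame(rows, columns=_TABLE_COLS)
        if not frame.empty:
            frame["p_adjusted"] = bh_adjust(frame["p_raw"].to_numpy())
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_TABLE_COLS)
    return out.sort_values(["direction", "p_adjusted", "term"]).reset_index(drop=True)
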