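"""Phylogeny-aware gene-family classification.

Builds the family x lineage presence matrix and computes the set categories
used throughout the analysis:

* per internal node N: ``node_total`` (families present in at least one
  descendant lineage of N) and ``node_specific`` (families present *only*
  within N's descendants);
* per lineage L: ``L-specific`` (present in exactly {L}) and ``L-absent``
  (present in every analysed lineage except L);
* core sets: families in all lineages including the outgroup, families in all
  ingroup clades regardless of the outgroup, and their difference;
* the exclusive-intersection partition (which lineage subset each family's
  presence pattern equals — the quantity behind UpSet-style bar plots).

All categories are simple row predicates on the boolean matrix, so everything
is vectorised over numpy arrays and checked against exhaustive row scans in
the test suite.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import Phylo

from .types import HomologGroup

DEFAULT_TOPOLOGY = "(P,(A,(E,(D,(B,(C,F))))));"


@dataclass(frozen=True)
class Cladogram:
    """A rooted cladogram with internal nodes auto-numbered N1.. in pre-order.

    ``node_leaves`` maps every node label (internal N1..Nk and every leaf) to
    its descendant-leaf set; for a leaf that set is the leaf itself.
    """

    newick: str
    leaves: Tuple[str, ...]
    internal_nodes: Tuple[str, ...]
    node_leaves: Mapping[str, FrozenSet[str]]
    parent: Mapping[str, Optional[str]]
    children: Mapping[str, Tuple[str, ...]]

    @property
    def root(self) -> str:
        return self.internal_nodes[0]

    def descendants(self, node: str) -> FrozenSet[str]:
        return self.node_leaves[node]


def parse_cladogram(newick: str) -> Cladogram:
    """Parse a rooted Newick string into a :class:`Cladogram`.

    Internal nodes are renamed N1..Nk by pre-order from the root (N1 = root).
    Trees with a single leaf, duplicate leaf labels, unary internal nodes, or
    unnamed leaves are rejected.
    """
    tree = Phylo.read(io.StringIO(newick), "newick")
    clade_leaves = tree.get_terminals()
    if len(clade_leaves) < 2:
        raise ValueError("cladogram must have >= 2 leaves")
    labels = [t.name for t in clade_leaves]
    if any(lab is None for lab in labels):
        raise ValueError("all leaves must be named")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")

    node_leaves: Dict[str, FrozenSet[str]] = {}
    parent: Dict[str, Optional[str]] = {}
    children: Dict[str, Tuple[str, ...]] = {}
    internal: List[str] = []
    counter = 0

    def visit(clade, parent_label: Optional[str]) -> str:
        nonlocal counter
        if clade.is_terminal():
            label = clade.name
            node_leaves[label] = frozenset([label])
            children[label] = ()
        else:
            if len(clade.clades) < 2:
                raise ValueError("internal nodes must have >= 2 children")
            counter += 1
            label = f"N{counter}"
            internal.append(label)
            kid_labels = tuple(visit(c, label) for c in clade.clades)
            children[label] = kid_labels
            node_leaves[label] = frozenset().union(*(node_leaves[k] for k in kid_labels))
        parent[label] = parent_label
        return label

    visit(tree.root, None)
    return Cladogram(
        newick=newick,
        leaves=tuple(labels),
        internal_nodes=tuple(internal),
        node_leaves=node_leaves,
        parent=parent,
        children=children,
    )


def build_presence_matrix(
    groups: Iterable[HomologGroup], lineages: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Boolean family x lineage matrix: True iff the family has >= 1 member
    from that lineage.

    ``lineages`` fixes the column order (defaults to the sorted union of
    lineages observed across groups). A group with an empty lineage set is a
    contract violation and is rejected.
    """
    groups = list(groups)
    for g in groups:
        if not g.lineages:
            raise ValueError(f"group {g.group_id} has an empty lineage set")
    if lineages is None:
        lineages = sorted(set().union(*(g.lineages for g in groups))) if groups else []
    cols = list(lineages)
    data = np.zeros((len(groups), len(cols)), dtype=bool)
    index = []
    col_idx = {c: i for i, c in enumerate(cols)}
    for r, g in enumerate(groups):
        index.append(g.group_id)
        for lin in g.lineages:
            if lin not in col_idx:
                raise ValueError(
                    f"group {g.group_id} carries lineage {lin!r} not in the requested columns"
                )
            data[r, col_idx[lin]] = True
    return pd.DataFrame(data, index=index, columns=cols)


def _check_columns(matrix: pd.DataFrame, tree: Cladogram) -> None:
    extra = set(matrix.columns) - set(tree.leaves)
    if extra:
        raise ValueError(f"matrix lineages absent from the cladogram: {sorted(extra)}")


def node_categories(
    matrix: pd.DataFrame, tree: Cladogram
) -> Dict[str, Tuple[Set[str], Set[str]]]:
    """Per internal node: (node_total, node_specific) family-id sets.

    node_total(N)    = families present in >= 1 leaf descendant from N.
    node_specific(N) = families whose (nonempty) presence set is contained in
                       N's descendant leaves.
    """
    _check_columns(matrix, tree)
    vals = matrix.to_numpy()
    fam_ids = np.asarray(matrix.index)
    out: Dict[str, Tuple[Set[str], Set[str]]] = {}
    col = {c: i for i, c in enumerate(matrix.columns)}
    for node in tree.internal_nodes:
        desc = [col[l] for l in tree.descendants(node) if l in col]
        inside = vals[:, desc].any(axis=1) if desc else np.zeros(len(vals), dtype=bool)
        outside_cols = [i for c, i in col.items() if c not in tree.descendants(node)]
        outside = vals[:, outside_cols].any(axis=1) if outside_cols else np.zeros(len(vals), dtype=bool)
        total = set(fam_ids[inside])
        specific = set(fam_ids[inside & ~outside])
        out[node] = (total, specific)
    return out


def lineage_categories(matrix: pd.DataFrame) -> Dict[str, Tuple[Set[str], Set[str]]]:
    """Per lineage L: (L_specific, L_absent) family-id sets.

    L_specific = presence set exactly {L}; L_absent = presence set exactly
    all analysed lineages minus {L}.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 lineages")
    vals = matrix.to_numpy()
    fam_ids = np.asarray(matrix.index)
    nlin = vals.shape[1]
    rowsum = vals.sum(axis=1)
    out: Dict[str, Tuple[Set[str], Set[str]]] = {}
    for i, lin in enumerate(matrix.columns):
        specific = set(fam_ids[vals[:, i] & (rowsum == 1)])
        absent = set(fam_ids[~vals[:, i] & (rowsum == nlin - 1)])
        out[lin] = (specific, absent)
    return out


def core_sets(
    matrix: pd.DataFrame, symbiont_lineages: Sequence[str], outgroup: str
) -> Tuple[Set[str], Set[str], Set[str]]:
    """(sues_core, sym_core, sym_core_specific).

    sues_core: present in every ingroup clade and the outgroup.
    sym_core: present in every ingroup clade, outgroup free to vary.
    sym_core_specific = sym_core minus sues_core (ingroup-exclusive core).
    """
    missing = (set(symbiont_lineages) | {outgroup}) - set(matrix.columns)
    if missing:
        raise ValueError(f"lineages not in matrix: {sorted(missing)}")
    vals = matrix.to_numpy()
    fam_ids = np.asarray(matrix.index)
    col = {c: i for i, c in enumerate(matrix.columns)}
    sym_idx = [col[l] for l in symbiont_lineages]
    in_all_sym = vals[:, sym_idx].all(axis=1)
    sym_core = set(fam_ids[in_all_sym])
    sues_core = set(fam_ids[in_all_sym & vals[:, col[outgroup]]])
    return sues_core, sym_core, sym_core - sues_core


def exclusive_intersections(
    matrix: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> Dict[FrozenSet[str], Set[str]]:
    """Map each realised lineage subset S to the families whose presence set
    equals S exactly.

    With ``columns`` the matrix is first projected onto those lineages
    (families empty after projection are dropped); otherwise the map is a
    partition of all families.
    """
    sub = matrix if columns is None else matrix.loc[:, list(columns)]
    vals = sub.to_numpy()
    fam_ids = np.asarray(sub.index)
    cols = np.asarray(sub.columns)
    out: Dict[FrozenSet[str], Set[str]] = {}
    for fid, row in zip(fam_ids, vals):
        key = frozenset(cols[row])
        if not key:
            continue
        out.setdefault(key, set()).add(fid)
    return out


@dataclass
class CategoryReport:
    """All classification outputs for one presence matrix + tree."""

    node: Dict[str, Tuple[Set[str], Set[str]]]
    lineage: Dict[str, Tuple[Set[str], Set[str]]]
    sues_core: Set[str]
    sym_core: Set[str]
    sym_core_specific: Set[str]
    intersections: Dict[FrozenSet[str], Set[str]]

    def node_counts(self) -> pd.DataFrame:
        rows = [
            {"node": n, "node_total": len(t), "node_specific": len(s)}
            for n, (t, s) in self.node.items()
        ]
        return pd.DataFrame(rows)

    def lineage_counts(self) -> pd.DataFrame:
        rows = [
            {"lineage": l, "l_specific": len(s), "l_absent": len(a)}
            for l, (s, a) in self.lineage.items()
        ]
        return pd.DataFrame(rows)

    def intersection_counts(self) -> pd.DataFrame:
        rows = [
            {"lineages": "+".join(sorted(k)), "n_families": len(v)}
            for k, v in sorted(self.intersections.items(), key=lambda kv: (-len(kv[1]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows)


def classify(
    matrix: pd.DataFrame,
    tree: Cladogram,
    symbiont_lineages: Optional[Sequence[str]] = None,
    outgroup: str = "P",
) -> CategoryReport:
    """Run the full set algebra and bundle the results."""
    if symbiont_lineages is None:
        symbiont_lineages = [c for c in matrix.columns if c != outgroup]
    sues, sym, sym_spec = core_sets(matrix, symbiont_lineages, outgroup)
    return CategoryReport(
        node=node_categories(matrix, tree),
        lineage=lineage_categories(matrix),
        sues_core=sues,
        sym_core=sym,
        sym_core_specific=sym_spec,
        intersections=exclusive_intersections(matrix),
    )
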