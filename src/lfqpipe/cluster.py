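"""Bidirectional hierarchical clustering with Cluster 3.0-compatible output.

Differentially expressed proteins are median-centred per feature row and then
clustered along both axes with Euclidean distance and complete linkage.  On
incomplete vectors the distance is computed over the positions observed in
both items and rescaled to the full vector length,

    d(u, v) = sqrt( (K / |O|) * sum_{i in O} (u_i − v_i)^2 ),

the convention applied by the Cluster 3.0 program; a pair with no shared
observed position is an error.  Merging is deterministic: among minimum-
distance cluster pairs the lexicographically smallest (older, younger) node-id
pair merges first, and in the leaf ordering the left subtree is the one
containing the lower original item index.  Results can be written as
``.cdt`` / ``.gtr`` / ``.atr`` files loadable in TreeView.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .tables import StudyDesign

__all__ = [
    "Merge",
    "LinkageTree",
    "BiclusterResult",
    "median_center_features",
    "pairwise_distance",
    "complete_linkage",
    "two_cut",
    "cluster_purity",
    "cluster_bidirectional",
    "write_cluster3",
]


class Merge(NamedTuple):
    node_a: int
    node_b: int
    height: float
    new_id: int


@dataclass
class LinkageTree:
    """An agglomerative merge sequence over n leaves (ids 0..n−1)."""

    n_leaves: int
    merges: list[Merge]
    labels: list[str]
    leaf_order: list[int] = field(default_factory=list)

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def leaves_under(self, node: int) -> list[int]:
        children = {m.new_id: (m.node_a, m.node_b) for m in self.merges}
        stack, out = [node], []
        while stack:
            k = stack.pop()
            if k < self.n_leaves:
                out.append(k)
            else:
                a, b = children[k]
                stack.extend((b, a))
        return out


def median_center_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each feature row's median observed value (idempotent)."""
    n_obs = matrix.notna().sum(axis=1)
    empty = n_obs[n_obs == 0]
    if len(empty) > 0:
        raise ValueError(
            f"feature(s) with no observed values cannot be centered: {list(empty.index)}"
        )
    return matrix.sub(matrix.median(axis=1, skipna=True), axis=0)


def pairwise_distance(matrix: pd.DataFrame, axis: str = "columns") -> pd.DataFrame:
    """Missing-rescaled Euclidean distances between rows or columns."""
    if axis == "columns":
        items = matrix.columns
        vals = matrix.to_numpy(dtype=float).T
    elif axis == "rows":
        items = matrix.index
        vals = matrix.to_numpy(dtype=float)
    else:
        raise ValueError("axis must be 'rows' or 'columns'")
    n, k_full = vals.shape
    if n < 2:
        raise ValueError("need at least 2 items to compute distances")
    obs = ~np.isnan(vals)
    dist = np.zeros((n, n))
    bad_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = obs[i] & obs[j]
            k_shared = int(shared.sum())
            if k_shared == 0:
                bad_pairs.append((items[i], items[j]))
                continue
            diff = vals[i, shared] - vals[j, shared]
            dist[i, j] = dist[j, i] = np.sqrt(
                (k_full / k_shared) * float(diff @ diff)
            )
    if bad_pairs:
        raise ValueError(f"item pair(s) share no observed positions: {bad_pairs}")
    return pd.DataFrame(dist, index=items, columns=items)


def complete_linkage(distances: pd.DataFrame | np.ndarray) -> LinkageTree:
    """Deterministic complete-linkage agglomeration of a distance matrix."""
    if isinstance(distances, pd.DataFrame):
        labels = [str(x) for x in distances.index]
        d0 = distances.to_numpy(dtype=float)
    else:
        d0 = np.asarray(distances, dtype=float)
        labels = [str(i) for i in range(len(d0))]
    n = len(d0)
    # active node id -> row in a growing Lance-Williams distance table
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d0[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    merges: list[Merge] = []
    next_id = n
    while len(active) > 1:
        best = min(
            ((dist[(a, b)], (a, b)) for a, b in _pairs(active)),
            key=lambda t: (t[0], t[1]),
        )
        h, (a, b) = best
        for other in active:
            if other in (a, b):
                continue
            key_a = (min(a, other), max(a, other))
            key_b = (min(b, other), max(b, other))
            dist[(other, next_id)] = max(dist[key_a], dist[key_b])
        active = [k for k in active if k not in (a, b)] + [next_id]
        merges.append(Merge(a, b, h, next_id))
        next_id += 1
    tree = LinkageTree(n_leaves=n, merges=merges, labels=labels)
    tree.leaf_order = _dendrogram_order(tree)
    return tree


def _pairs(active: list[int]):
    for i in range(len(active)):
        for j in range(i + 1, len(active)):
            a, b = active[i], active[j]
            yield (a, b) if a < b else (b, a)


def _dendrogram_order(tree: LinkageTree) -> list[int]:
    """Leaf order: the subtree containing the lower original index goes left."""
    if tree.n_leaves == 1:
        return [0]
    children = {m.new_id: (m.node_a, m.node_b) for m in tree.merges}
    min_leaf: dict[int, int] = {}

    def walk(node: int) -> list[int]:
        if node < tree.n_leaves:
            min_leaf[node] = node
            return [node]
        a, b = children[node]
        left, right = walk(a), walk(b)
        if min_leaf[b] < min_leaf[a]:
            left, right = right, left
        min_leaf[node] = min(min_leaf[a], min_leaf[b])
        return left + right

    return walk(tree.merges[-1].new_id)


def two_cut(tree: LinkageTree) -> tuple[list[int], list[int]]:
    """The two clusters obtained by cutting below the final merge."""
    if tree.n_leaves < 2:
        raise ValueError("cannot 2-cut a single-leaf tree")
    last = tree.merges[-1]
    return tree.leaves_under(last.node_a), tree.leaves_under(last.node_b)


def cluster_purity(tree: LinkageTree, group_of_label: dict[str, str]) -> float:
    """Majority-group purity of the 2-cut, over labelled leaves only."""
    total = majority = 0
    for side in two_cut(tree):
        groups = [group_of_label[tree.labels[i]] for i in side
                  if tree.labels[i] in group_of_label]
        if not groups:
            continue
        counts = pd.Series(groups).value_counts()
        majority += int(counts.iloc[0])
        total += len(groups)
    return majority / total if total else float("nan")


@dataclass
class BiclusterResult:
    sample_tree: LinkageTree
    feature_tree: LinkageTree | None
    matrix: pd.DataFrame        # rows and columns permuted to leaf order
    sample_purity: float


def cluster_bidirectional(
    matrix: pd.DataFrame, design: StudyDesign | None = None
) -> BiclusterResult:
    """Cluster both samples (columns) and features (rows) of a log2 matrix.

    The matrix should be restricted to the differentially expressed proteins;
    rows are median-centred here.  With a single feature only the sample tree
    is built.  When a design is given, the majority-group purity of the sample
    tree's 2-cut is reported.
    """
    centered = median_center_features(matrix)
    sample_tree = complete_linkage(pairwise_distance(centered, axis="columns"))
    feature_tree = None
    if len(centered) >= 2:
        feature_tree = complete_linkage(pairwise_distance(centered, axis="rows"))
    row_order = (
        centered.index[feature_tree.leaf_order] if feature_tree else centered.index
    )
    col_order = [centered.columns[i] for i in sample_tree.leaf_order]
    purity = float("nan")
    if design is not None:
        group_of = {
            sid: row["group_label"]
            for sid, row in design.frame.iterrows()
            if row["group_label"]
        }
        purity = cluster_purity(sample_tree, group_of)
    return BiclusterResult(
        sample_tree=sample_tree,
        feature_tree=feature_tree,
        matrix=centered.loc[row_order, col_order],
        sample_purity=purity,
    )


def _tree_lines(tree: LinkageTree, prefix: str) -> list[str]:
    """GTR/ATR lines; the score column is 1 − h/h_max (similarity scale)."""
    h_max = max((m.height for m in tree.merges), default=0.0)
    lines = []
    for k, m in enumerate(tree.merges, start=1):
        def name(node: int) -> str:
            if node < tree.n_leaves:
                return f"{prefix}{node}X"
            return f"NODE{node - tree.n_leaves + 1}X"
        score = 1.0 - (m.height / h_max if h_max > 0 else 0.0)
        lines.append(f"NODE{k}X\t{name(m.node_a)}\t{name(m.node_b)}\t{score:.6f}")
    return lines


def write_cluster3(result: BiclusterResult, basename) -> None:
    """Write ``<basename>.cdt`` (+ ``.gtr``/``.atr``) in Cluster 3.0 format."""
    base = str(basename)
    mat = result.matrix
    gene_id_of = {}
    if result.feature_tree is not None:
        for leaf, label in enumerate(result.feature_tree.labels):
            gene_id_of[label] = f"GENE{leaf}X"
        with open(base + ".gtr", "w") as fh:
            fh.write("\n".join(_tree_lines(result.feature_tree, "GENE")) + "\n")
    else:
        gene_id_of = {label: f"GENE{i}X" for i, label in enumerate(mat.index)}
    arry_id_of = {
        label: f"ARRY{leaf}X"
        for leaf, label in enumerate(result.sample_tree.labels)
    }
    with open(base + ".atr", "w") as fh:
        fh.write("\n".join(_tree_lines(result.sample_tree, "ARRY")) + "\n")
    with open(base + ".cdt", "w") as fh:
        cols = list(mat.columns)
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(cols) + "\n")
        fh.write("AID\t\t\t\t" + "\t".join(arry_id_of[c] for c in cols) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join("1" for _ in cols) + "\n")
        for rid, row in mat.iterrows():
            cells = ["" if np.isnan(v) else f"{v:.6g}" for v in row.to_numpy()]
            fh.write(
                f"{gene_id_of[str(rid)]}\t{rid}\t{rid}\t1\t" + "\t".join(cells) + "\n"
            )
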