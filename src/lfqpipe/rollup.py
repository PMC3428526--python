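"""Protein abundance reconstruction from peptide intensities (LFQ rollup).

For each protein, every pair of samples that shares at least ``min_shared``
observed member peptides contributes one edge to a ratio graph: the edge value
is the median of the peptide-wise log2 intensity differences between the two
samples.  Within each connected component of that graph the per-sample protein
log2 abundances are the least-squares solution of the edge equations
``x_a - x_b = r[a, b]``; the free additive constant of a component is anchored
so that the mean of the solved values equals the mean of the observed
per-sample median peptide log2 intensities, which keeps the output on the
absolute intensity scale of the input.  Samples with no quantifiable evidence
stay missing.

Only peptides unique to the protein group enter the rollup (razor peptides
would also qualify when a razor annotation is available; plain uniqueness is
what the tables carry here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import PeptideQuantTable, ProteinQuantTable

__all__ = [
    "RatioGraph",
    "pairwise_median_ratio",
    "build_ratio_graph",
    "solve_abundances",
    "rollup_protein_table",
]


@dataclass
class RatioGraph:
    """Median log2-ratio edges between samples for one protein."""

    samples: list[str]
    # edge key (i, j) with i < j (positional indices); value r = x_i - x_j
    ratios: dict[tuple[int, int], float]
    support: dict[tuple[int, int], int]

    def ratio(self, a: str, b: str) -> float | None:
        """Signed ratio r[a, b] (antisymmetric); None when there is no edge."""
        i, j = self.samples.index(a), self.samples.index(b)
        if i == j:
            return None
        key, sign = ((i, j), 1.0) if i < j else ((j, i), -1.0)
        r = self.ratios.get(key)
        return None if r is None else sign * r


def pairwise_median_ratio(
    log2_rows: pd.DataFrame, sample_a: str, sample_b: str, min_shared: int = 1
) -> tuple[float | None, int]:
    """Median peptide log2 ratio (a − b) and its support for one sample pair."""
    a = log2_rows[sample_a].to_numpy(dtype=float)
    b = log2_rows[sample_b].to_numpy(dtype=float)
    shared = ~np.isnan(a) & ~np.isnan(b)
    support = int(shared.sum())
    if support < max(min_shared, 1):
        return None, support
    return float(np.median(a[shared] - b[shared])), support


def build_ratio_graph(log2_rows: pd.DataFrame, min_shared: int = 1) -> RatioGraph:
    """All pairwise median-ratio edges for one protein's peptide rows."""
    vals = log2_rows.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    n = vals.shape[1]
    # support matrix and per-pair medians in one broadcast pass
    support = obs.T.astype(int) @ obs.astype(int)
    ratios: dict[tuple[int, int], float] = {}
    supp: dict[tuple[int, int], int] = {}
    min_shared = max(min_shared, 1)
    for i in range(n):
        for j in range(i + 1, n):
            s = int(support[i, j])
            if s < min_shared:
                continue
            shared = obs[:, i] & obs[:, j]
            ratios[(i, j)] = float(np.median(vals[shared, i] - vals[shared, j]))
            supp[(i, j)] = s
    return RatioGraph(samples=list(log2_rows.columns), ratios=ratios, support=supp)


def _components(n: int, edges) -> list[list[int]]:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    comp: dict[int, list[int]] = {}
    for k in range(n):
        comp.setdefault(find(k), []).append(k)
    return list(comp.values())


def solve_abundances(
    log2_rows: pd.DataFrame, min_shared: int = 1, graph: RatioGraph | None = None
) -> pd.Series:
    """Per-sample protein log2 abundance for one protein (NaN = no evidence)."""
    if graph is None:
        graph = build_ratio_graph(log2_rows, min_shared=min_shared)
    vals = log2_rows.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    n = vals.shape[1]
    x = np.full(n, np.nan)
    with np.errstate(all="ignore"):
        col_median = np.array(
            [np.median(vals[obs[:, k], k]) if obs[:, k].any() else np.nan for k in range(n)]
        )
    quantifiable = [k for k in range(n) if obs[:, k].any()]
    for comp in _components(n, graph.ratios.keys()):
        comp = [k for k in comp if k in quantifiable]
        if not comp:
            continue
        if len(comp) == 1:
            x[comp[0]] = col_median[comp[0]]
            continue
        pos = {k: idx for idx, k in enumerate(comp)}
        edges = [(i, j, r) for (i, j), r in graph.ratios.items() if i in pos and j in pos]
        a_mat = np.zeros((len(edges), len(comp)))
        rhs = np.zeros(len(edges))
        for row, (i, j, r) in enumerate(edges):
            a_mat[row, pos[i]] = 1.0
            a_mat[row, pos[j]] = -1.0
            rhs[row] = r
        sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
        sol = sol - sol.mean() + np.mean(col_median[comp])  # anchor the free constant
        for k in comp:
            x[k] = sol[pos[k]]
    return pd.Series(x, index=log2_rows.columns)


def rollup_protein_table(
    peptides: PeptideQuantTable, min_shared: int = 1
) -> ProteinQuantTable:
    """Build a protein-group table from unique member peptides.

    Per-sample MS/MS counts are the sums over member peptides; abundances are
    the solved log2 values mapped back to the linear scale.  A protein group
    is emitted when it has at least one unique member peptide, and is flagged
    as decoy when any member peptide is a decoy.
    """
    unique_mask = peptides.is_unique
    keys = peptides.peptide_keys[unique_mask]
    parents = peptides.protein_groups.loc[keys].map(lambda g: g[0])
    log2_all = np.log2(peptides.intensity.loc[keys])

    rows_ab, rows_ms, ids, entries, rev = [], [], [], [], []
    for pid, members in parents.groupby(parents).groups.items():
        members = list(members)
        x = solve_abundances(log2_all.loc[members], min_shared=min_shared)
        rows_ab.append(np.power(2.0, x.to_numpy()))
        rows_ms.append(peptides.msms.loc[members].sum(axis=0).to_numpy())
        ids.append(pid)
        entries.append((pid,))
        rev.append(bool(peptides.is_reverse.loc[members].any()))

    idx = pd.Index(ids, name="protein_group_id")
    samples = peptides.samples
    return ProteinQuantTable(
        abundance=pd.DataFrame(rows_ab, index=idx, columns=samples),
        msms=pd.DataFrame(
            np.asarray(rows_ms, dtype=int), index=idx, columns=samples
        ),
        entry_names=pd.Series(entries, index=idx, name="entry_names"),
        is_reverse=pd.Series(rev, index=idx, name="is_reverse"),
    )
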