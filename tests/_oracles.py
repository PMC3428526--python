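"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different computational route from the
implementation it validates: exact rational arithmetic for the Fisher test,
recompute-from-scratch agglomeration for complete linkage, the literal
step-up definition for Benjamini-Hochberg, and the textbook Welch formulas.
"""

from fractions import Fraction
from math import comb, sqrt

from scipy import stats


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p via exact rational hypergeometric enumeration."""
    n = a + b + c + d
    k_col = a + c
    n_row = a + b
    if n == 0 or n_row in (0, n) or k_col in (0, n):
        return 1.0
    denom = comb(n, n_row)
    lo = max(0, n_row - (n - k_col))
    hi = min(n_row, k_col)
    probs = {
        x: Fraction(comb(k_col, x) * comb(n - k_col, n_row - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(v for v in probs.values() if v <= p_obs))


def complete_linkage_naive(dist) -> list[tuple[int, int, float, int]]:
    """Complete-linkage merges recomputed from the original matrix each step.

    No Lance-Williams update: every cluster-pair distance is the max over all
    member pairs, taken directly from the input matrix.  Ties resolve to the
    lexicographically smallest (older, younger) node-id pair.
    """
    n = len(dist)
    members = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(members) > 1:
        best = None
        for i in sorted(members):
            for j in sorted(members):
                if i >= j:
                    continue
                d = max(dist[x][y] for x in members[i] for y in members[j])
                key = (d, i, j)
                if best is None or key < best:
                    best = key
        d, i, j = best
        members[next_id] = members.pop(i) + members.pop(j)
        merges.append((i, j, d, next_id))
        next_id += 1
    return merges


def bh_stepup_naive(p_values: list[float]) -> list[float]:
    """Literal step-up definition: adjusted_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [None] * m
    for rank_i in range(m):
        candidates = [
            p_values[order[rank_j]] * m / (rank_j + 1) for rank_j in range(rank_i, m)
        ]
        adjusted[order[rank_i]] = min(1.0, min(candidates))
    return adjusted


def welch_t_p(x: list[float], y: list[float]) -> tuple[float, float]:
    """Textbook Welch statistic, two-sided p (mean(y) − mean(x) orientation)."""
    n1, n2 = len(x), len(y)
    m1, m2 = sum(x) / n1, sum(y) / n2
    v1 = sum((v - m1) ** 2 for v in x) / (n1 - 1)
    v2 = sum((v - m2) ** 2 for v in y) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m2 - m1) / sqrt(se2)
    dof = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, 2.0 * stats.t.sf(abs(t), dof)


def pearson_naive(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)
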