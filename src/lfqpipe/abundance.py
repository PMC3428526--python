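"""Abundance-difference branch: peptide-level ANOVA with t-test refinement.

The pre-selection step fits, per protein, a fixed-effects linear model on the
observed peptide-level log2 abundances of the (at most) ten most abundant
member peptides:

    log2 abundance = intercept + group effect + peptide offset + residual

The fit is robust — iteratively reweighted least squares with Huber weights
(tuning constant 1.345, MAD residual scale) — so single aberrant peptide
measurements do not dominate the protein-level group effect.  Per-sample
median centering upstream absorbs run-level ("experimental") bias, and with a
single measurement per sample and peptide a sample-level random effect is not
separable from the residual, so the model is fitted as fixed effects.  The
group-effect p-values come from a Wald t-test with ``n_obs − n_params``
degrees of freedom and are corrected across proteins by Benjamini-Hochberg.

Pre-selected proteins (adjusted p below ``alpha_pre``) are then refined at the
protein level: a Welch two-sample t-test on the per-sample log2 protein
abundances, with a permutation-based false discovery rate computed SAM-style
by re-deriving all test statistics under permuted group labels.  For the
5-vs-4 design all 125 non-identity label splits are enumerated, which makes
the q-values deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import log2_transform, median_center
from .tables import PeptideQuantTable, ProteinQuantTable, StudyDesign

__all__ = [
    "MEAnovaResult",
    "DifferentialResults",
    "select_top_peptides",
    "fit_me_anova",
    "run_me_anova",
    "bh_adjust",
    "group_ttest",
    "permutation_fdr",
    "run_abundance_branch",
]

HUBER_C = 1.345
MAD_TO_SD = 0.6744897501960817  # Phi^-1(0.75): MAD of a normal = this * sd


@dataclass
class MEAnovaResult:
    """Group effect for one protein from the peptide-level model."""

    protein_group_id: str
    group_effect: float      # log2 difference, group2 − group1
    p_value: float
    n_peptides_used: int
    converged: bool
    p_adjusted: float = math.nan


@dataclass
class DifferentialResults:
    """Per-protein statistics plus decision flags for one branch."""

    branch: str
    table: pd.DataFrame  # indexed by protein_group_id
    group_labels: tuple[str, str]

    @property
    def preselected_ids(self) -> list[str]:
        return list(self.table.index[self.table["preselected"]])

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def select_top_peptides(log2_rows: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k member peptides with the largest median observed log2 intensity.

    Ties at the cutoff are broken lexicographically by peptide key, so the
    selection is deterministic.
    """
    if len(log2_rows) == 0:
        return log2_rows
    med = log2_rows.median(axis=1, skipna=True)
    order = sorted(log2_rows.index, key=lambda key: (-med[key], key))
    return log2_rows.loc[order[:k]]


def _greedy_full_rank(columns: list[np.ndarray]) -> list[int]:
    """Indices of a maximal independent column subset, earliest-first.

    Columns are offered in order (intercept, group, peptide dummies), so the
    group effect keeps priority over peptide dummies: a dummy collinear with
    the columns admitted so far is the one dropped.
    """
    kept: list[int] = []
    basis: list[np.ndarray] = []
    for idx, col in enumerate(columns):
        resid = col.astype(float).copy()
        for b in basis:
            resid -= (resid @ b) * b
        norm = np.linalg.norm(resid)
        if norm > 1e-8 * max(1.0, np.linalg.norm(col)):
            kept.append(idx)
            basis.append(resid / norm)
    return kept


def _huber_irls(
    x_mat: np.ndarray,
    y: np.ndarray,
    robust: bool = True,
    c: float = HUBER_C,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS fit with Huber weights; returns (beta, weights, converged)."""
    beta, *_ = np.linalg.lstsq(x_mat, y, rcond=None)
    w = np.ones(len(y))
    if not robust:
        return beta, w, True
    converged = False
    for _ in range(max_iter):
        r = y - x_mat @ beta
        mad = np.median(np.abs(r - np.median(r)))
        scale = mad / MAD_TO_SD
        if scale <= 0:
            w = np.ones(len(y))
            converged = True
            break
        u = np.abs(r) / scale
        w = np.where(u <= c, 1.0, c / np.maximum(u, 1e-300))
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(x_mat * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    return beta, w, converged


def fit_me_anova(
    log2_rows: pd.DataFrame,
    design: StudyDesign,
    protein_group_id: str = "",
    robust: bool = True,
) -> MEAnovaResult:
    """Fit the intercept + group + peptide model for one protein.

    Only observed cells enter the fit.  Peptide dummy columns that are
    collinear with already-admitted columns are dropped; if the group effect
    itself is inestimable (all observations in one group, or group confounded
    with the admitted peptide structure) the result carries ``converged=False``
    and a missing p-value.
    """
    label1, g1, label2, g2 = design.group_pair()
    samples = [s for s in g1 + g2 if s in log2_rows.columns]
    sub = log2_rows[samples]
    long = sub.stack(future_stack=True).dropna()
    if len(long) == 0:
        return MEAnovaResult(protein_group_id, math.nan, math.nan, 0, False)
    y = long.to_numpy(dtype=float)
    sample_of = long.index.get_level_values(-1)
    pep_of = long.index.get_level_values(0)
    in_g2 = np.isin(sample_of, g2).astype(float)
    if in_g2.all() or not in_g2.any():
        return MEAnovaResult(
            protein_group_id, math.nan, math.nan, len(set(pep_of)), False
        )

    peptide_keys = sorted(set(pep_of))
    cols = [np.ones(len(y)), in_g2]
    names = ["intercept", "group"]
    for key in peptide_keys[1:]:  # first peptide is the reference level
        cols.append((pep_of == key).astype(float))
        names.append(f"pep:{key}")
    kept = _greedy_full_rank(cols)
    if 1 not in kept:
        return MEAnovaResult(
            protein_group_id, math.nan, math.nan, len(peptide_keys), False
        )
    x_mat = np.column_stack([cols[i] for i in kept])
    g_idx = kept.index(1)

    beta, w, converged = _huber_irls(x_mat, y, robust=robust)
    effect = float(beta[g_idx])
    n_obs, n_par = x_mat.shape
    dof = n_obs - n_par
    if dof <= 0:
        return MEAnovaResult(protein_group_id, effect, math.nan, len(peptide_keys), False)
    r = y - x_mat @ beta
    sigma2 = float(np.sum(w * r * r) / dof)
    xtwx = (x_mat * w[:, None]).T @ x_mat
    cov = np.linalg.pinv(xtwx) * sigma2
    se = math.sqrt(max(cov[g_idx, g_idx], 0.0))
    if se == 0.0:
        p = 1.0 if effect == 0.0 else 0.0
        t = 0.0 if effect == 0.0 else math.inf
    else:
        t = effect / se
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return MEAnovaResult(protein_group_id, effect, p, len(peptide_keys), converged)


def run_me_anova(
    peptide_log2: pd.DataFrame,
    parent_of_peptide: pd.Series,
    design: StudyDesign,
    top_k: int = 10,
    robust: bool = True,
) -> pd.DataFrame:
    """Per-protein peptide-level model fits with BH adjustment.

    ``parent_of_peptide`` maps each peptide key to its single protein group.
    """
    records = []
    for pid, members in parent_of_peptide.groupby(parent_of_peptide).groups.items():
        rows = select_top_peptides(peptide_log2.loc[list(members)], k=top_k)
        res = fit_me_anova(rows, design, protein_group_id=str(pid), robust=robust)
        records.append(res)
    out = pd.DataFrame(
        {
            "group_effect": [r.group_effect for r in records],
            "p_meanova": [r.p_value for r in records],
            "n_peptides_used": [r.n_peptides_used for r in records],
            "converged": [r.converged for r in records],
        },
        index=pd.Index([r.protein_group_id for r in records], name="protein_group_id"),
    )
    out["p_adjusted"] = bh_adjust(out["p_meanova"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries are passed through.

    adjusted_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, with m the
    number of non-missing p-values.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(vals)
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out


def _welch_arrays(
    a: np.ndarray, b: np.ndarray, min_per_group: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t of b vs a on NaN-masked matrices.

    Returns (t, p, mean_diff, n1, n2) with mean_diff = mean(b) − mean(a).
    Rows with fewer than ``min_per_group`` observations in either group get
    NaN statistics.  Zero pooled variance resolves to t=0/p=1 on equal means
    and t=±inf/p=0 otherwise.
    """
    n1 = np.sum(~np.isnan(a), axis=1).astype(float)
    n2 = np.sum(~np.isnan(b), axis=1).astype(float)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(a, axis=1)
        m2 = np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
        diff = m2 - m1
        se2 = v1 / n1 + v2 / n2
        t = diff / np.sqrt(se2)
        dof = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        # degenerate zero-variance rows
        zero = se2 == 0
        t = np.where(zero & (diff == 0), 0.0, t)
        p = np.where(zero & (diff == 0), 1.0, p)
        t = np.where(zero & (diff != 0), np.sign(diff) * np.inf, t)
        p = np.where(zero & (diff != 0), 0.0, p)
        invalid = (n1 < min_per_group) | (n2 < min_per_group)
        t = np.where(invalid, np.nan, t)
        p = np.where(invalid, np.nan, p)
        diff = np.where(invalid, np.nan, diff)
    return t, p, diff, n1, n2


def group_ttest(
    protein_log2: pd.DataFrame, design: StudyDesign, min_per_group: int = 2
) -> pd.DataFrame:
    """Welch two-sided t-test per protein row (group2 − group1)."""
    label1, g1, label2, g2 = design.group_pair()
    a = protein_log2[g1].to_numpy(dtype=float)
    b = protein_log2[g2].to_numpy(dtype=float)
    t, p, diff, n1, n2 = _welch_arrays(a, b, min_per_group=min_per_group)
    return pd.DataFrame(
        {
            "t_statistic": t,
            "p_ttest": p,
            "mean_diff": diff,
            "n1": n1.astype(int),
            "n2": n2.astype(int),
        },
        index=protein_log2.index,
    )


def _label_splits(n: int, n1: int, identity: tuple[int, ...], n_perm: int, seed: int):
    """Permuted index splits: enumerated when few, sampled otherwise."""
    total = math.comb(n, n1)
    budget = n_perm + 1 + (1 if 2 * n1 == n else 0)
    if total <= budget:
        ident = frozenset(identity)
        for combo in combinations(range(n), n1):
            cset = frozenset(combo)
            if cset == ident:
                continue
            if 2 * n1 == n and cset == frozenset(range(n)) - ident:
                continue
            yield combo
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            yield tuple(sorted(perm[:n1]))


def permutation_fdr(
    t_observed: pd.Series,
    protein_log2: pd.DataFrame,
    design: StudyDesign,
    n_perm: int = 250,
    seed: int = 0,
    min_per_group: int = 2,
) -> pd.Series:
    """SAM-style permutation q-values for the observed Welch statistics.

    For each protein the raw estimate is the mean number of permuted
    statistics at least as extreme, divided by the observed count at least as
    extreme; the result is made monotone non-increasing in |t| (a q-value
    suffix minimum) and capped at 1.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    label1, g1, label2, g2 = design.group_pair()
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("permutation FDR needs at least 2 samples per group")
    cols = g1 + g2
    mat = protein_log2[cols].to_numpy(dtype=float)
    mat = mat[np.isin(protein_log2.index, t_observed.index)]
    index = protein_log2.index[np.isin(protein_log2.index, t_observed.index)]
    n, n1 = len(cols), len(g1)

    perm_stats = []
    n_used = 0
    for combo in _label_splits(n, n1, tuple(range(n1)), n_perm, seed):
        in_a = np.zeros(n, dtype=bool)
        in_a[list(combo)] = True
        t, *_ = _welch_arrays(
            mat[:, in_a], mat[:, ~in_a], min_per_group=min_per_group
        )
        perm_stats.append(np.abs(t[~np.isnan(t)]))
        n_used += 1
    pooled = np.sort(np.concatenate(perm_stats)) if perm_stats else np.array([])

    t_obs = t_observed.reindex(index).to_numpy(dtype=float)
    abs_obs = np.abs(t_obs)
    valid = ~np.isnan(abs_obs)
    q = np.full(len(abs_obs), np.nan)
    if valid.any() and n_used > 0:
        thr = abs_obs[valid]
        obs_sorted = np.sort(thr)
        n_obs_ge = len(thr) - np.searchsorted(obs_sorted, thr, side="left")
        n_perm_ge = (len(pooled) - np.searchsorted(pooled, thr, side="left")) / n_used
        raw = np.where(n_obs_ge > 0, n_perm_ge / np.maximum(n_obs_ge, 1), np.nan)
        # monotone non-increasing in |t|: suffix minimum in descending order
        order = np.argsort(-thr, kind="stable")
        mono = np.minimum.accumulate(raw[order][::-1])[::-1]
        qv = np.empty(len(thr))
        qv[order] = np.minimum(mono, 1.0)
        q[valid] = qv
    return pd.Series(q, index=index, name="q")


def run_abundance_branch(
    peptides: PeptideQuantTable,
    proteins: ProteinQuantTable,
    design: StudyDesign,
    top_k: int = 10,
    alpha_pre: float = 0.05,
    alpha_refine: float = 0.05,
    fdr: float = 0.05,
    n_perm: int = 250,
    seed: int = 0,
    robust: bool = True,
) -> DifferentialResults:
    """Peptide-level pre-selection followed by protein-level refinement.

    ``peptides`` should already be filtered (unique, forward, sufficiently
    observed); intensities are log2 transformed and median centred here.
    Proteins with adjusted model p below ``alpha_pre`` form the pre-selection;
    of those, proteins whose protein-level t-test has p < ``alpha_refine`` and
    permutation q ≤ ``fdr`` form the refined (selected) set.
    """
    label1, _, label2, _ = design.group_pair()
    lam = median_center(log2_transform(peptides.intensity, axis_name="peptide"))
    unique = peptides.is_unique
    parents = peptides.protein_groups[unique].map(lambda g: g[0])
    me = run_me_anova(lam.values.loc[parents.index], parents, design,
                      top_k=top_k, robust=robust)

    table = me.copy()
    table["preselected"] = table["p_adjusted"] < alpha_pre
    pre_ids = [pid for pid in table.index[table["preselected"]]
               if pid in proteins.protein_group_ids]

    table[["t_statistic", "p_ttest", "mean_diff"]] = np.nan
    table[["n1", "n2"]] = 0
    table["q"] = np.nan
    table["selected"] = False
    if pre_ids:
        prot_log2 = np.log2(proteins.abundance.loc[pre_ids])
        tt = group_ttest(prot_log2, design)
        q = permutation_fdr(tt["t_statistic"], prot_log2, design,
                            n_perm=n_perm, seed=seed)
        table.loc[pre_ids, ["t_statistic", "p_ttest", "mean_diff", "n1", "n2"]] = (
            tt[["t_statistic", "p_ttest", "mean_diff", "n1", "n2"]].to_numpy()
        )
        table.loc[pre_ids, "q"] = q.to_numpy()
        sel = (tt["p_ttest"] < alpha_refine) & (q <= fdr)
        table.loc[pre_ids, "selected"] = sel.fillna(False).to_numpy()
    return DifferentialResults(
        branch="abundance", table=table, group_labels=(label1, label2)
    )
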