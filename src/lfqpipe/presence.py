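"""Presence/absence branch: Fisher test on spectral counts plus imputation.

Proteins expressed in (mainly) one biological group produce invalid or
powerless abundance tests because their intensities are missing in the other
group.  This branch instead tests, per protein, the 2×2 table of summed MS/MS
(spectral) counts in each group against the remaining spectral-count library::

    [[ SpC_A,          SpC_B         ],
     [ Tot_A − SpC_A,  Tot_B − SpC_B ]]

with a two-sided Fisher exact p-value obtained by hypergeometric enumeration.
An alternative ``detection`` mode tabulates the number of samples per group in
which the protein was detected at all.

Because missingness here is missing-not-at-random (low-abundance features drop
below the detection limit), Fisher-significant proteins are consolidated by a
t-test on *imputed* log2 abundances: each missing cell is drawn from a normal
distribution centred ``downshift`` observed standard deviations below the
sample's observed mean, with width ``width`` times the observed standard
deviation (the downshifted normal standard in label-free proteomics,
defaults 1.8 and 0.3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .abundance import DifferentialResults, group_ttest, permutation_fdr
from .preprocess import drop_reverse_proteins
from .tables import ProteinQuantTable, StudyDesign

__all__ = [
    "FisherResult",
    "ImputationSpec",
    "fisher_two_sided",
    "fisher_presence",
    "impute_downshifted_normal",
    "run_presence_branch",
    "branch_overlap",
    "OverlapReport",
]


@dataclass
class FisherResult:
    protein_group_id: str
    counts: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    direction: str  # group label with the count excess, or "" on a tie
    valid: bool


@dataclass(frozen=True)
class ImputationSpec:
    """Downshifted-normal imputation parameters (per-sample statistics)."""

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.downshift < 0:
            raise ValueError("downshift must be non-negative")


def _hypergeom_pmf(support: np.ndarray, n_pop: int, k_col: int, n_row: int) -> np.ndarray:
    """Hypergeometric pmf over ``support``, via log binomial coefficients."""
    def ln_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    logp = (
        ln_comb(k_col, support)
        + ln_comb(n_pop - k_col, n_row - support)
        - ln_comb(n_pop, n_row)
    )
    return np.exp(logp)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Conditions on the margins and enumerates the hypergeometric support,
    summing the probabilities of all tables no more probable than the observed
    one (with the customary 1+1e-7 relative tolerance for ties).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n_pop = a + b + c + d
    k_col = a + c          # first-column margin
    n_row = a + b          # first-row margin
    if n_pop == 0 or n_row == 0 or n_row == n_pop or k_col == 0 or k_col == n_pop:
        return 1.0
    support = np.arange(max(0, n_row - (n_pop - k_col)), min(n_row, k_col) + 1)
    pmf = _hypergeom_pmf(support, n_pop, k_col, n_row)
    p_obs = pmf[support == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def fisher_presence(
    proteins: ProteinQuantTable,
    design: StudyDesign,
    alpha: float = 0.05,
    mode: str = "counts",
) -> pd.DataFrame:
    """Per-protein 2×2 Fisher exact test on spectral counts.

    ``mode="counts"`` (default) compares summed MS/MS counts per group against
    the remaining library totals; ``mode="detection"`` compares the number of
    samples with/without any detection per group.  Decoy rows must already be
    removed.  Proteins with no counts in either group get p = 1 and are
    flagged invalid.
    """
    label1, g1, label2, g2 = design.group_pair()
    if mode not in ("counts", "detection"):
        raise ValueError(f"unknown fisher mode {mode!r}")
    if mode == "counts":
        spc_a = proteins.msms[g1].sum(axis=1).to_numpy()
        spc_b = proteins.msms[g2].sum(axis=1).to_numpy()
        tot_a, tot_b = int(spc_a.sum()), int(spc_b.sum())
        rest_a = tot_a - spc_a
        rest_b = tot_b - spc_b
    else:
        det = proteins.msms > 0
        spc_a = det[g1].sum(axis=1).to_numpy()
        spc_b = det[g2].sum(axis=1).to_numpy()
        rest_a = len(g1) - spc_a
        rest_b = len(g2) - spc_b

    p = np.ones(len(spc_a))
    valid = (spc_a + spc_b) > 0
    for i in np.flatnonzero(valid):
        p[i] = fisher_two_sided(
            int(spc_a[i]), int(spc_b[i]), int(rest_a[i]), int(rest_b[i])
        )
    denom_a = spc_a + rest_a
    denom_b = spc_b + rest_b
    with np.errstate(all="ignore"):
        rate_a = np.where(denom_a > 0, spc_a / np.maximum(denom_a, 1), 0.0)
        rate_b = np.where(denom_b > 0, spc_b / np.maximum(denom_b, 1), 0.0)
    direction = np.where(rate_a > rate_b, label1, np.where(rate_b > rate_a, label2, ""))
    return pd.DataFrame(
        {
            "spc_1": spc_a.astype(int),
            "spc_2": spc_b.astype(int),
            "rest_1": rest_a.astype(int),
            "rest_2": rest_b.astype(int),
            "fisher_p": p,
            "direction": direction,
            "valid_test": valid,
            "fisher_hit": valid & (p < alpha),
        },
        index=proteins.protein_group_ids,
    )


def impute_downshifted_normal(
    protein_log2: pd.DataFrame, spec: ImputationSpec
) -> pd.DataFrame:
    """Replace missing log2 cells with downshifted-normal draws.

    Per sample ``s`` with observed mean ``m_s`` and standard deviation
    ``d_s``, each missing cell is drawn independently from
    ``Normal(m_s − downshift·d_s, (width·d_s)^2)``.  Observed cells are never
    modified.  Cells are drawn in row-major order (protein, then sample) from
    a generator seeded with ``spec.seed``, so the completion is reproducible.
    """
    vals = protein_log2.to_numpy(dtype=float).copy()
    missing = np.isnan(vals)
    if not missing.any():
        return protein_log2.copy()
    n_obs = (~missing).sum(axis=0)
    too_few = np.flatnonzero(n_obs < 2)
    if len(too_few) > 0:
        names = [protein_log2.columns[i] for i in too_few]
        raise ValueError(f"sample(s) {names} have fewer than 2 observed values")
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=1)
    rng = np.random.default_rng(spec.seed)
    flat = np.flatnonzero(missing.ravel(order="C"))
    draws = rng.standard_normal(flat.size)
    col = flat % vals.shape[1]
    vals.ravel(order="C")[flat] = (
        mean[col] - spec.downshift * sd[col] + spec.width * sd[col] * draws
    )
    return pd.DataFrame(vals, index=protein_log2.index, columns=protein_log2.columns)


def run_presence_branch(
    proteins: ProteinQuantTable,
    design: StudyDesign,
    spec: ImputationSpec | None = None,
    alpha_fisher: float = 0.05,
    alpha_refine: float = 0.05,
    fdr: float = 0.05,
    n_perm: int = 250,
    seed: int = 0,
    mode: str = "counts",
) -> DifferentialResults:
    """Fisher pre-selection consolidated by a t-test on imputed abundances.

    Decoy protein groups are removed first.  The downshifted-normal imputation
    is applied to the full log2 abundance matrix (per-sample statistics over
    all proteins), then only Fisher-significant rows are tested, with the same
    Welch t + permutation-FDR machinery as the abundance branch.
    """
    spec = spec or ImputationSpec(seed=seed)
    label1, g1, label2, g2 = design.group_pair()
    fwd = drop_reverse_proteins(proteins) if proteins.is_reverse.any() else proteins
    table = fisher_presence(fwd, design, alpha=alpha_fisher, mode=mode)
    table = table.rename(columns={"fisher_hit": "preselected"})

    table[["t_statistic", "p_ttest", "mean_diff"]] = np.nan
    table["q"] = np.nan
    table["selected"] = False
    hits = list(table.index[table["preselected"]])
    if hits:
        exp = g1 + g2
        log2_all = np.log2(fwd.abundance[exp])
        imputed = impute_downshifted_normal(log2_all, spec)
        sub = imputed.loc[hits]
        tt = group_ttest(sub, design)
        q = permutation_fdr(tt["t_statistic"], sub, design, n_perm=n_perm, seed=seed)
        table.loc[hits, ["t_statistic", "p_ttest", "mean_diff"]] = (
            tt[["t_statistic", "p_ttest", "mean_diff"]].to_numpy()
        )
        table.loc[hits, "q"] = q.to_numpy()
        sel = (tt["p_ttest"] < alpha_refine) & (q <= fdr)
        table.loc[hits, "selected"] = sel.fillna(False).to_numpy()
    return DifferentialResults(
        branch="presence", table=table, group_labels=(label1, label2)
    )


@dataclass
class OverlapReport:
    """Cross-branch agreement of the selected protein sets."""

    shared: list[str]
    only_abundance: list[str]
    only_presence: list[str]
    concordant: list[str]   # shared proteins with the same regulation direction
    discordant: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in self.shared:
            rows.append((pid, "shared", pid in self.concordant))
        for pid in self.only_abundance:
            rows.append((pid, "abundance_only", None))
        for pid in self.only_presence:
            rows.append((pid, "presence_only", None))
        return pd.DataFrame(
            rows, columns=["protein_group_id", "membership", "concordant"]
        ).set_index("protein_group_id")


def branch_overlap(
    results_abundance: DifferentialResults,
    results_presence: DifferentialResults,
) -> OverlapReport:
    """Intersection, exclusives and direction concordance of the two branches.

    A shared protein is concordant when the sign of its abundance-branch mean
    difference points to the same group as the presence-branch count excess.
    """
    set_a = set(results_abundance.selected_ids)
    set_p = set(results_presence.selected_ids)
    shared = sorted(set_a & set_p)
    label1, label2 = results_presence.group_labels
    concordant, discordant = [], []
    for pid in shared:
        diff = results_abundance.table.loc[pid, "mean_diff"]
        direction = results_presence.table.loc[pid, "direction"]
        if not isinstance(direction, str) or direction == "" or math.isnan(diff):
            discordant.append(pid)
            continue
        toward = label2 if diff > 0 else label1
        (concordant if toward == direction else discordant).append(pid)
    return OverlapReport(
        shared=shared,
        only_abundance=sorted(set_a - set_p),
        only_presence=sorted(set_p - set_a),
        concordant=concordant,
        discordant=discordant,
    )
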