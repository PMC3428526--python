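"""Peptide-level robust ANOVA, BH adjustment, Welch t and permutation FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from lfqpipe import (
    SimulationConfig,
    bh_adjust,
    filter_peptides,
    generate_dataset,
    group_ttest,
    permutation_fdr,
    run_abundance_branch,
    select_top_peptides,
)
from lfqpipe.abundance import fit_me_anova

from conftest import make_design  # noqa: F401 - used via design fixtures below
from _oracles import bh_stepup_naive, welch_t_p


def _pep_rows(values, samples, keys=None):
    keys = keys or [f"p{i}" for i in range(len(values))]
    return pd.DataFrame(
        values, index=pd.Index(keys, name="peptide_key"), columns=samples
    ).astype(float)


class TestSelectTopPeptides:
    def test_fewer_than_k_returns_all(self):
        rows = _pep_rows(np.arange(9.0).reshape(3, 3) + 1, ["a", "b", "c"])
        assert len(select_top_peptides(rows, k=10)) == 3

    def test_exactly_k_largest_medians(self):
        vals = [[float(i)] * 3 for i in range(12)]
        rows = _pep_rows(vals, ["a", "b", "c"])
        top = select_top_peptides(rows, k=10)
        assert len(top) == 10
        assert set(top.index) == {f"p{i}" for i in range(2, 12)}

    def test_tie_broken_lexicographically(self):
        rows = _pep_rows(
            [[5.0, 5.0], [5.0, 5.0], [9.0, 9.0]], ["a", "b"], keys=["zzz", "aaa", "top"]
        )
        top = select_top_peptides(rows, k=2)
        assert list(top.index) == ["top", "aaa"]


class TestFitMeAnova:
    def test_identical_groups_zero_effect(self, design_5v4, exp_samples):
        rows = _pep_rows([[7.0] * 9, [9.0] * 9], exp_samples)
        res = fit_me_anova(rows, design_5v4)
        assert res.group_effect == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=0.05)
        assert res.converged

    def test_single_peptide_ols_matches_pooled_ttest(self, design_5v4, exp_samples):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, 9)
        rows = _pep_rows([vals], exp_samples)
        res = fit_me_anova(rows, design_5v4, robust=False)
        t_ref, p_ref = stats.ttest_ind(vals[5:], vals[:5], equal_var=True)
        assert res.p_value == pytest.approx(p_ref, rel=1e-10)
        assert res.group_effect == pytest.approx(np.mean(vals[5:]) - np.mean(vals[:5]))

    def test_additive_peptide_offsets_exact_group_effect(self, design_5v4, exp_samples):
        base = np.array([0.0] * 5 + [1.0] * 4)  # group shift of exactly 1
        rows = _pep_rows([10.0 + base, 12.0 + base], exp_samples)
        res = fit_me_anova(rows, design_5v4)
        assert res.group_effect == pytest.approx(1.0, abs=1e-12)

    def test_group_only_in_one_side_inestimable(self, design_5v4, exp_samples):
        vals = [[1.0] * 5 + [np.nan] * 4]
        res = fit_me_anova(_pep_rows(vals, exp_samples), design_5v4)
        assert not res.converged and np.isnan(res.p_value)

    def test_robust_fit_matches_statsmodels_rlm(self, design_5v4, exp_samples):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        rows = _pep_rows(rng.normal(20, 1, size=(3, 9)), exp_samples)
        rows.iloc[0, 0] += 5.0  # outlier for the robust weighting to shrink
        res = fit_me_anova(rows, design_5v4)
        long = rows.stack().reset_index()
        long.columns = ["pep", "sample", "y"]
        x = pd.get_dummies(long[["pep"]], drop_first=True).astype(float)
        x.insert(0, "group", long["sample"].isin(exp_samples[5:]).astype(float))
        x = sm.add_constant(x)
        fit = sm.RLM(long["y"], x, M=sm.robust.norms.HuberT(t=1.345)).fit()
        # scale estimators differ in detail; the fits must agree closely and
        # the robust estimate must sit nearer the reference than plain OLS does
        ols = fit_me_anova(rows, design_5v4, robust=False)
        assert res.group_effect == pytest.approx(fit.params["group"], abs=0.02)
        assert abs(res.group_effect - fit.params["group"]) < abs(
            ols.group_effect - fit.params["group"]
        )


class TestBHAdjust:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_missing_excluded_from_m(self):
        adj = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], bh_adjust([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        ps=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_matches_stepup_definition_and_monotone(self, ps):
        mine = bh_adjust(ps)
        ref = bh_stepup_naive(ps)
        assert np.allclose(mine, ref, atol=1e-12)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(np.asarray(mine)[order]) >= -1e-12)


class TestGroupTtest:
    def _matrix(self, rows, exp_samples):
        return pd.DataFrame(
            rows, index=pd.Index([f"P{i}" for i in range(len(rows))], name="protein_group_id"),
            columns=exp_samples,
        ).astype(float)

    def test_equal_groups_give_t0_p1(self, design_5v4, exp_samples):
        m = self._matrix([[3.0] * 9], exp_samples)
        res = group_ttest(m, design_5v4)
        assert res.loc["P0", "t_statistic"] == 0.0
        assert res.loc["P0", "p_ttest"] == 1.0

    def test_separated_groups_tiny_p(self, design_5v4, exp_samples):
        rng = np.random.default_rng(2)
        vals = np.array([0.0] * 5 + [1.0] * 4) + rng.normal(0, 1e-6, 9)
        res = group_ttest(self._matrix([vals], exp_samples), design_5v4)
        assert res.loc["P0", "p_ttest"] < 1e-6
        t_ref, p_ref = welch_t_p(list(vals[:5]), list(vals[5:]))
        assert res.loc["P0", "t_statistic"] == pytest.approx(t_ref)
        assert res.loc["P0", "p_ttest"] == pytest.approx(p_ref)

    def test_label_swap_negates_t_keeps_p(self, design_5v4, exp_samples):
        rng = np.random.default_rng(4)
        m = self._matrix(rng.normal(0, 1, size=(20, 9)), exp_samples)
        res = group_ttest(m, design_5v4)
        # reverse the group order: the ER- block becomes group 1
        frame = design_5v4.frame.copy()
        frame["order_index"] = [8, 7, 6, 5, 4, 3, 2, 1, 0]
        res2 = group_ttest(m, type(design_5v4)(frame))
        assert np.allclose(res["t_statistic"], -res2["t_statistic"])
        assert np.allclose(res["mean_diff"], -res2["mean_diff"])
        assert np.allclose(res["p_ttest"], res2["p_ttest"])

    def test_too_few_observations_missing(self, design_5v4, exp_samples):
        vals = [[1.0, np.nan, np.nan, np.nan, np.nan, 2.0, 2.5, 2.0, 2.2]]
        res = group_ttest(self._matrix(vals, exp_samples), design_5v4)
        assert np.isnan(res.loc["P0", "p_ttest"])


class TestPermutationFdr:
    def _null_matrix(self, n_prot, exp_samples, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(0, 1, size=(n_prot, 9)),
            index=pd.Index([f"P{i}" for i in range(n_prot)], name="protein_group_id"),
            columns=exp_samples,
        )

    def test_determinism_same_seed(self, design_5v4, exp_samples):
        m = self._null_matrix(50, exp_samples, 8)
        tt = group_ttest(m, design_5v4)
        q1 = permutation_fdr(tt["t_statistic"], m, design_5v4, seed=1)
        q2 = permutation_fdr(tt["t_statistic"], m, design_5v4, seed=1)
        pd.testing.assert_series_equal(q1, q2)

    def test_extreme_protein_gets_q_zero(self, design_5v4, exp_samples):
        m = self._null_matrix(30, exp_samples, 8) * 0.01
        m.iloc[0] = [0.0] * 5 + [50.0] * 4  # beyond anything permutable
        tt = group_ttest(m, design_5v4)
        q = permutation_fdr(tt["t_statistic"], m, design_5v4, seed=1)
        assert q.iloc[0] == 0.0

    def test_null_data_median_q_at_least_half(self, design_5v4, exp_samples):
        m = self._null_matrix(1000, exp_samples, 12)
        tt = group_ttest(m, design_5v4)
        q = permutation_fdr(tt["t_statistic"], m, design_5v4, seed=3)
        assert float(np.median(q)) >= 0.5

    def test_q_monotone_in_abs_t(self, design_5v4, exp_samples):
        m = self._null_matrix(100, exp_samples, 5)
        tt = group_ttest(m, design_5v4)
        q = permutation_fdr(tt["t_statistic"], m, design_5v4, seed=5)
        order = tt["t_statistic"].abs().sort_values(ascending=False).index
        assert np.all(np.diff(q.loc[order]) >= -1e-12)

    def test_tiny_n_perm_rejected(self, design_5v4, exp_samples):
        m = self._null_matrix(10, exp_samples, 5)
        tt = group_ttest(m, design_5v4)
        with pytest.raises(ValueError):
            permutation_fdr(tt["t_statistic"], m, design_5v4, n_perm=5)


class TestRunAbundanceBranch:
    def test_refined_nested_in_preselected_and_stats_reported(self):
        data = generate_dataset(SimulationConfig(n_proteins=60, seed=17))
        flt, _ = filter_peptides(data.peptides, data.design)
        res = run_abundance_branch(flt, data.proteins, data.design, seed=17)
        assert set(res.selected_ids) <= set(res.preselected_ids)
        assert {"group_effect", "p_meanova", "p_adjusted", "t_statistic",
                "p_ttest", "q", "preselected", "selected"} <= set(res.table.columns)
        assert (res.table["n_peptides_used"].loc[res.table["converged"]] <= 10).all()

    def test_column_permutation_with_labels_invariant(self):
        data = generate_dataset(SimulationConfig(n_proteins=30, seed=23))
        flt, _ = filter_peptides(data.peptides, data.design)
        res1 = run_abundance_branch(flt, data.proteins, data.design, seed=23)
        # permute sample columns; the design carries the labels, so nothing changes
        perm = list(data.peptides.samples)[::-1]
        flt_perm = type(flt)(
            intensity=flt.intensity[perm], msms=flt.msms[perm],
            protein_groups=flt.protein_groups, is_reverse=flt.is_reverse,
        )
        prot_perm = type(data.proteins)(
            abundance=data.proteins.abundance[perm], msms=data.proteins.msms[perm],
            entry_names=data.proteins.entry_names, is_reverse=data.proteins.is_reverse,
        )
        res2 = run_abundance_branch(flt_perm, prot_perm, data.design, seed=23)
        pd.testing.assert_frame_equal(res1.table, res2.table)
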