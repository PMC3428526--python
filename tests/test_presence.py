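"""Fisher presence test, downshifted-normal imputation and branch overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lfqpipe import (
    ImputationSpec,
    SimulationConfig,
    branch_overlap,
    filter_peptides,
    fisher_presence,
    fisher_two_sided,
    generate_dataset,
    impute_downshifted_normal,
    run_abundance_branch,
    run_presence_branch,
)

from conftest import make_design, make_proteins
from _oracles import fisher_two_sided_exact


class TestFisherTwoSided:
    def test_balanced_table_p_one(self):
        assert fisher_two_sided(5, 5, 95, 95) == pytest.approx(1.0)

    def test_example_matches_exact_enumeration(self):
        mine = fisher_two_sided(5, 0, 95, 100)
        assert mine == pytest.approx(fisher_two_sided_exact(5, 0, 95, 100), abs=1e-12)

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact

        for table in [(5, 0, 95, 100), (2, 8, 10, 4), (1, 1, 1, 1), (0, 7, 12, 3)]:
            a, b, c, d = table
            ref = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert fisher_two_sided(a, b, c, d) == pytest.approx(ref, abs=1e-12)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_column_swap_symmetry_and_exactness(self, a, b, c, d):
        p = fisher_two_sided(a, b, c, d)
        assert p == pytest.approx(fisher_two_sided(b, a, d, c), abs=1e-12)
        assert p == pytest.approx(fisher_two_sided_exact(a, b, c, d), abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_doubling_counts_never_raises_p(self):
        for a in range(0, 8):
            for b in range(0, 8):
                base = fisher_two_sided(a, b, 20 - a, 20 - b)
                doubled = fisher_two_sided(2 * a, 2 * b, 40 - 2 * a, 40 - 2 * b)
                assert doubled <= base + 1e-12

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided(-1, 0, 1, 1)


class TestFisherPresence:
    def _proteins(self, msms_rows, exp_samples):
        idx = pd.Index([f"P{i}" for i in range(len(msms_rows))], name="protein_group_id")
        msms = pd.DataFrame(msms_rows, index=idx, columns=exp_samples)
        ab = msms.where(msms > 0).astype(float)
        return make_proteins(ab, msms=msms)

    def test_one_group_only_protein_flagged(self, design_5v4, exp_samples):
        rows = [[40, 40, 40, 40, 40, 0, 0, 0, 0]] + [[5] * 9] * 20
        res = fisher_presence(self._proteins(rows, exp_samples), design_5v4)
        assert bool(res.loc["P0", "fisher_hit"])
        assert res.loc["P0", "direction"] == "ER+"

    def test_zero_count_protein_invalid(self, design_5v4, exp_samples):
        rows = [[0] * 9, [5] * 9]
        res = fisher_presence(self._proteins(rows, exp_samples), design_5v4)
        assert res.loc["P0", "fisher_p"] == 1.0
        assert not bool(res.loc["P0", "valid_test"])

    def test_detection_mode_uses_sample_counts(self, design_5v4, exp_samples):
        rows = [[9, 8, 9, 7, 9, 0, 0, 0, 0], [5] * 9]
        res = fisher_presence(
            self._proteins(rows, exp_samples), design_5v4, mode="detection"
        )
        assert res.loc["P0", "spc_1"] == 5 and res.loc["P0", "spc_2"] == 0
        assert res.loc["P0", "fisher_p"] == pytest.approx(
            fisher_two_sided_exact(5, 0, 0, 4), abs=1e-12
        )


class TestImputation:
    def _matrix(self, n_prot, exp_samples, seed, missing_frac=0.3):
        rng = np.random.default_rng(seed)
        vals = rng.normal(25, 2, size=(n_prot, len(exp_samples)))
        vals[rng.random(vals.shape) < missing_frac] = np.nan
        return pd.DataFrame(
            vals,
            index=pd.Index([f"P{i}" for i in range(n_prot)], name="protein_group_id"),
            columns=exp_samples,
        )

    def test_complete_matrix_returned_unchanged(self, exp_samples):
        m = self._matrix(20, exp_samples, 1, missing_frac=0.0)
        out = impute_downshifted_normal(m, ImputationSpec(seed=123))
        pd.testing.assert_frame_equal(out, m)

    def test_observed_cells_untouched_and_deterministic(self, exp_samples):
        m = self._matrix(50, exp_samples, 2)
        out1 = impute_downshifted_normal(m, ImputationSpec(seed=7))
        out2 = impute_downshifted_normal(m, ImputationSpec(seed=7))
        pd.testing.assert_frame_equal(out1, out2)
        obs = m.notna()
        pd.testing.assert_frame_equal(out1[obs], m[obs])
        assert not out1.isna().any().any()

    def test_large_sample_moments_match_spec(self):
        # one sample, 2e5 rows, ~half missing: imputed cells follow
        # Normal(m - 1.8 d, (0.3 d)^2) within tight sampling error
        rng = np.random.default_rng(3)
        observed = rng.normal(25, 2, size=100_000)
        vals = np.concatenate([observed, np.full(100_000, np.nan)])
        rng.shuffle(vals)
        m = pd.DataFrame({"S01": vals, "S02": rng.normal(25, 2, size=200_000)})
        out = impute_downshifted_normal(m, ImputationSpec(seed=11))
        mean_s = np.nanmean(m["S01"])
        sd_s = np.nanstd(m["S01"], ddof=1)
        imputed = out["S01"][m["S01"].isna()]
        assert abs(imputed.mean() - (mean_s - 1.8 * sd_s)) < 0.02 * sd_s
        assert abs(imputed.std(ddof=1) - 0.3 * sd_s) < 0.02 * 0.3 * sd_s

    def test_sample_with_one_observation_rejected(self):
        m = pd.DataFrame({"S01": [1.0, np.nan, np.nan], "S02": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="S01"):
            impute_downshifted_normal(m, ImputationSpec(seed=1))


class TestRunPresenceBranch:
    def test_extreme_separation_protein_consolidated(self, design_5v4, exp_samples):
        rng = np.random.default_rng(6)
        n = 40
        idx = pd.Index([f"P{i}" for i in range(n)], name="protein_group_id")
        ab = pd.DataFrame(
            np.power(2.0, rng.normal(25, 0.5, size=(n, 9))), index=idx,
            columns=exp_samples,
        )
        msms = pd.DataFrame(rng.poisson(10, size=(n, 9)) + 1, index=idx,
                            columns=exp_samples)
        # protein present only in the ER+ group, abundant and count-rich there
        ab.iloc[0, 5:] = np.nan
        ab.iloc[0, :5] = 2.0**27
        msms.iloc[0, :5] = 80
        msms.iloc[0, 5:] = 0
        proteins = make_proteins(ab, msms=msms)
        res = run_presence_branch(proteins, design_5v4, seed=2)
        assert "P0" in res.selected_ids
        assert set(res.selected_ids) <= set(res.preselected_ids)

    def test_decoys_removed_before_testing(self, design_5v4, exp_samples):
        rng = np.random.default_rng(8)
        idx = pd.Index(["P0", "REV__P0"], name="protein_group_id")
        ab = pd.DataFrame(
            np.power(2.0, rng.normal(25, 1, size=(2, 9))), index=idx, columns=exp_samples
        )
        proteins = make_proteins(ab, reverse=[False, True])
        res = run_presence_branch(proteins, design_5v4, seed=2)
        assert "REV__P0" not in res.table.index


class TestBranchOverlap:
    def test_overlap_and_concordance(self):
        data = generate_dataset(
            SimulationConfig(n_proteins=80, frac_de=0.2, log2_effect=2.0, seed=31)
        )
        flt, _ = filter_peptides(data.peptides, data.design)
        res_a = run_abundance_branch(flt, data.proteins, data.design, seed=31)
        res_p = run_presence_branch(data.proteins, data.design, seed=31)
        rep = branch_overlap(res_a, res_p)
        assert set(rep.shared) == set(res_a.selected_ids) & set(res_p.selected_ids)
        assert set(rep.shared) == set(rep.concordant) | set(rep.discordant)
        assert len(rep.only_abundance) == len(set(res_a.selected_ids) - set(res_p.selected_ids))

    def test_disjoint_and_identical_sets(self, design_5v4):
        from lfqpipe.abundance import DifferentialResults

        def mk(ids, diffs, directions):
            tab = pd.DataFrame(
                {
                    "selected": True,
                    "preselected": True,
                    "mean_diff": diffs,
                    "direction": directions,
                },
                index=pd.Index(ids, name="protein_group_id"),
            )
            return DifferentialResults("x", tab, ("ER+", "ER-"))

        a = mk(["P1", "P2"], [1.0, -1.0], ["ER-", "ER+"])
        b = mk(["P3"], [1.0], ["ER-"])
        assert branch_overlap(a, b).shared == []
        same = branch_overlap(a, a)
        assert same.shared == ["P1", "P2"]
        assert same.concordant == ["P1", "P2"]  # positive diff toward ER-, matches
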