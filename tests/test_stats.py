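import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermopheno.phenostats import (anova_two_way, average_replicates,
                                    bartlett_test, block_adjust, boxcox_fit,
                                    gs_regression, h2_combined, h2_within,
                                    paired_t, reml_components, shape_stats,
                                    spearman_rho)


class TestBoxCox:
    def test_lambda_one_is_shift_by_one(self):
        from thermopheno.phenostats import TransformSpec
        y = np.array([1.0, 2.0, 5.0])
        assert np.allclose(TransformSpec(1.0).apply(y), y - 1.0)

    def test_lognormal_prefers_log_transform(self, rng):
        y = np.exp(rng.normal(0, 1, 4000))
        spec, _ = boxcox_fit(y)
        assert abs(spec.lambda_) <= 0.2

    def test_constant_response_defaults_to_identity(self):
        with pytest.warns(UserWarning, match="flat"):
            spec, z = boxcox_fit(np.full(10, 3.0))
        assert spec.lambda_ == 1.0
        assert np.allclose(z, 2.0)

    def test_nonpositive_data_rejected(self):
        with pytest.raises(ValueError):
            boxcox_fit(np.array([-1.0, 2.0, 3.0]))

    def test_profile_on_additive_model_removes_group_shifts(self, rng):
        # residuals are lognormal around genotype/treatment means:
        # profiling on the additive model should still find lambda ~ 0
        g = np.repeat(np.arange(50), 20)
        t = np.tile(np.repeat([0, 1], 10), 50)
        mu = 5.0 + 0.5 * t + rng.normal(0, 0.3, 50)[g]
        y = np.exp(np.log(mu) + rng.normal(0, 0.4, g.size))
        spec, _ = boxcox_fit(y, genotype=g, treatment=t)
        assert abs(spec.lambda_) <= 0.3


class TestBartlett:
    def test_identical_groups(self):
        res = bartlett_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            bartlett_test([1.0, 2.0, 3.0])

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            bartlett_test([1.0, 2.0], [3.0])

    def test_matches_scipy_on_unequal_variances(self, rng):
        from scipy import stats
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 3, 60)
        res = bartlett_test(a, b)
        chi2, p = stats.bartlett(a, b)
        assert res.statistic == pytest.approx(chi2)
        assert res.p_value == pytest.approx(p)


class TestBlockAdjust:
    def test_equal_block_means_unchanged(self):
        y = np.array([1.0, 2.0, 1.0, 2.0])
        out = block_adjust(y, ["b1", "b1", "b2", "b2"])
        assert np.allclose(out, y)

    def test_symmetric_offsets_removed(self):
        # blocks offset +1 / -1 from the grand mean
        y = np.array([11.0, 11.0, 9.0, 9.0])
        out = block_adjust(y, ["b1", "b1", "b2", "b2"])
        assert np.allclose(out, 10.0)

    def test_grand_mean_preserved(self, rng):
        y = rng.normal(20, 2, 60)
        blocks = rng.integers(1, 5, 60)
        out = block_adjust(y, blocks)
        # equal-weight preservation within each block implies overall
        # preservation up to block-size weighting; with the same data the
        # weighted statement is exact per block:
        for b in np.unique(blocks):
            assert out[blocks == b].mean() == pytest.approx(y.mean())

    def test_adjustment_per_plot(self):
        y = np.array([11.0, 9.0, 110.0, 90.0])
        out = block_adjust(y, ["b1", "b2", "b1", "b2"],
                           plots=["WW", "WW", "mDr", "mDr"])
        assert np.allclose(out, [10.0, 10.0, 100.0, 100.0])


class TestAnova:
    def test_balanced_toy_against_hand_computed_ss(self):
        # 2 genotypes x 2 treatments, r=2, cell means 10/12/14/20
        g = ["A"] * 4 + ["B"] * 4
        t = ["WW", "WW", "mDr", "mDr"] * 2
        y = [9.0, 11.0, 11.0, 13.0, 13.0, 15.0, 19.0, 21.0]
        table = anova_two_way(g, t, y)
        # hand computation: grand 14; A mean 11, B mean 17 -> SS_G = 8*9=72
        # WW mean 12, mDr mean 16 -> SS_T = 8*4=32; cells 10,12,14,20:
        # interaction = cell - g - t + grand = -1,+1,+1,-1 -> SS_GT = 2*4=8
        # within-cell SS = 8 * 1 = 8
        assert table.loc["Genotype", "sum_sq"] == pytest.approx(72.0)
        assert table.loc["Treatment", "sum_sq"] == pytest.approx(32.0)
        assert table.loc["G x T", "sum_sq"] == pytest.approx(8.0)
        assert table.loc["Error", "sum_sq"] == pytest.approx(8.0)
        assert table.loc["Genotype", "df"] == 1
        assert table.loc["Error", "df"] == 4

    def test_degrees_of_freedom_for_many_genotypes(self, rng):
        # 499 genotype levels with replication: df 498 / 1 / 498
        m = 499
        g = np.repeat([f"G{i}" for i in range(m)], 4)
        t = np.tile(["WW", "WW", "mDr", "mDr"], m)
        y = rng.normal(20, 1, g.size)
        table = anova_two_way(g, t, y)
        assert table.loc["Genotype", "df"] == 498
        assert table.loc["Treatment", "df"] == 1
        assert table.loc["G x T", "df"] == 498
        assert table.loc["Total", "df"] == g.size - 1

    def test_ss_identity(self, rng):
        g = rng.choice(["A", "B", "C"], 60)
        t = rng.choice(["WW", "mDr"], 60)
        y = rng.normal(0, 1, 60)
        table = anova_two_way(g, t, y)
        total = ((y - y.mean()) ** 2).sum()
        assert table.loc["Total", "sum_sq"] == pytest.approx(total, rel=1e-10)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            anova_two_way(["A", "A"], ["WW", "mDr"], [1.0, 2.0])


def _simulate_trial(rng, m=80, r=4, comps=(1.0, 0.5, 2.0), n_t=2):
    g = np.repeat(np.arange(m), n_t * r)
    t = np.tile(np.repeat(np.arange(n_t), r), m)
    y = (10 + 0.5 * t + rng.normal(0, np.sqrt(comps[0]), m)[g]
         + rng.normal(0, np.sqrt(comps[1]), (m, n_t))[g, t]
         + rng.normal(0, np.sqrt(comps[2]), m * n_t * r))
    return np.char.add("G", g.astype(str)), np.array(["WW", "mDr"])[t], y


class TestReml:
    def test_matches_ems_oracle_on_balanced_design(self, rng):
        """On balanced data REML equals the expected-mean-squares
        method-of-moments: sG2=(MS_G-MS_GT)/(rn), sGT2=(MS_GT-MS_E)/r."""
        r, n_t = 4, 2
        for _ in range(3):
            g, t, y = _simulate_trial(rng, m=60, r=r)
            vc = reml_components(g, t, y)
            table = anova_two_way(g, t, y)
            ms_g = table.loc["Genotype", "mean_sq"]
            ms_gt = table.loc["G x T", "mean_sq"]
            ms_e = table.loc["Error", "mean_sq"]
            assert vc.sigma2_eps == pytest.approx(ms_e, rel=1e-6)
            assert vc.sigma2_GT == pytest.approx((ms_gt - ms_e) / r, rel=1e-6)
            assert vc.sigma2_G == pytest.approx(
                (ms_g - ms_gt) / (r * n_t), rel=1e-6)

    def test_zero_genotype_variance_recovered(self, rng):
        estimates = []
        for _ in range(5):
            g, t, y = _simulate_trial(rng, m=100, r=3, comps=(0.0, 0.0, 1.0))
            vc = reml_components(g, t, y)
            estimates.append(vc.sigma2_G)
        assert np.median(estimates) < 0.05 * 1.0

    def test_unbalanced_data_accepted(self, rng):
        g, t, y = _simulate_trial(rng, m=60, r=4)
        keep = rng.random(y.size) > 0.2
        vc = reml_components(g[keep], t[keep], y[keep])
        assert vc.sigma2_eps > 0
        assert vc.n_treatments == 2

    def test_average_replicates(self):
        g = ["A", "A", "A", "A", "B", "B"]
        t = ["WW", "WW", "mDr", "mDr", "WW", "mDr"]
        r_within, r_exp = average_replicates(g, t)
        assert r_within == pytest.approx((2 + 2 + 1 + 1) / 4)
        assert r_exp == pytest.approx((4 + 2) / 2)


class TestHeritability:
    def test_within_formula_identity(self):
        assert h2_within(2.0, 7.0, 3.5) == pytest.approx(0.5)
        assert h2_within(0.0, 5.0, 2.0) == 0.0
        assert h2_within(3.0, 0.0, 2.0) == 1.0

    def test_combined_formula_identity(self):
        assert h2_combined(1.0, 2.0, 7.3, 2, 7.3) == pytest.approx(0.4)
        assert h2_combined(0.0, 1.0, 1.0, 2, 3.0) == 0.0
        assert h2_combined(2.0, 0.0, 0.0, 2, 3.0) == 1.0

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            h2_within(0.0, 0.0, 3.5)
        with pytest.raises(ValueError):
            h2_within(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            h2_combined(-1.0, 1.0, 1.0, 2, 3.0)

    @given(s_g=st.floats(0.01, 10), s_e=st.floats(0.01, 10),
           r=st.floats(0.5, 10), bump=st.floats(0.01, 5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_genetic_variance_and_replicates(self, s_g, s_e, r,
                                                         bump):
        assert h2_within(s_g + bump, s_e, r) > h2_within(s_g, s_e, r)
        assert h2_within(s_g, s_e, r + bump) > h2_within(s_g, s_e, r)


class TestShapeStats:
    def test_symmetric_sample_has_zero_skewness(self):
        s = shape_stats([1.0, 2.0, 3.0, 4.0])
        assert s.skewness == pytest.approx(0.0, abs=1e-12)
        assert s.mean == 2.5 and s.median == 2.5

    def test_normal_sample_near_zero_shape(self, rng):
        x = rng.normal(0, 1, 20000)
        s = shape_stats(x)
        se_skew = np.sqrt(6 / x.size)
        se_kurt = np.sqrt(24 / x.size)
        assert abs(s.skewness) < 3 * se_skew
        assert abs(s.kurtosis) < 3 * se_kurt

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            shape_stats(np.full(10, 2.0))

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            shape_stats([1.0, 2.0, 3.0])


class TestAgreementTests:
    def test_identical_vectors(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        rho = spearman_rho(x, x)
        assert rho.statistic == pytest.approx(1.0)
        tt = paired_t(x, x)
        assert tt.statistic == 0.0 and tt.p_value == 1.0

    def test_reversed_ranking(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman_rho(x, x[::-1]).statistic == pytest.approx(-1.0)

    def test_tied_ranks_average(self):
        # hand-computed with average ranks: x ranks 1,2.5,2.5,4
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([10.0, 20.0, 30.0, 40.0])
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 2.0, 3.0, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y).statistic == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [1, 2])

    def test_unpaired_variant(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 60)
        res = paired_t(a, b, paired=False)
        assert res.p_value < 0.05


class TestGsRegression:
    def test_perfectly_collinear(self):
        x = np.array([-9.0, -8.0, -7.0, -6.0])
        fit = gs_regression(500 + 50 * x, x)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(50.0)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            gs_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_one_sided_p_is_half_two_sided(self, rng):
        x = rng.normal(-7, 1, 30)
        y = 100 - 50 * x + rng.normal(0, 40, 30)
        fit = gs_regression(y, x)
        assert fit.p_value_one_sided == pytest.approx(fit.p_value / 2)
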