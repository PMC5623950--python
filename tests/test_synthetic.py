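import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermopheno import (SyntheticConfig, draw_gs, draw_true_tc, make_layout,
                         render_mosaic)
from thermopheno.phenostats import gs_regression


class TestConfig:
    def test_defaults_are_valid(self):
        SyntheticConfig()

    @pytest.mark.parametrize("kwargs", [
        {"n_genotypes": 0},
        {"mortality_rate": 1.5},
        {"pixel_size_m": 0.0},
        {"sigma_G": -1.0},
        {"soil_temp_mean": 20.0},   # inside/below the canopy band
        {"weed_temp_mean": 20.0},   # inside/above the canopy band
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestLayout:
    def test_full_factorial_when_no_mortality(self):
        cfg = SyntheticConfig(seed=0, n_genotypes=2, n_blocks=4,
                              reps_per_block=1, mortality_rate=0.0)
        layout = make_layout(cfg)
        assert len(layout) == 2 * 4 * 1 * 2
        assert layout["alive"].sum() == 16
        # one tree per genotype x block x treatment
        counts = layout.groupby(["genotype_id", "block", "treatment"]).size()
        assert (counts == 1).all()

    def test_total_mortality_leaves_no_alive_trees(self):
        cfg = SyntheticConfig(seed=0, n_genotypes=3, mortality_rate=1.0)
        assert make_layout(cfg)["alive"].sum() == 0

    def test_mortality_within_binomial_bounds(self):
        cfg = SyntheticConfig(seed=123)
        layout = make_layout(cfg)
        n = len(layout)
        assert n == 503 * 4 * 2
        lo = stats.binom.ppf(0.005, n, 1 - 0.127)
        hi = stats.binom.ppf(0.995, n, 1 - 0.127)
        assert lo <= layout["alive"].sum() <= hi

    def test_unique_positions_and_grid_spacing(self):
        cfg = SyntheticConfig(seed=5, n_genotypes=10)
        layout = make_layout(cfg)
        assert layout.duplicated(["x_m", "y_m", "treatment"]).sum() == 0
        xs = np.sort(layout["x_m"].unique())
        assert np.all(np.diff(xs) % 2.5 == pytest.approx(0.0, abs=1e-9))

    def test_seed_determinism(self):
        a = make_layout(SyntheticConfig(seed=7, n_genotypes=5))
        b = make_layout(SyntheticConfig(seed=7, n_genotypes=5))
        pd.testing.assert_frame_equal(a, b)

    def test_border_rows_rendered_but_never_analysed(self):
        from thermopheno.extraction import summarize_genotypes
        cfg = SyntheticConfig(seed=8, n_genotypes=3, mortality_rate=0.0,
                              border_rows=2)
        layout = make_layout(cfg)
        border = layout[layout["border"]]
        assert len(border) > 0
        assert (border["genotype_id"] == "BORDER").all()
        state = draw_true_tc(cfg, layout)
        # border trees draw no genotype effect: true T_c has no g_i term
        b_ww = state.trees[(state.trees["border"])
                           & (state.trees["treatment"] == "WW")]
        assert b_ww["true_tc"].sub(b_ww["residual"]).sub(19.55).abs().max() \
            < 1e-9
        records = state.trees[["tree_id", "true_tc"]].rename(
            columns={"true_tc": "tc"}).assign(n_pixels=1)
        out = summarize_genotypes(records, layout)
        assert "BORDER" not in set(out["genotype_id"])


class TestTrueTc:
    def test_degenerate_sds_give_treatment_means(self):
        cfg = SyntheticConfig(seed=0, n_genotypes=4, sigma_G=0, sigma_GT=0,
                              sigma_block=0, sigma_eps=0)
        layout = make_layout(cfg)
        state = draw_true_tc(cfg, layout)
        ww = state.trees[state.trees["treatment"] == "WW"]
        mdr = state.trees[state.trees["treatment"] == "mDr"]
        assert np.allclose(ww["true_tc"], 19.55)
        assert np.allclose(mdr["true_tc"], 21.60)

    def test_genotype_effect_scale_recovered(self):
        cfg = SyntheticConfig(seed=3, n_genotypes=2000, sigma_G=1.0,
                              sigma_GT=0, sigma_block=0, sigma_eps=0,
                              mortality_rate=0.0)
        layout = make_layout(cfg)
        state = draw_true_tc(cfg, layout)
        means = state.trees.groupby("genotype_id")["true_tc"].mean()
        sd = means.std(ddof=1)
        se = 1.0 / np.sqrt(2 * (2000 - 1))  # SE of a sample SD
        assert sd == pytest.approx(1.0, abs=3 * se)

    def test_effects_shared_across_replicates(self):
        cfg = SyntheticConfig(seed=2, n_genotypes=3, sigma_eps=0,
                              sigma_block=0)
        layout = make_layout(cfg)
        state = draw_true_tc(cfg, layout)
        # same genotype x treatment -> identical true value across blocks
        nun = state.trees.groupby(["genotype_id", "treatment"])["true_tc"].nunique()
        assert (nun == 1).all()

    def test_seed_determinism(self):
        cfg = SyntheticConfig(seed=9, n_genotypes=6)
        layout = make_layout(cfg)
        a = draw_true_tc(cfg, layout)
        b = draw_true_tc(cfg, layout)
        pd.testing.assert_frame_equal(a.trees, b.trees)
        pd.testing.assert_series_equal(a.genotype_effects, b.genotype_effects)


class TestRenderMosaic:
    def test_single_tree_crown_pixels_carry_true_temperature(self):
        cfg = SyntheticConfig(seed=0, n_genotypes=1, n_blocks=1,
                              mortality_rate=0.0, sensor_noise_sd=0.0,
                              crown_radius_sd_m=0.0, weed_fraction=0.0,
                              sigma_G=0, sigma_GT=0, sigma_block=0,
                              sigma_eps=0)
        layout = make_layout(cfg)
        state = draw_true_tc(cfg, layout)
        mosaic = render_mosaic(cfg, layout, state, "WW")
        tree = layout[layout["treatment"] == "WW"].iloc[0]
        X, Y = mosaic.pixel_centers()
        inside = (X - tree.x_m) ** 2 + (Y - tree.y_m) ** 2 <= 0.45**2
        assert np.allclose(mosaic.values[inside], 19.55)
        assert not np.any(np.isclose(mosaic.values[~inside], 19.55))

    def test_background_stays_outside_canopy_band(self):
        cfg = SyntheticConfig(seed=1, n_genotypes=2, mortality_rate=1.0)
        layout = make_layout(cfg)
        state = draw_true_tc(cfg, layout)
        mosaic = render_mosaic(cfg, layout, state, "WW")
        vals = mosaic.valid_values()
        in_band = (vals >= 15.0) & (vals <= 27.0)
        assert in_band.sum() == 0

    def test_crown_means_are_unbiased(self, small_trial):
        cfg = small_trial["config"]
        mosaic = small_trial["mosaics"]["WW"]
        trees = small_trial["true_state"].trees
        ww = trees[(trees["treatment"] == "WW") & trees["alive"]]
        X, Y = mosaic.pixel_centers()
        errors = []
        for _, t in ww.iterrows():
            inside = ((X - t.x_m) ** 2 + (Y - t.y_m) ** 2 <= 0.35**2)
            vals = mosaic.values[inside]
            vals = vals[(vals > 14) & (vals < 28)]  # crown only
            if vals.size:
                errors.append(vals.mean() - t.true_tc)
                assert abs(errors[-1]) < 3 * cfg.sensor_noise_sd / np.sqrt(vals.size) + 1e-6
        assert len(errors) > 10
        # no systematic bias across trees
        assert abs(np.mean(errors)) < 3 * cfg.sensor_noise_sd / np.sqrt(len(errors))

    def test_dead_trees_leave_background(self):
        cfg = SyntheticConfig(seed=4, n_genotypes=1, n_blocks=1,
                              mortality_rate=1.0, weed_fraction=0.0)
        layout = make_layout(cfg)
        state = draw_true_tc(cfg, layout)
        mosaic = render_mosaic(cfg, layout, state, "mDr")
        assert mosaic.valid_values().min() > 28.0  # soil only

    def test_seed_determinism(self, small_trial):
        cfg = small_trial["config"]
        again = render_mosaic(cfg, small_trial["layout"],
                              small_trial["true_state"], "WW")
        assert np.array_equal(again.values,
                              small_trial["mosaics"]["WW"].values,
                              equal_nan=True)


class TestDrawGs:
    def test_arithmetic_examples(self):
        cfg = SyntheticConfig(seed=0, n_genotypes=1, n_blocks=1,
                              mortality_rate=0.0, sigma_G=0, sigma_GT=0,
                              sigma_block=0, sigma_eps=0, gs_slope=-50.0,
                              gs_intercept=50.0, gs_noise_sd=0.0,
                              mu_WW=28.75 - 9.0)  # T_c - T_a = -9
        layout = make_layout(cfg)
        state = draw_true_tc(cfg, layout)
        gs = draw_gs(state, cfg)
        ww = gs[gs["treatment"] == "WW"]
        assert np.allclose(ww["gs"], 50 + (-50) * (-9.0))

    def test_zero_slope_returns_intercept(self):
        cfg = SyntheticConfig(seed=0, n_genotypes=2, gs_slope=0.0,
                              gs_noise_sd=0.0, gs_intercept=321.0)
        layout = make_layout(cfg)
        state = draw_true_tc(cfg, layout)
        assert np.allclose(draw_gs(state, cfg)["gs"], 321.0)

    def test_regression_recovers_generating_line(self):
        cfg = SyntheticConfig(seed=6, n_genotypes=300, gs_noise_sd=1e-6)
        layout = make_layout(cfg)
        state = draw_true_tc(cfg, layout)
        gs = draw_gs(state, cfg)
        gs = gs[gs["gs"] > 0]  # exclude the floor at zero conductance
        fit = gs_regression(gs["gs"], gs["tc_minus_ta"])
        assert fit.slope == pytest.approx(cfg.gs_slope, rel=1e-4)
        assert fit.intercept == pytest.approx(cfg.gs_intercept, rel=1e-3)
        assert fit.r_squared > 0.999
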