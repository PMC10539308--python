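"""Displacement-distribution model, histogramming, and the three-component fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfkinetics import (
    DiffusionParams,
    build_jump_histogram,
    compare_groups,
    eq2_pdf,
    fit_three_component,
    simulate_jumps,
)
from tfkinetics.diffusion import DEFAULT_BIN_WIDTH, JumpHistogram, histogram_from_jumps
from tfkinetics.sim import simulate_tracks


class TestEq2Pdf:
    def test_normalization_over_full_grid(self, wt_params):
        centers = np.arange(0.01, 1.5, 0.02)
        p = eq2_pdf(wt_params, centers, 0.02)
        assert p.sum() >= 0.999

    def test_single_component_mode_is_rayleigh_scale(self):
        # argmax of the Rayleigh magnitude density sits at sqrt(2 D dt)
        params = DiffusionParams((0.0, 1.0, 0.0), (0.01, 0.46, 3.4), 0.01)
        centers = np.arange(0.0005, 0.5, 0.001)
        p = eq2_pdf(params, centers, 0.001)
        assert centers[np.argmax(p)] == pytest.approx(np.sqrt(2 * 0.46 * 0.01), abs=0.002)

    def test_cumulative_below_100nm_matches_mixture_cdf(self, wt_params):
        centers = np.arange(0.01, 1.5, 0.02)
        p = eq2_pdf(wt_params, centers, 0.02)
        # midpoint-rule bin probabilities slightly overweight the steep small-r
        # region, so agreement with the exact CDF 0.5979 is to ~2 points
        assert p[centers < 0.1].sum() == pytest.approx(0.5979, abs=0.02)

    def test_zero_d_component_is_point_mass_in_first_bin(self):
        params = DiffusionParams((0.3, 0.4, 0.3), (0.0, 0.46, 3.4), 0.01)
        centers = np.arange(0.01, 1.5, 0.02)
        p = eq2_pdf(params, centers, 0.02)
        assert p[0] >= 0.3

    def test_invalid_dt_rejected(self, wt_params):
        bad = DiffusionParams.__new__(DiffusionParams)
        object.__setattr__(bad, "fractions", wt_params.fractions)
        object.__setattr__(bad, "coeffs", wt_params.coeffs)
        object.__setattr__(bad, "dt", 0.0)
        with pytest.raises(ValueError):
            eq2_pdf(bad, np.array([0.01]), 0.02)


class TestJumpHistogram:
    def test_stationary_track_fills_first_bin(self):
        ts, _ = simulate_tracks(
            DiffusionParams((1.0, 0.0, 0.0), (0.0, 0.1, 1.0), 0.01),
            n_tracks=10, track_len=6, seed=1,
        )
        hist = build_jump_histogram(ts, pooled=True)["pooled"]
        assert hist.counts[0] == hist.n_jumps

    def test_jump_count_is_points_minus_one(self, wt_params):
        ts, _ = simulate_tracks(wt_params, n_tracks=7, track_len=11, seed=2)
        hist = build_jump_histogram(ts, pooled=True)["pooled"]
        assert hist.n_jumps == 7 * 10

    def test_histogram_matches_model_chi2(self, wt_params):
        r = simulate_jumps(wt_params, 1_000_000, seed=3)
        hist = histogram_from_jumps(r, wt_params.dt)
        expected = eq2_pdf(wt_params, hist.bin_centers, hist.bin_width) * hist.n_jumps
        # pool overflow and tail bins so every class has decent expectation
        keep = expected >= 5
        obs = np.append(hist.counts[keep], hist.counts[~keep].sum() + hist.overflow)
        exp = np.append(expected[keep], hist.n_jumps - expected[keep].sum())
        exp *= obs.sum() / exp.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, df=obs.size - 1)
        assert p > 0.001

    def test_empty_jump_set_rejected(self):
        with pytest.raises(ValueError, match="no jumps"):
            histogram_from_jumps(np.empty(0), 0.01)


class TestThreeComponentFit:
    def test_single_component_collapses(self):
        params = DiffusionParams((1.0, 0.0, 0.0), (0.03, 0.46, 3.4), 0.01)
        r = simulate_jumps(params, 50_000, seed=4)
        fit = fit_three_component(histogram_from_jumps(r, 0.01))
        assert fit.params.fractions[0] >= 0.95

    def test_wt_recovery_within_ten_percent(self, wt_jumps_large, wt_params):
        fit = fit_three_component(histogram_from_jumps(wt_jumps_large, wt_params.dt))
        truth = np.array([*wt_params.fractions[:2], *wt_params.coeffs])
        got = np.array([*fit.params.fractions[:2], *fit.params.coeffs])
        np.testing.assert_allclose(got, truth, rtol=0.10)

    def test_noise_free_self_consistency(self, wt_params):
        # refitting the model's own expected bin fractions returns the truth
        n = 1_000_000
        centers = np.arange(0.01, 1.5, DEFAULT_BIN_WIDTH)
        p = eq2_pdf(wt_params, centers, DEFAULT_BIN_WIDTH)
        hist = JumpHistogram(
            counts=p * n, bin_width=DEFAULT_BIN_WIDTH, dt=wt_params.dt,
            n_jumps=n, overflow=n - int(p.sum() * n),
        )
        fit = fit_three_component(hist)
        np.testing.assert_allclose(fit.params.fractions, wt_params.fractions, rtol=1e-3)
        np.testing.assert_allclose(fit.params.coeffs, wt_params.coeffs, rtol=1e-3)
        assert fit.sse < 1e-8

    def test_fractions_on_simplex_and_sorted_components(self, wt_jumps_large, wt_params):
        fit = fit_three_component(histogram_from_jumps(wt_jumps_large, wt_params.dt))
        f, d = fit.params.fractions, fit.params.coeffs
        assert all(x >= 0 for x in f)
        assert sum(f) == pytest.approx(1.0, abs=1e-9)
        assert d[0] < d[1] < d[2]

    def test_invariant_to_init_component_order(self, wt_params):
        r = simulate_jumps(wt_params, 30_000, seed=5)
        hist = histogram_from_jumps(r, wt_params.dt)
        init_sorted = DiffusionParams((0.4, 0.4, 0.2), (0.02, 0.5, 4.0), 0.01)
        init_shuffled = DiffusionParams((0.2, 0.4, 0.4), (0.02, 0.5, 4.0), 0.01)
        a = fit_three_component(hist, init=init_sorted)
        b = fit_three_component(hist, init=init_shuffled)
        np.testing.assert_allclose(a.params.coeffs, b.params.coeffs, rtol=1e-6)

    def test_fix_d1_pins_slowest_coefficient(self, wt_params):
        r = simulate_jumps(wt_params, 50_000, seed=6)
        fit = fit_three_component(histogram_from_jumps(r, wt_params.dt), fix_d1=0.034)
        assert fit.params.coeffs[0] == pytest.approx(0.034, rel=1e-9)

    def test_low_count_warning(self, wt_params):
        r = simulate_jumps(wt_params, 500, seed=7)
        with pytest.warns(UserWarning, match="fewer than"):
            fit_three_component(histogram_from_jumps(r, wt_params.dt))

    def test_bound_fraction_recovery_across_cells(self, wt_params):
        # 20 synthetic cells at 10^4 jumps each: median F1 within 3 points
        f1s = []
        for i in range(20):
            r = simulate_jumps(wt_params, 10_000, seed=1000 + i)
            fit = fit_three_component(histogram_from_jumps(r, wt_params.dt))
            f1s.append(fit.params.fractions[0])
        assert abs(np.median(f1s) - wt_params.fractions[0]) < 0.03


class TestCompareGroups:
    def test_identical_groups_give_h_zero_p_one(self):
        df = pd.DataFrame({"F1": [0.4, 0.5, 0.45]})
        gc = compare_groups({"a": df, "b": df.copy()})
        row = gc.table.iloc[0]
        assert row["H"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_all_constant_values_handled(self):
        df = pd.DataFrame({"F1": [0.4, 0.4]})
        gc = compare_groups({"a": df, "b": df.copy()})
        assert gc.table.iloc[0]["p"] == 1.0

    def test_type_one_error_rate_near_nominal(self):
        rng = np.random.default_rng(8)
        n_sim, alpha = 1000, 0.05
        rejections = 0
        for _ in range(n_sim):
            groups = {
                c: pd.DataFrame({"F1": rng.normal(0.4, 0.05, 10)})
                for c in ("a", "b", "c")
            }
            if compare_groups(groups).table.iloc[0]["p"] < alpha:
                rejections += 1
        se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rejections / n_sim - alpha) < 3 * se

    def test_condition_medians_reflect_generator(self, wt_params):
        f1s = []
        for i in range(8):
            r = simulate_jumps(wt_params, 10_000, seed=2000 + i)
            f1s.append(
                fit_three_component(histogram_from_jumps(r, wt_params.dt)).params.fractions[0]
            )
        other = pd.DataFrame({"F1": np.full(8, 0.13)})
        gc = compare_groups({"wt": pd.DataFrame({"F1": f1s}), "halo": other})
        assert gc.table.iloc[0]["wt_median"] == pytest.approx(0.44, abs=0.04)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": pd.DataFrame({"F1": [1.0, 2.0]})})
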