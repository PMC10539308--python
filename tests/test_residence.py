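"""Dwell extraction, survival curves, bleach correction, RMST and resampling."""

import numpy as np
import pytest

from tfkinetics import (
    DwellSet,
    SlowMovieConfig,
    SurvivalCurve,
    correct_bleaching,
    estimate_bleach_rate,
    extract_dwells,
    summarize_residence,
    survival_curve,
)
from tfkinetics.sim import simulate_slow_movie_dwells, simulate_slow_movie_tracks
from tfkinetics.tracks_io import Track, TrackSet


def stationary_track(n_frames, dt=0.5, cell="c", tid="t"):
    return Track(cell, tid, dt, frames=np.arange(n_frames), xy=np.zeros((n_frames, 2)))


class TestExtractDwells:
    def test_stationary_track_duration_convention(self):
        ts = TrackSet([stationary_track(10)], regime="slow")
        dwells = extract_dwells(ts)
        np.testing.assert_allclose(dwells.durations, [5.0])  # 10 frames x 0.5 s
        assert dwells.censored.all()  # run reaches the end of the track

    def test_large_jump_splits_runs(self):
        xy = np.zeros((12, 2))
        xy[6:, 0] = 0.5  # one 0.5 um jump after frame index 5
        t = Track("c", "t", 0.5, frames=np.arange(12), xy=xy)
        dwells = extract_dwells(TrackSet([t], regime="slow"), r_immobile=0.2)
        np.testing.assert_allclose(np.sort(dwells.durations), [3.0, 3.0])

    def test_short_runs_dropped(self):
        ts = TrackSet([stationary_track(4)], regime="slow")
        assert len(extract_dwells(ts, min_frames=5)) == 0

    def test_generator_tracks_reproduce_dwell_list(self, h2b_like_config):
        # same seed: the track materialization and the dwell generator share
        # the exact observed-duration bookkeeping
        dwells, _ = simulate_slow_movie_dwells(h2b_like_config, 300, seed=21)
        tracks, _ = simulate_slow_movie_tracks(h2b_like_config, 300, seed=21)
        extracted = extract_dwells(tracks, r_immobile=0.2, min_frames=5)
        np.testing.assert_allclose(
            np.sort(extracted.durations), np.sort(dwells.durations)
        )

    def test_fast_regime_rejected(self):
        ts = TrackSet([Track("c", "t", 0.01, [0, 1], np.zeros((2, 2)))], regime="fast")
        with pytest.raises(ValueError, match="slow"):
            extract_dwells(ts)


class TestSurvivalCurve:
    def test_two_point_empirical_survival(self):
        d = DwellSet([2.5, 5.0], [False, False], frame_interval=0.5)
        s = survival_curve(d)
        assert s(2.5) == 1.0
        assert s(3.0) == 0.5
        assert s(5.5) == 0.0

    def test_truncated_exponential_within_dkw_band(self):
        rng = np.random.default_rng(22)
        n, k, dt = 100_000, 0.05, 0.5
        raw = 2.5 + rng.exponential(1 / k, n)
        d = DwellSet(np.floor(raw / dt) * dt, np.zeros(n, bool), frame_interval=dt)
        s = survival_curve(d)
        t = np.arange(2.5, 60.0, dt)
        # at frame-grid times, discretized survival equals the continuous one
        emp = np.array([s(ti) for ti in t])
        band = np.sqrt(np.log(2 / 0.001) / (2 * n))
        assert np.max(np.abs(emp - np.exp(-k * (t - 2.5)))) < band

    def test_duplicate_order_invariance(self):
        a = survival_curve(DwellSet([2.5, 2.5, 5.0], [0, 0, 0], 0.5))
        b = survival_curve(DwellSet([5.0, 2.5, 2.5], [0, 0, 0], 0.5))
        np.testing.assert_allclose(a.survival, b.survival)
        np.testing.assert_allclose(a.times, b.times)

    def test_censoring_modes(self):
        d = DwellSet([2.5, 5.0, 7.5], [False, True, False], frame_interval=0.5)
        full = survival_curve(d, censoring="include")
        excl = survival_curve(d, censoring="exclude")
        km = survival_curve(d, censoring="km")
        assert full.n_molecules == 3
        assert excl.n_molecules == 2
        # treating censored dwells as events underestimates survival, so the
        # product-limit estimate lies at or above the raw curve
        assert km(7.5) >= full(7.5) - 1e-12
        with pytest.raises(ValueError):
            survival_curve(d, censoring="bogus")

    def test_empty_dwell_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            survival_curve(DwellSet(np.empty(0), np.empty(0, bool), 0.5))


class TestBleachRate:
    def test_two_exponential_recovery(self, h2b_like_config):
        dwells, _ = simulate_slow_movie_dwells(h2b_like_config, 100_000, seed=23)
        est = estimate_bleach_rate(dwells, n_components=2)
        assert est.k_b == pytest.approx(0.0316, rel=0.10)

    def test_single_exponential_degenerates_to_one_rate(self):
        cfg = SlowMovieConfig(frame_interval=0.5, movie_length=2000.0,
                              k_off_components=((1.0, 0.0),), k_bleach=0.05)
        dwells, _ = simulate_slow_movie_dwells(cfg, 50_000, seed=24)
        with pytest.warns(UserWarning, match="identifiable"):
            est = estimate_bleach_rate(dwells, n_components=2)
        assert est.k_b == pytest.approx(0.05, rel=0.1)
        assert est.rates.max() / est.rates.min() < 3

    def test_noise_free_model_fit_residual_near_zero(self):
        from tfkinetics.residence import _multiexp_fit

        t = np.arange(2.5, 200.0, 0.5)
        s = 0.6 * np.exp(-0.0316 * (t - 2.5)) + 0.4 * np.exp(-0.15 * (t - 2.5))
        lam, w, sse, ok = _multiexp_fit(t, s, np.ones_like(t), 2.5, 2)
        assert ok
        assert sse < 1e-10
        np.testing.assert_allclose(np.sort(lam), [0.0316, 0.15], rtol=1e-4)

    def test_few_dwells_warns(self):
        d = DwellSet(2.5 + 0.5 * np.arange(20), np.zeros(20, bool), 0.5)
        with pytest.warns(UserWarning, match="unstable"):
            estimate_bleach_rate(d)


class TestCorrectBleaching:
    def make_curve(self, k):
        t = np.arange(2.5, 100.5, 0.5)
        return SurvivalCurve(times=t, survival=np.exp(-k * (t - 2.5)), n_molecules=1000)

    def test_zero_rate_is_identity(self):
        c = self.make_curve(0.04)
        cc = correct_bleaching(c, 0.0)
        np.testing.assert_allclose(cc.survival, c.survival)
        assert cc.corrected

    def test_removes_bleaching_exponential_exactly(self):
        k_off, k_b = 0.01, 0.0316
        cc = correct_bleaching(self.make_curve(k_off + k_b), k_b)
        t = cc.times
        np.testing.assert_allclose(cc.survival, np.exp(-k_off * (t - 2.5)), atol=1e-12)

    def test_double_correction_refused(self):
        cc = correct_bleaching(self.make_curve(0.05), 0.01)
        with pytest.raises(ValueError, match="already"):
            correct_bleaching(cc, 0.01)

    def test_overcorrection_warns(self):
        with pytest.warns(UserWarning, match="10-fold"):
            correct_bleaching(self.make_curve(0.001), 0.05)


class TestSummarizeResidence:
    def test_flat_survival_upper_bound(self):
        t = np.arange(2.5, 100.5, 0.5)
        c = SurvivalCurve(t, np.ones_like(t), 100, corrected=True, k_b_applied=0.0)
        s = summarize_residence(c, None)
        assert s.rmst == pytest.approx(97.5)
        assert s.frac_gt_end == pytest.approx(1.0)

    def test_closed_form_exponential_oracle(self):
        # RMST of exp(-0.02 (t-2.5)) over [2.5, 100] = 50 (1 - e^-1.95)
        t = np.arange(2.5, 100.5, 0.5)
        c = SurvivalCurve(t, np.exp(-0.02 * (t - 2.5)), 100, corrected=True, k_b_applied=0.0)
        s = summarize_residence(c, None)
        assert abs(s.rmst - 50.0 * (1 - np.exp(-1.95))) < 0.1
        assert s.frac_gt_end == pytest.approx(np.exp(-1.95), abs=1e-9)

    def test_zero_variance_data_zero_errors(self):
        d = DwellSet(np.full(40, 5.0), np.zeros(40, bool), 0.5)
        c = correct_bleaching(survival_curve(d), 0.0316)
        s = summarize_residence(c, d, n_resamples=50, seed=1, window=(2.5, 5.0))
        assert s.err_rmst == pytest.approx(0.0, abs=1e-12)
        assert s.err_frac == pytest.approx(0.0, abs=1e-12)

    def test_window_beyond_support_rejected(self):
        t = np.arange(2.5, 50.0, 0.5)
        c = SurvivalCurve(t, np.exp(-0.02 * t), 100, corrected=True, k_b_applied=0.0)
        with pytest.raises(ValueError, match="truncate"):
            summarize_residence(c, None, window=(2.5, 100.0))

    def test_uncorrected_requires_explicit_opt_in(self):
        t = np.arange(2.5, 100.5, 0.5)
        c = SurvivalCurve(t, np.exp(-0.02 * (t - 2.5)), 100)
        with pytest.raises(ValueError, match="allow_uncorrected"):
            summarize_residence(c, None)
        assert summarize_residence(c, None, allow_uncorrected=True).rmst > 0

    def test_pointwise_dominance_implies_rmst_order(self):
        t = np.arange(2.5, 100.5, 0.5)
        hi = SurvivalCurve(t, np.exp(-0.01 * (t - 2.5)), 100, corrected=True, k_b_applied=0.0)
        lo = SurvivalCurve(t, np.exp(-0.03 * (t - 2.5)), 100, corrected=True, k_b_applied=0.0)
        assert summarize_residence(hi, None).rmst >= summarize_residence(lo, None).rmst

    def test_resampling_errors_shrink_with_n(self):
        cfg = SlowMovieConfig(frame_interval=0.5, movie_length=300.0,
                              k_off_components=((1.0, 0.02),), k_bleach=0.0316)
        sizes = (2_000, 20_000)
        errs = []
        for n, seed in zip(sizes, (25, 26)):
            d, _ = simulate_slow_movie_dwells(cfg, n, seed=seed)
            c = correct_bleaching(survival_curve(d), 0.0316)
            s = summarize_residence(c, d, n_resamples=200, seed=seed, window=(2.5, 100.0))
            errs.append(s.err_rmst)
        assert errs[1] < errs[0]


def test_end_to_end_corrected_curve_recovers_unbinding_mixture():
    """Simulated dwells, bleach-corrected, match the true k_off mixture survival."""
    comps = ((0.7, 0.05), (0.3, 0.01))
    k_b = 0.0316
    cfg = SlowMovieConfig(frame_interval=0.5, movie_length=2000.0,
                          k_off_components=comps, k_bleach=k_b)
    dwells, _ = simulate_slow_movie_dwells(cfg, 100_000, seed=27)
    corrected = correct_bleaching(survival_curve(dwells), k_b)
    t = np.arange(2.5, 100.5, 0.5)
    s_true = sum(w * np.exp(-k * t) for w, k in comps)
    s_true = s_true / s_true[0]
    got = np.array([corrected(ti) for ti in t])
    rel_ok = np.abs(got - s_true) < 0.05 * s_true + 0.01
    assert rel_ok.mean() >= 0.95
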