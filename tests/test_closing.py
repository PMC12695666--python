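import numpy as np
import pytest

from loopx.closing import (
    AlignedCurve,
    align_on_onsets,
    bootstrap_cr,
    cr_from_slope,
    fit_piecewise,
    shuffle_control,
)
from loopx.proximal import ProximalInterval, SegmentationParams, segment_proximal
from tests.conftest import make_series


def _curve(lags, values, sem=1.0):
    lags = np.asarray(lags, float)
    return AlignedCurve(
        lags=lags,
        mean_sq=np.asarray(values, float),
        sem=np.full(len(lags), sem),
        n_series=np.full(len(lags), 20),
        weight=np.full(len(lags), 1.0 / sem**2),
    )


def piecewise_model(lags, plateau, intercept, t_extr):
    lags = np.asarray(lags, float)
    u = np.where(lags > t_extr, 1.0 - lags / t_extr, 0.0)
    return plateau * (1 - u) + intercept * u


class TestFitPiecewise:
    def test_flat_curve_selects_constant(self):
        lags = -np.arange(24)[::-1] * 30.0
        fit = fit_piecewise(_curve(lags, np.full(24, 3e5)))
        assert fit.model_choice == "constant"
        assert fit.r2_plateau == pytest.approx(3e5)

    def test_exact_recovery_on_constructed_curve(self):
        # plateau 6e5 for t < -600 s, then linear to 1e5 at t = 0
        lags = -np.arange(40)[::-1] * 30.0
        y = piecewise_model(lags, 6e5, 1e5, -600.0)
        fit = fit_piecewise(_curve(lags, y))
        assert fit.model_choice == "piecewise"
        assert fit.r2_plateau == pytest.approx(6e5)
        assert fit.r2_int == pytest.approx(1e5)
        assert fit.t_extr == pytest.approx(-600.0)
        assert fit.slope == pytest.approx((1e5 - 6e5) / 600.0)

    def test_cr_is_separation_over_closing_time(self):
        lags = -np.arange(40)[::-1] * 30.0
        y = piecewise_model(lags, 6e5, 1e5, -600.0)
        fit = fit_piecewise(_curve(lags, y))
        # linear map anchored at plateau <-> s and intercept <-> 0: CR = s/T
        assert cr_from_slope(fit, 300_000) == pytest.approx(300 / 600)

    def test_cr_invariant_under_distance_rescaling(self):
        lags = -np.arange(40)[::-1] * 30.0
        y = piecewise_model(lags, 6e5, 1e5, -600.0)
        f1 = fit_piecewise(_curve(lags, y))
        f2 = fit_piecewise(_curve(lags, 4.0 * y, sem=4.0))
        assert cr_from_slope(f1, 300_000) == pytest.approx(
            cr_from_slope(f2, 300_000)
        )

    def test_min_decrease_rule_excludes_short_breakpoints(self):
        # true breakpoint at -90 s has exactly 3 supporting lags (-60,-30,0);
        # requiring 4 forces the search away from the optimum
        lags = -np.arange(20)[::-1] * 30.0
        y = piecewise_model(lags, 6e5, 1e5, -90.0)
        fit3 = fit_piecewise(_curve(lags, y), min_decrease_lags=3)
        assert fit3.model_choice == "piecewise"
        assert fit3.t_extr == pytest.approx(-90.0)
        fit4 = fit_piecewise(_curve(lags, y), min_decrease_lags=4)
        assert fit4.model_choice == "constant" or fit4.t_extr <= -120.0

    def test_too_few_lags_raise(self):
        with pytest.raises(ValueError, match="lags"):
            fit_piecewise(_curve([-60, -30, 0], [1, 1, 1]))

    def test_cr_requires_piecewise_choice(self):
        lags = -np.arange(24)[::-1] * 30.0
        fit = fit_piecewise(_curve(lags, np.full(24, 3e5)))
        with pytest.raises(ValueError):
            cr_from_slope(fit, 300_000)


class TestAlign:
    def test_single_series_single_onset_reindexes_squares(self):
        d = np.concatenate([np.linspace(700, 300, 20), np.full(10, 100.0)])
        s = make_series(d)
        iv = [ProximalInterval(20, 29, right_censored=True)]
        curve = align_on_onsets([s], [iv])
        # strictly pre-onset frames, re-indexed so the last lag is -1 frame
        assert curve.lags[-1] == -30.0
        assert np.allclose(curve.mean_sq, d[:20] ** 2)

    def test_duplicate_series_halves_sem(self):
        rng = np.random.default_rng(0)
        d = np.concatenate([rng.uniform(400, 700, 20), np.full(10, 100.0)])
        s = make_series(d)
        iv = [ProximalInterval(20, 29, right_censored=True)]
        c1 = align_on_onsets([s], [iv])
        c2 = align_on_onsets([s, s], [iv, iv])
        assert np.allclose(c2.mean_sq, c1.mean_sq)
        mid = slice(1, -1)
        assert np.allclose(c2.sem[mid], c1.sem[mid] / np.sqrt(2), rtol=0.05)

    def test_onset_preceded_by_recent_interval_excluded(self):
        d = [100.0] * 10 + [600.0] * 10 + [100.0] * 10 + [600.0] * 30 + [100.0] * 10
        s = make_series(d)  # 30-s frames
        ivs = segment_proximal(
            s, SegmentationParams(spatial_threshold=150, temporal_threshold=240)
        )
        assert len(ivs) == 3
        # first interval starts at frame 0 (left-censored: no onset); the
        # second onset comes 330 s after the first interval ends (inside the
        # 10-min exclusion window); the third comes 930 s after the second
        from loopx.closing import eligible_onsets

        assert eligible_onsets(ivs, 30.0, exclusion_window=600.0) == [60]

    def test_no_eligible_onsets_is_an_error(self):
        s = make_series([100.0] * 30)  # single left-censored interval
        iv = [ProximalInterval(0, 29, left_censored=True, right_censored=True)]
        with pytest.raises(ValueError, match="eligible"):
            align_on_onsets([s], [iv])


class TestShuffle:
    def test_single_frame_series_unchanged(self):
        s = make_series([500.0])
        out = shuffle_control(s, np.random.default_rng(0))
        assert out.distance[0] == 500.0

    def test_multiset_of_distances_preserved(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(100, 700, 100)
        d[::7] = np.nan
        s = make_series(d)
        out = shuffle_control(s, rng)
        assert np.array_equal(np.sort(out.distance[out.valid]),
                              np.sort(s.distance[s.valid]))
        assert np.array_equal(out.valid, s.valid)


def synthetic_extrusion_ensemble(
    n_series=120, cr_kb_s=0.1, s_rep=300_000.0, noise=0.15, seed=0,
    frame_interval=30.0,
):
    """Series whose squared distance tracks a contour shrinking at cr_kb_s."""
    rng = np.random.default_rng(seed)
    sq_per_bp = 6e5 / s_rep  # nm^2 of squared distance per bp of contour
    out = []
    for _ in range(n_series):
        n = 240
        onset = rng.integers(120, 180)
        t_close = s_rep / (cr_kb_s * 1000.0)  # seconds to close from full
        ell = np.empty(n)
        for j in range(n):
            t = (j - onset) * frame_interval
            if t < -t_close:
                ell[j] = s_rep
            elif t < 0:
                ell[j] = -t * cr_kb_s * 1000.0
            else:
                ell[j] = 0.0
        d2 = sq_per_bp * ell + 100.0**2
        d2 = d2 * (1 + rng.normal(scale=noise, size=n))
        out.append(make_series(np.sqrt(np.clip(d2, 1, None)),
                               frame_interval=frame_interval))
    return out


class TestCRRecovery:
    def test_generate_and_recover_closing_rate(self):
        series = synthetic_extrusion_ensemble(cr_kb_s=0.1, seed=2)
        params = SegmentationParams(spatial_threshold=150, temporal_threshold=240)
        ivs = [segment_proximal(s, params) for s in series]
        curve = align_on_onsets(series, ivs, max_lag=6000.0)
        fit = fit_piecewise(curve)
        assert fit.model_choice == "piecewise"
        cr = cr_from_slope(fit, 300_000)
        assert cr == pytest.approx(0.1, abs=0.02)

    def test_bootstrap_gating_and_median(self):
        series = synthetic_extrusion_ensemble(n_series=40, cr_kb_s=0.1, seed=3)
        params = SegmentationParams(spatial_threshold=150, temporal_threshold=240)
        ivs = [segment_proximal(s, params) for s in series]
        res = bootstrap_cr(series, ivs, s_reporters=300_000, n_bootstrap=100,
                           seed=4, max_lag=6000.0)
        assert res["detectable"]
        assert res["n_kept"] >= 80
        assert res["median"] == pytest.approx(0.1, abs=0.03)
        assert res["p10"] <= res["median"] <= res["p90"]

    def test_flat_ensemble_is_undetectable(self):
        rng = np.random.default_rng(5)
        series = []
        for _ in range(30):
            d = rng.uniform(400, 700, 240)
            k = rng.integers(30, 200)
            d[k : k + 12] = 100.0  # a proximal event without any approach
            series.append(make_series(d))
        params = SegmentationParams(spatial_threshold=150, temporal_threshold=240)
        ivs = [segment_proximal(s, params) for s in series]
        res = bootstrap_cr(series, ivs, s_reporters=300_000, n_bootstrap=60, seed=6)
        assert res["n_kept"] <= 10  # overwhelmingly flat draws

    def test_shuffling_destroys_the_decrease(self):
        series = synthetic_extrusion_ensemble(n_series=40, cr_kb_s=0.1, seed=7)
        rng = np.random.default_rng(8)
        shuffled = [shuffle_control(s, rng) for s in series]
        params = SegmentationParams(spatial_threshold=150, temporal_threshold=240)
        ivs = [segment_proximal(s, params) for s in shuffled]
        res = bootstrap_cr(shuffled, ivs, s_reporters=300_000, n_bootstrap=60,
                           seed=9, max_lag=6000.0)
        assert res["n_piecewise"] <= 30  # piecewise in at most half the draws
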