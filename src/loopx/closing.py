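"""Closing-rate (CR) estimation from proximal-onset-aligned distance series.

The CR is the rate (kb/s) at which the unextruded DNA between anchors
shrinks; it reflects the joint action of all extruders on the shortest 1D
path and is distinct from the single-motor speed.  The estimator aligns
squared distances on proximal-state onsets (t_start), pools them with
inverse-variance weights, fits a constant plateau followed by a linear
decrease (parameters R2_plateau, R2_int and breakpoint t_extr, exhaustive
breakpoint search on the lag grid), and converts the slope to genomic units
through the ideal-chain proportionality of squared distance to contour
length, anchored at (R2_plateau <-> reporter separation) and (R2_int <-> 0):

    CR = |slope| * s_reporters / (R2_plateau - R2_int)  =  s_reporters / |t_extr|

A shuffle control destroys processive structure while preserving the
marginal distance distribution; bootstrap resampling of whole series gates
the estimate on draws that retain >= 15 series and a non-constant fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .proximal import ProximalInterval
from .synth import DistanceTimeSeries

__all__ = [
    "AlignedCurve",
    "PiecewiseFit",
    "align_on_onsets",
    "fit_piecewise",
    "cr_from_slope",
    "shuffle_control",
    "bootstrap_cr",
]


@dataclass
class AlignedCurve:
    lags: np.ndarray  # s, <= 0, increasing to 0
    mean_sq: np.ndarray  # weighted mean squared distance, nm^2
    sem: np.ndarray  # weighted standard error, nm^2
    n_series: np.ndarray  # contributing series per lag
    weight: np.ndarray | None = None  # total pooled inverse-variance weight


@dataclass
class PiecewiseFit:
    r2_plateau: float
    r2_int: float
    t_extr: float | None  # s, < 0 for piecewise
    slope: float | None  # nm^2/s, <= 0
    model_choice: str  # {"piecewise", "constant"}
    sse: float
    sse_constant: float


def eligible_onsets(
    intervals: list[ProximalInterval], frame_interval: float, exclusion_window: float = 600.0
) -> list[int]:
    """Onset frames usable for alignment.

    A left-censored interval has no observed onset; an onset is also dropped
    when another proximal interval ends within ``exclusion_window`` seconds
    before it (the preceding event contaminates the approach).
    """
    out = []
    for k, iv in enumerate(intervals):
        if iv.left_censored:
            continue
        ok = True
        for j, other in enumerate(intervals):
            if j == k:
                continue
            gap = (iv.start_frame - other.end_frame) * frame_interval
            if 0 < gap <= exclusion_window:
                ok = False
                break
        if ok:
            out.append(iv.start_frame)
    return out


def align_on_onsets(
    series_set: list[DistanceTimeSeries],
    intervals_set: list[list[ProximalInterval]],
    exclusion_window: float = 600.0,
    max_lag: float | None = None,
) -> AlignedCurve:
    """Pool squared distances by lag relative to each eligible onset.

    Only frames strictly before the onset contribute: the onset frame itself
    is sub-threshold by construction (it begins the proximal state), so
    including it would plant an artificial terminal drop in every curve,
    shuffled controls included.  Weights are inverse squared per-frame
    precision (1/sigma_d^2); per-lag outputs are the weighted mean, the
    weighted standard error and the number of distinct contributing series.
    """
    acc: dict[int, list[tuple[float, float, int]]] = {}
    for si, (series, intervals) in enumerate(zip(series_set, intervals_set)):
        dt = series.frame_interval
        onsets = eligible_onsets(intervals, dt, exclusion_window)
        for onset in onsets:
            for j in range(onset):
                if not series.valid[j] or not np.isfinite(series.distance[j]):
                    continue
                lag_frames = j - onset  # <= 0
                if max_lag is not None and -lag_frames * dt > max_lag:
                    continue
                w = 1.0 / series.sigma_d[j] ** 2
                acc.setdefault(lag_frames, []).append((series.distance[j] ** 2, w, si))
    if not acc:
        raise ValueError("no eligible onsets in the supplied series")
    dt0 = series_set[0].frame_interval
    lag_frames = np.array(sorted(acc.keys()))
    lags = lag_frames * dt0
    mean_sq = np.empty(len(lags))
    sem = np.empty(len(lags))
    weight = np.empty(len(lags))
    n_series = np.empty(len(lags), dtype=int)
    for k, lf in enumerate(lag_frames):
        vals = np.array([v for v, _, _ in acc[lf]])
        ws = np.array([w for _, w, _ in acc[lf]])
        m = np.sum(ws * vals) / np.sum(ws)
        mean_sq[k] = m
        weight[k] = np.sum(ws)
        n_eff = np.sum(ws) ** 2 / np.sum(ws**2)
        var = np.sum(ws * (vals - m) ** 2) / np.sum(ws)
        sem[k] = np.sqrt(var / max(n_eff - 1.0, 1.0))
        n_series[k] = len({s for _, _, s in acc[lf]})
    return AlignedCurve(lags=lags, mean_sq=mean_sq, sem=sem, n_series=n_series,
                        weight=weight)


def fit_piecewise(
    curve: AlignedCurve,
    min_decrease_lags: int = 3,
    sse_margin: float = 0.10,
    min_lags: int = 6,
    min_series_per_lag: int = 3,
) -> PiecewiseFit:
    """Weighted plateau-plus-linear-decrease fit with exhaustive breakpoints.

    The linear segment runs from (t_extr, R2_plateau) to (0, R2_int) with
    continuity at the breakpoint.  Lags backed by fewer than
    ``min_series_per_lag`` series are dropped (their pooled means are
    dominated by single trajectories).  The piecewise model is selected only
    when its decreasing segment is supported by at least
    ``min_decrease_lags`` lag points, its slope is negative, and it reduces
    the weighted SSE of the constant model by at least the fractional
    ``sse_margin``; otherwise the constant model is reported (no CR).
    """
    t = np.asarray(curve.lags, float)
    y = np.asarray(curve.mean_sq, float)
    if curve.weight is not None:
        w = np.asarray(curve.weight, float)
    else:
        w = 1.0 / np.maximum(np.asarray(curve.sem, float), 1e-300) ** 2
    ok = np.isfinite(y) & np.isfinite(w) & (w > 0)
    if curve.n_series is not None and min_series_per_lag > 1:
        ok &= np.asarray(curve.n_series) >= min_series_per_lag
    t, y, w = t[ok], y[ok], w[ok]
    if len(t) < min_lags:
        raise ValueError(f"need >= {min_lags} lags with data, got {len(t)}")
    if np.all(w == 0):
        raise ValueError("all weights zero: non-identifiable")

    p_const = np.sum(w * y) / np.sum(w)
    sse_const = float(np.sum(w * (y - p_const) ** 2))

    best = None
    for j, t_e in enumerate(t):
        if t_e >= 0:
            continue
        n_dec = int(np.sum(t > t_e))  # points strictly inside the decrease
        if n_dec < min_decrease_lags:
            continue
        u = np.where(t > t_e, 1.0 - t / t_e, 0.0)  # 0 at breakpoint, 1 at lag 0
        a = 1.0 - u  # coefficient of plateau
        # WLS normal equations for (P, I)
        saa = np.sum(w * a * a)
        sau = np.sum(w * a * u)
        suu = np.sum(w * u * u)
        say = np.sum(w * a * y)
        suy = np.sum(w * u * y)
        det = saa * suu - sau * sau
        if det <= 0:
            continue
        p = (say * suu - sau * suy) / det
        i_ = (saa * suy - sau * say) / det
        if i_ >= p:
            continue  # not a decrease
        resid = y - (a * p + u * i_)
        sse = float(np.sum(w * resid**2))
        if best is None or sse < best[0]:
            best = (sse, p, i_, t_e)

    if best is not None:
        sse, p, i_, t_e = best
        if sse_const - sse >= sse_margin * sse_const:
            return PiecewiseFit(
                r2_plateau=float(p),
                r2_int=float(i_),
                t_extr=float(t_e),
                slope=float((i_ - p) / (0.0 - t_e)),
                model_choice="piecewise",
                sse=sse,
                sse_constant=sse_const,
            )
    return PiecewiseFit(
        r2_plateau=float(p_const),
        r2_int=float(p_const),
        t_extr=None,
        slope=None,
        model_choice="constant",
        sse=sse_const,
        sse_constant=sse_const,
    )


def cr_from_slope(fit: PiecewiseFit, s_reporters: float) -> float:
    """Closing rate in kb/s from a piecewise fit.

    Uses the linear map between squared distance and unextruded genomic
    length anchored at (R2_plateau <-> s_reporters) and (R2_int <-> 0):
    CR = |slope| * s_reporters / (R2_plateau - R2_int), which reduces to
    s_reporters / |t_extr|.
    """
    if fit.model_choice != "piecewise":
        raise ValueError("CR is only defined for the piecewise model")
    if fit.r2_plateau <= fit.r2_int:
        raise ValueError("R2_plateau must exceed R2_int for the genomic calibration")
    cr_bp_s = abs(fit.slope) * s_reporters / (fit.r2_plateau - fit.r2_int)
    return cr_bp_s / 1000.0


def shuffle_control(series: DistanceTimeSeries, rng: np.random.Generator) -> DistanceTimeSeries:
    """Permute time points within the series, preserving the valid mask.

    Distances and their precisions move together; the multiset of measured
    values is exactly preserved, destroying any processive signature.
    """
    idx = np.flatnonzero(series.valid & np.isfinite(series.distance))
    perm = rng.permutation(idx)
    d = series.distance.copy()
    s = series.sigma_d.copy()
    d[idx] = series.distance[perm]
    s[idx] = series.sigma_d[perm]
    return DistanceTimeSeries(
        times=series.times.copy(),
        distance=d,
        sigma_d=s,
        valid=series.valid.copy(),
        condition=series.condition,
        region=series.region,
        seed=series.seed,
    )


def bootstrap_cr(
    series_set: list[DistanceTimeSeries],
    intervals_set: list[list[ProximalInterval]],
    s_reporters: float,
    n_bootstrap: int = 5000,
    seed: int = 0,
    min_series: int = 15,
    exclusion_window: float = 600.0,
    max_lag: float | None = None,
    **fit_kwargs,
) -> dict:
    """Bootstrap distribution of the CR over series resampling.

    Draws resample whole series with replacement; a draw is kept when at
    least ``min_series`` distinct series contribute eligible onsets and the
    piecewise model is selected.  Reports the median and 10-90 percentiles of
    the CR over kept draws; zero kept draws is an 'undetectable' result, not
    an error.
    """
    n = len(series_set)
    with_onsets = [
        i
        for i in range(n)
        if eligible_onsets(intervals_set[i], series_set[i].frame_interval, exclusion_window)
    ]
    if len(with_onsets) < min_series:
        raise ValueError(
            f"only {len(with_onsets)} series with eligible onsets (< {min_series})"
        )
    rng = np.random.default_rng(seed)
    crs = []
    n_kept = 0
    n_piecewise = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        sub_series = [series_set[i] for i in idx]
        sub_intervals = [intervals_set[i] for i in idx]
        contributing = len(
            {
                int(i)
                for i in idx
                if eligible_onsets(
                    intervals_set[i], series_set[i].frame_interval, exclusion_window
                )
            }
        )
        if contributing < min_series:
            continue
        try:
            curve = align_on_onsets(sub_series, sub_intervals, exclusion_window,
                                    max_lag=max_lag)
            fit = fit_piecewise(curve, **fit_kwargs)
        except ValueError:
            continue
        if fit.model_choice != "piecewise":
            continue
        n_piecewise += 1
        try:
            crs.append(cr_from_slope(fit, s_reporters))
            n_kept += 1
        except ValueError:
            continue
    out = {
        "n_total": n_bootstrap,
        "n_kept": n_kept,
        "n_piecewise": n_piecewise,
        "detectable": n_kept > 0,
    }
    if n_kept:
        crs = np.array(crs)
        out.update(
            median=float(np.median(crs)),
            p10=float(np.percentile(crs, 10)),
            p90=float(np.percentile(crs, 90)),
            draws=crs,
        )
    return out
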