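"""Proximal-state segmentation of distance time series and summary metrics.

A proximal state is a temporally sustained interval of small anchor-anchor
distances: a maximal run of frames below a spatial threshold, tolerating up
to ``gap_tolerance`` consecutive above-threshold or invalid frames inside
the run, and kept only if its duration reaches a temporal threshold.
Intervals touching the series boundary are flagged censored; frequency
excludes left-censored onsets (an event already in progress at t=0 is not a
new transition) and lifetimes use non-censored intervals only.

Summary metrics pool frames over series and come with percentile bootstrap
confidence intervals obtained by resampling whole series with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import DistanceTimeSeries

__all__ = [
    "SegmentationParams",
    "ProximalInterval",
    "ProximalMetrics",
    "segment_proximal",
    "proximal_metrics",
    "calibrate_temporal_threshold",
    "calibrate_spatial_threshold",
]


@dataclass
class SegmentationParams:
    spatial_threshold: float  # nm
    temporal_threshold: float  # s
    gap_tolerance: int = 1  # frames allowed above threshold inside a run

    def __post_init__(self) -> None:
        if self.spatial_threshold <= 0 or self.temporal_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be >= 0")


@dataclass
class ProximalInterval:
    start_frame: int
    end_frame: int  # inclusive
    left_censored: bool = False
    right_censored: bool = False

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class ProximalMetrics:
    fraction: float
    frequency: float  # onsets per observed hour
    mean_lifetime: float | None  # minutes; None when no uncensored interval
    n_series: int
    n_intervals: int
    fraction_ci: tuple[float, float] | None = None
    frequency_ci: tuple[float, float] | None = None
    lifetime_ci: tuple[float, float] | None = None


def segment_proximal(
    series: DistanceTimeSeries, params: SegmentationParams
) -> list[ProximalInterval]:
    """Segment one series into proximal intervals.

    Runs start and end on valid sub-threshold frames; interior gaps of at
    most ``gap_tolerance`` consecutive non-qualifying frames (above threshold
    or invalid) are bridged.  A run qualifies when
    n_frames * frame_interval >= temporal_threshold.
    """
    d = series.distance
    n = len(d)
    if n == 0:
        return []
    below = series.valid & np.isfinite(d) & (d < params.spatial_threshold)
    dt = series.frame_interval
    intervals: list[ProximalInterval] = []
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        start = i
        end = i
        j = i + 1
        gap = 0
        while j < n:
            if below[j]:
                end = j
                gap = 0
            else:
                gap += 1
                if gap > params.gap_tolerance:
                    break
            j += 1
        if (end - start + 1) * dt >= params.temporal_threshold:
            intervals.append(
                ProximalInterval(
                    start_frame=start,
                    end_frame=end,
                    left_censored=(start == 0) or not series.valid[start - 1],
                    right_censored=(end == n - 1) or not series.valid[end + 1],
                )
            )
        i = end + 1 + max(gap, 1)
    return intervals


def _series_stats(
    series: DistanceTimeSeries, params: SegmentationParams
) -> dict:
    ivs = segment_proximal(series, params)
    dt = series.frame_interval
    n_prox = sum(iv.n_frames for iv in ivs)
    return {
        "n_prox": n_prox,
        "n_valid": series.n_valid(),
        "n_onsets": sum(1 for iv in ivs if not iv.left_censored),
        "hours": series.n_valid() * dt / 3600.0,
        "lifetimes_min": [
            iv.n_frames * dt / 60.0
            for iv in ivs
            if not (iv.left_censored or iv.right_censored)
        ],
        "intervals": ivs,
    }


def proximal_metrics(
    series_set: list[DistanceTimeSeries],
    params: SegmentationParams,
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> ProximalMetrics:
    """Pooled fraction, frequency and mean lifetime with bootstrap CIs.

    fraction = proximal frames / valid frames; frequency = non-left-censored
    onsets per pooled observed hour; lifetime = mean duration of fully
    uncensored intervals.  CIs are 2.5-97.5 percentiles over ``n_bootstrap``
    resamplings of whole series.
    """
    if not series_set:
        raise ValueError("need >= 1 series")
    stats = [_series_stats(s, params) for s in series_set]

    def pool(idx):
        n_prox = sum(stats[i]["n_prox"] for i in idx)
        n_valid = sum(stats[i]["n_valid"] for i in idx)
        n_on = sum(stats[i]["n_onsets"] for i in idx)
        hours = sum(stats[i]["hours"] for i in idx)
        lt = [x for i in idx for x in stats[i]["lifetimes_min"]]
        frac = n_prox / n_valid if n_valid else 0.0
        freq = n_on / hours if hours else 0.0
        life = float(np.mean(lt)) if lt else None
        return frac, freq, life

    n = len(stats)
    frac, freq, life = pool(range(n))
    n_intervals = sum(len(st["intervals"]) for st in stats)
    fci = qci = lci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        bf, bq, bl = [], [], []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            f, q, l = pool(idx)
            bf.append(f)
            bq.append(q)
            if l is not None:
                bl.append(l)
        fci = tuple(np.percentile(bf, [2.5, 97.5]))
        qci = tuple(np.percentile(bq, [2.5, 97.5]))
        lci = tuple(np.percentile(bl, [2.5, 97.5])) if bl else None
    return ProximalMetrics(
        fraction=frac,
        frequency=freq,
        mean_lifetime=life,
        n_series=n,
        n_intervals=n_intervals,
        fraction_ci=fci,
        frequency_ci=qci,
        lifetime_ci=lci,
    )


def calibrate_temporal_threshold(
    auxin_series: list[DistanceTimeSeries],
    params_grid: list[SegmentationParams],
    target_fraction_range: tuple[float, float] = (0.01, 0.10),
    untreated_series: list[DistanceTimeSeries] | None = None,
) -> list[dict]:
    """Threshold sweep anchored on the cohesin-depleted condition.

    Returns, for each parameter set whose depleted-condition proximal
    fraction falls inside ``target_fraction_range``, the depleted fraction
    and (when untreated series are supplied) the untreated metrics at the
    same thresholds.  If no set qualifies, the nearest-achieving set is
    returned with ``in_target=False``.
    """
    if not auxin_series:
        raise ValueError("depleted ensemble must be non-empty")
    lo, hi = target_fraction_range
    rows = []
    for p in params_grid:
        m = proximal_metrics(auxin_series, p, n_bootstrap=0)
        row = {
            "params": p,
            "auxin_fraction": m.fraction,
            "in_target": lo <= m.fraction <= hi,
        }
        if untreated_series is not None:
            row["untreated"] = proximal_metrics(untreated_series, p, n_bootstrap=0)
        rows.append(row)
    kept = [r for r in rows if r["in_target"]]
    if kept:
        return kept
    nearest = min(rows, key=lambda r: min(abs(r["auxin_fraction"] - lo), abs(r["auxin_fraction"] - hi)))
    return [nearest]


def calibrate_spatial_threshold(
    closed_state_distances: np.ndarray, quantile: float = 0.90
) -> float:
    """Spatial threshold as a quantile of distances during true closed states.

    Intended to be fed distances observed during ground-truth closed frames
    of matched simulations (default: 90th percentile).
    """
    d = np.asarray(closed_state_distances, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) == 0:
        raise ValueError("no closed-state distances supplied")
    return float(np.quantile(d, quantile))
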