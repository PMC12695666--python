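"""Simulation-vs-experiment comparison and grid-based parameter inference.

A :class:`MetricBundle` condenses one condition into the quantities the
comparison uses: the p(s) curve (when contact data exist), the two-point MSD
curve of the reporter-reporter vector, the distance distribution summarized
by its nine deciles, and the proximal-state fraction, frequency and mean
lifetime.  The deviation between two bundles is an equally weighted mean of
per-metric sub-scores: mean squared log-ratio over shared support for
curves, squared relative error for scalars (and for the decile vector,
averaged).  Scores are >= 0 and vanish only for identical bundles.

The inference procedure scans a (cohesin density, residence time) grid at
fixed motor speed, simulating each cell under identical analysis settings,
and extracts the 10%/25% lowest-deviation parameter sets.  Recovery of known
ground truth on synthetic references validates the whole loop.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import polymer, proximal, synth
from .extrusion import CTCFSite, ExtrusionParams
from .polymer import PolymerParams
from .proximal import SegmentationParams
from .synth import DistanceTimeSeries, MeasurementModel

__all__ = [
    "MetricBundle",
    "DeviationSurface",
    "summarize",
    "deviation",
    "grid_search",
    "best_sets",
    "recovery_check",
]

_DECILES = np.arange(0.1, 1.0, 0.1)


@dataclass
class MetricBundle:
    distance_deciles: np.ndarray  # 9 values, nm
    msd_lags: np.ndarray  # s
    msd: np.ndarray  # nm^2
    proximal_fraction: float
    proximal_frequency: float  # per hour
    proximal_lifetime: float | None  # minutes
    frame_interval: float  # s
    p_of_s: tuple[np.ndarray, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.distance_deciles, self.msd_lags, self.msd):
            h.update(np.asarray(arr, float).tobytes())
        scalars = [
            self.proximal_fraction,
            self.proximal_frequency,
            -1.0 if self.proximal_lifetime is None else self.proximal_lifetime,
            self.frame_interval,
        ]
        h.update(np.array(scalars).tobytes())
        if self.p_of_s is not None:
            h.update(np.asarray(self.p_of_s[0], float).tobytes())
            h.update(np.asarray(self.p_of_s[1], float).tobytes())
        return h.hexdigest()


@dataclass
class DeviationSurface:
    densities: np.ndarray  # per Mb
    residences: np.ndarray  # minutes
    motor_speed: float  # kb/s
    scores: np.ndarray  # (n_density, n_residence), NaN where unassessed
    sub_scores: dict  # metric -> (n_density, n_residence)
    assessed: np.ndarray  # bool mask

    def n_assessed(self) -> int:
        return int(self.assessed.sum())


def summarize(
    series_set: list[DistanceTimeSeries],
    seg_params: SegmentationParams,
    contact: np.ndarray | None = None,
    contact_bin_bp: int = 2000,
    msd_lag_frames: tuple[int, ...] = (1, 2, 4, 8, 16),
) -> MetricBundle:
    """Condense a series ensemble (plus optional contact map) into a bundle.

    Deterministic given inputs; the segmentation parameters and binning are
    recorded so only identically configured bundles are compared.
    """
    if not series_set:
        raise ValueError("empty series set")
    cadences = {round(s.frame_interval, 6) for s in series_set}
    if len(cadences) > 1:
        raise ValueError(f"mixed cadences in ensemble: {sorted(cadences)}")
    dt = series_set[0].frame_interval
    pooled = np.concatenate([s.distance[s.valid] for s in series_set])
    pooled = pooled[np.isfinite(pooled)]
    deciles = np.quantile(pooled, _DECILES)
    vectors = []
    for s in series_set:
        if s.spots1 is None or s.spots2 is None:
            raise ValueError("series lack spot coordinates needed for the MSD metric")
        r = s.spots2 - s.spots1
        r = np.where(s.valid[:, None], r, np.nan)
        vectors.append(r)
    lags = np.array(msd_lag_frames, dtype=int)
    msd = polymer.two_point_msd(vectors, lags)
    pm = proximal.proximal_metrics(series_set, seg_params, n_bootstrap=0)
    ps = None
    if contact is not None:
        ps = polymer.p_of_s(contact, bin_bp=contact_bin_bp)
    return MetricBundle(
        distance_deciles=deciles,
        msd_lags=lags * dt,
        msd=msd,
        proximal_fraction=pm.fraction,
        proximal_frequency=pm.frequency,
        proximal_lifetime=pm.mean_lifetime,
        frame_interval=dt,
        p_of_s=ps,
        meta={
            "seg": (seg_params.spatial_threshold, seg_params.temporal_threshold,
                    seg_params.gap_tolerance),
            "msd_lag_frames": tuple(msd_lag_frames),
            "contact_bin_bp": contact_bin_bp,
            "n_series": len(series_set),
        },
    )


def _curve_score(sim: np.ndarray, ref: np.ndarray) -> float:
    ok = np.isfinite(sim) & np.isfinite(ref) & (sim > 0) & (ref > 0)
    if not np.any(ok):
        raise ValueError("empty shared support between curves")
    return float(np.mean(np.log(sim[ok] / ref[ok]) ** 2))


def _scalar_score(sim: float, ref: float) -> float:
    # squared relative error; a zero reference with a non-zero simulation is
    # capped at 1 so surfaces stay finite and comparable
    if ref == 0:
        return 0.0 if sim == 0 else 1.0
    return float(((sim - ref) / ref) ** 2)


def deviation(sim: MetricBundle, ref: MetricBundle, weights: dict | None = None) -> tuple[float, dict]:
    """Deviation score between two bundles; returns (total, sub-scores).

    Sub-scores: 'p_of_s' and 'msd' are mean squared log-ratios over shared
    support; 'distances' averages the squared relative errors of the nine
    deciles; 'fraction', 'frequency', 'lifetime' are squared relative
    errors.  The total is the (weighted) mean of the available sub-scores.
    """
    if abs(sim.frame_interval - ref.frame_interval) > 1e-9:
        raise ValueError("cadence mismatch between bundles")
    if sim.meta.get("seg") != ref.meta.get("seg"):
        raise ValueError("segmentation parameters differ between bundles")
    sub: dict[str, float] = {}
    sub["distances"] = float(
        np.mean([_scalar_score(a, b) for a, b in zip(sim.distance_deciles, ref.distance_deciles)])
    )
    if len(sim.msd_lags) != len(ref.msd_lags) or not np.allclose(
        sim.msd_lags, ref.msd_lags
    ):
        raise ValueError("MSD lag grids differ between bundles")
    sub["msd"] = _curve_score(sim.msd, ref.msd)
    sub["fraction"] = _scalar_score(sim.proximal_fraction, ref.proximal_fraction)
    sub["frequency"] = _scalar_score(sim.proximal_frequency, ref.proximal_frequency)
    if sim.proximal_lifetime is not None and ref.proximal_lifetime is not None:
        sub["lifetime"] = _scalar_score(sim.proximal_lifetime, ref.proximal_lifetime)
    if sim.p_of_s is not None and ref.p_of_s is not None:
        s1, p1 = sim.p_of_s
        s2, p2 = ref.p_of_s
        shared = np.intersect1d(s1, s2)
        if len(shared) == 0:
            raise ValueError("empty shared support for p(s)")
        i1 = np.searchsorted(s1, shared)
        i2 = np.searchsorted(s2, shared)
        sub["p_of_s"] = _curve_score(p1[i1], p2[i2])
    if weights is None:
        weights = {k: 1.0 for k in sub}
    tot_w = sum(weights.get(k, 0.0) for k in sub)
    total = sum(weights.get(k, 0.0) * v for k, v in sub.items()) / tot_w
    return float(total), sub


def grid_search(
    region_length: int,
    anchor_a: float,
    anchor_b: float,
    sites: list[CTCFSite],
    model: MeasurementModel,
    seg_params: SegmentationParams,
    densities: np.ndarray,
    residences: np.ndarray,
    motor_speed: float,
    ref_bundle: MetricBundle,
    n_series: int,
    seed: int,
    pparams: PolymerParams | None = None,
    observable: str = "gaussian-ou",
    stall_probability: float = 0.5,
    assess: np.ndarray | None = None,
    weights: dict | None = None,
) -> DeviationSurface:
    """Deviation surface over the (density, residence) grid at one motor speed.

    Every cell is simulated and summarized with identical analysis settings;
    cells excluded by the ``assess`` mask are reported as NaN (unassessed).
    """
    densities = np.asarray(densities, float)
    residences = np.asarray(residences, float)
    nd, nr = len(densities), len(residences)
    if assess is None:
        assess = np.ones((nd, nr), dtype=bool)
    scores = np.full((nd, nr), np.nan)
    subs: dict[str, np.ndarray] = {}
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(nd * nr) % (2**31 - 1)
    for i, rho in enumerate(densities):
        for j, tau in enumerate(residences):
            if not assess[i, j]:
                continue
            ep = ExtrusionParams(
                density=float(rho),
                residence_time=float(tau),
                motor_speed=motor_speed,
                region_length=region_length,
                stall_probability=stall_probability,
            )
            series = synth.emulate_experiment(
                region_length, anchor_a, anchor_b, sites, ep, model,
                n_series=n_series, seed=int(cell_seeds[i * nr + j]),
                pparams=pparams, observable=observable,
            )
            bundle = summarize(series, seg_params,
                               msd_lag_frames=ref_bundle.meta["msd_lag_frames"])
            total, sub = deviation(bundle, ref_bundle, weights=weights)
            scores[i, j] = total
            for k, v in sub.items():
                subs.setdefault(k, np.full((nd, nr), np.nan))[i, j] = v
    return DeviationSurface(
        densities=densities,
        residences=residences,
        motor_speed=motor_speed,
        scores=scores,
        sub_scores=subs,
        assessed=assess & np.isfinite(scores),
    )


def best_sets(surface: DeviationSurface, q: float) -> np.ndarray:
    """Boolean mask of the ceil(q * n_assessed) lowest-score cells.

    Ties are broken lexicographically toward (lower density, lower residence)
    so masks are deterministic; masks for nested q are nested.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    n_assessed = surface.n_assessed()
    if n_assessed == 0:
        raise ValueError("no assessed cells")
    k = int(np.ceil(q * n_assessed))
    cells = [
        (surface.scores[i, j], surface.densities[i], surface.residences[j], i, j)
        for i in range(len(surface.densities))
        for j in range(len(surface.residences))
        if surface.assessed[i, j]
    ]
    cells.sort(key=lambda c: (c[0], c[1], c[2]))
    mask = np.zeros_like(surface.assessed)
    for c in cells[:k]:
        mask[c[3], c[4]] = True
    return mask


def recovery_check(
    truth_density: float,
    truth_residence: float,
    densities: np.ndarray,
    residences: np.ndarray,
    motor_speed: float,
    region_length: int,
    anchor_a: float,
    anchor_b: float,
    sites: list[CTCFSite],
    model: MeasurementModel,
    seg_params: SegmentationParams,
    n_series: int,
    seed: int,
    observable: str = "gaussian-ou",
) -> dict:
    """Generate a synthetic reference at known truth and try to recover it.

    Passes when the truth density's grid column intersects the 10% best set
    of the resulting deviation surface.
    """
    if truth_density not in np.asarray(densities) or truth_residence not in np.asarray(residences):
        raise ValueError("truth parameters must lie on the grid")
    ep = ExtrusionParams(
        density=truth_density,
        residence_time=truth_residence,
        motor_speed=motor_speed,
        region_length=region_length,
    )
    ss = np.random.SeedSequence(seed)
    ref_seed, grid_seed = (int(x % (2**31 - 1)) for x in ss.generate_state(2))
    ref_series = synth.emulate_experiment(
        region_length, anchor_a, anchor_b, sites, ep, model,
        n_series=n_series, seed=ref_seed, observable=observable,
    )
    ref_bundle = summarize(ref_series, seg_params)
    surface = grid_search(
        region_length, anchor_a, anchor_b, sites, model, seg_params,
        densities, residences, motor_speed, ref_bundle,
        n_series=n_series, seed=grid_seed, observable=observable,
    )
    mask10 = best_sets(surface, 0.10)
    di = int(np.flatnonzero(np.asarray(densities) == truth_density)[0])
    passed = bool(mask10[di, :].any())
    return {
        "passed": passed,
        "surface": surface,
        "mask10": mask10,
        "mask25": best_sets(surface, 0.25),
        "truth": (truth_density, truth_residence),
    }
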