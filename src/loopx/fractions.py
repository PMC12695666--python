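"""Mixture decomposition of anchor-anchor distance distributions.

The observed radial distance distribution is modelled as a convex mixture of
three ingredients: (i) the proximal-state distribution, estimated by kernel
smoothing of distances inside segmented proximal intervals of untreated
series; (ii) the open-state distribution, estimated from cohesin-depleted
series (or density-0 simulations); and (iii) an extruding family of
ideal-chain radial (Maxwell) laws indexed by an effective genomic separation
s_eff on a grid in (0, s_total], whose squared spatial scale interpolates
linearly in s_eff between the measurement-noise floor and the open-state
scale, so the s_eff = s_total member reproduces the open distribution.

Mixture weights are maximum-likelihood estimates under simplex constraints,
obtained with EM (weights are the only free parameters, so each EM step is a
closed-form responsibility average).  A model-free upper bound on the open
fraction follows from the tail inequality observed_mass >= f_open *
open_mass in any distance bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "ComponentDistributions",
    "StateFractions",
    "build_components",
    "fit_fractions",
    "open_fraction_bound",
]


def _maxwell_pdf(d: np.ndarray, sigma: float) -> np.ndarray:
    """Radial density of a 3D isotropic Gaussian with per-axis scale sigma."""
    d = np.asarray(d, dtype=float)
    return np.sqrt(2.0 / np.pi) * d**2 * np.exp(-(d**2) / (2.0 * sigma**2)) / sigma**3


class _ReflectedKDE:
    """Gaussian KDE on [0, inf) with reflection correction at zero.

    Evaluation cost is O(n_sample * n_eval); datasets are subsampled to
    ``max_points`` (the density estimate is already smooth at that size).
    """

    def __init__(self, sample: np.ndarray, max_points: int = 4000):
        sample = np.asarray(sample, dtype=float)
        sample = sample[np.isfinite(sample)]
        if len(sample) < 2:
            raise ValueError("need >= 2 finite observations for a KDE")
        self.n = len(sample)
        if len(sample) > max_points:
            idx = np.random.default_rng(0).choice(len(sample), max_points, replace=False)
            sample = sample[idx]
        self._kde = gaussian_kde(sample)

    def __call__(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        out = self._kde(d) + self._kde(-d)
        return np.where(d >= 0, out, 0.0)


@dataclass
class ComponentDistributions:
    """Fixed component densities used by the mixture fit."""

    proximal: _ReflectedKDE
    open: _ReflectedKDE
    s_grid: np.ndarray  # effective separations, bp
    extruding_sigmas: np.ndarray  # per-axis scales, nm (NaN marks the p_open member)
    s_total: float

    @property
    def n_components(self) -> int:
        return 2 + len(self.s_grid)

    def component_sigma(self, k: int) -> float:
        return float(self.extruding_sigmas[k])

    def evaluate(self, d: np.ndarray) -> np.ndarray:
        """Density matrix of shape (n_components, len(d))."""
        d = np.asarray(d, dtype=float)
        open_row = self.open(d)
        rows = [self.proximal(d), open_row]
        for sig in self.extruding_sigmas:
            if np.isnan(sig):  # the s_eff = s_total member is p_open itself
                rows.append(open_row)
            else:
                rows.append(_maxwell_pdf(d, sig))
        return np.vstack(rows)

    def mean_distances(self) -> np.ndarray:
        """Mean distance of each extruding member (Maxwell mean 2*sigma*sqrt(2/pi))."""
        out = []
        for sig in self.extruding_sigmas:
            if np.isnan(sig):
                finite = self.extruding_sigmas[np.isfinite(self.extruding_sigmas)]
                top = 6 * finite.max() if len(finite) else 5000.0
                grid = np.linspace(0, top + 1, 2000)
                p = self.open(grid)
                out.append(np.trapezoid(grid * p, grid) / np.trapezoid(p, grid))
            else:
                out.append(2.0 * sig * np.sqrt(2.0 / np.pi))
        return np.array(out)


@dataclass
class StateFractions:
    f_proximal: float
    f_open: float
    f_extruding: float
    weights: np.ndarray  # full weight vector (proximal, open, extruding grid...)
    log_likelihood: float
    n_iter: int
    bootstrap: dict = field(default_factory=dict)


def build_components(
    proximal_distances: np.ndarray,
    open_distances: np.ndarray,
    s_total: float,
    n_grid: int = 20,
    noise_sigma_d: float = 0.0,
    min_open_frames: int = 1000,
) -> ComponentDistributions:
    """Assemble the fixed component densities.

    The extruding family has per-axis variance
    sigma^2(s_eff) = sigma_n^2 + (sigma_open^2 - sigma_n^2) * s_eff/s_total,
    with sigma_open^2 moment-matched to the depleted sample (E[d^2]/3) and
    sigma_n^2 = noise_sigma_d^2 / 2 the per-axis measurement floor.  The last
    grid point (s_eff = s_total) is the empirical open density itself.
    """
    prox = np.asarray(proximal_distances, float)
    op = np.asarray(open_distances, float)
    prox = prox[np.isfinite(prox)]
    op = op[np.isfinite(op)]
    if len(prox) == 0 or len(op) == 0:
        raise ValueError("both proximal and open inputs must be non-empty")
    if len(op) < min_open_frames:
        warnings.warn(
            f"depleted ensemble has only {len(op)} frames; open-state density "
            "may be imprecise",
            stacklevel=2,
        )
    sigma_open2 = float(np.mean(op**2)) / 3.0
    sigma_n2 = noise_sigma_d**2 / 2.0
    if sigma_n2 >= sigma_open2:
        raise ValueError("noise floor exceeds the open-state scale")
    # the grid starts at s_total/8: states with less unextruded DNA than that
    # are observationally proximal-like, and including them would make the
    # extruding family collinear with the proximal component
    s_grid = np.geomspace(s_total / 8.0, s_total, max(n_grid, 1))
    s_grid[-1] = s_total
    sigmas = np.sqrt(sigma_n2 + (sigma_open2 - sigma_n2) * s_grid / s_total)
    sigmas[-1] = np.nan  # degenerate to empirical p_open
    return ComponentDistributions(
        proximal=_ReflectedKDE(prox),
        open=_ReflectedKDE(op),
        s_grid=s_grid,
        extruding_sigmas=sigmas,
        s_total=float(s_total),
    )


def fit_fractions(
    observed: np.ndarray,
    components: ComponentDistributions,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    min_frames: int = 1000,
    series_samples: list[np.ndarray] | None = None,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> StateFractions:
    """Maximum-likelihood mixture weights over {proximal, open, extruding grid}.

    EM with simplex-constrained weights; f_extruding is the total weight on
    the extruding grid.  Optional bootstrap over series (``series_samples``,
    a partition of the observations) attaches percentile CIs.
    """
    d = np.asarray(observed, float)
    d = d[np.isfinite(d)]
    if len(d) < min_frames:
        warnings.warn(f"only {len(d)} observed frames (< {min_frames})", stacklevel=2)

    def _em(x: np.ndarray) -> tuple[np.ndarray, float, int]:
        pmat = components.evaluate(x)  # (K, n)
        pmat = np.maximum(pmat, 1e-300)
        k = pmat.shape[0]
        w = np.full(k, 1.0 / k)
        prev = -np.inf
        for it in range(1, max_iter + 1):
            mix = w @ pmat  # (n,)
            ll = float(np.sum(np.log(mix)))
            resp = (w[:, None] * pmat) / mix[None, :]
            w = resp.mean(axis=1)
            if prev != -np.inf and abs(ll - prev) <= tol * abs(prev):
                break
            prev = ll
        else:
            raise RuntimeError(
                f"EM did not converge in {max_iter} iterations (last ll={prev:.6g})"
            )
        # tie-break toward the open state: members near s_eff = s_total are
        # near-duplicates of p_open (exactly so for the last grid point), so
        # the MLE weight split between them and f_open is ill-determined.
        # Reassign a member's weight to f_open when the likelihood cost is
        # below 0.02 nats per reassigned observation -- the scale of the
        # KDE-vs-parametric mismatch, far below the divergence of genuinely
        # distinct extruding scales.
        ll = float(np.sum(np.log(w @ pmat)))
        for j in range(k - 1, 1, -1):
            if w[j] <= 0:
                continue
            w2 = w.copy()
            w2[1] += w2[j]
            w2[j] = 0.0
            ll2 = float(np.sum(np.log(w2 @ pmat)))
            if ll2 >= ll - 0.02 * w[j] * len(x):
                w, ll = w2, ll2
        return w, ll, it

    w, ll, n_iter = _em(d)
    boot: dict = {}
    if n_bootstrap > 0 and series_samples:
        rng = np.random.default_rng(seed)
        draws = []
        ns = len(series_samples)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, ns, size=ns)
            x = np.concatenate([series_samples[i] for i in idx])
            x = x[np.isfinite(x)]
            bw, _, _ = _em(x)
            draws.append([bw[0], bw[1], bw[2:].sum()])
        draws = np.array(draws)
        boot = {
            "draws": draws,
            "ci": {
                name: tuple(np.percentile(draws[:, j], [2.5, 97.5]))
                for j, name in enumerate(["proximal", "open", "extruding"])
            },
        }
    return StateFractions(
        f_proximal=float(w[0]),
        f_open=float(w[1]),
        f_extruding=float(w[2:].sum()),
        weights=w,
        log_likelihood=ll,
        n_iter=n_iter,
        bootstrap=boot,
    )


def open_fraction_bound(
    observed: np.ndarray,
    open_sample: np.ndarray,
    n_bins: int = 6,
    max_rel_err: float = 0.20,
    min_frames: int = 1000,
) -> float:
    """Model-free upper bound on the open-state fraction.

    For any distance bin b, observed_mass(b) >= f_open * open_mass(b), so
    f_open <= min_b observed_mass(b)/open_mass(b).  The minimum is taken over
    upper-tail bins (edges at open-sample quantiles above the median) whose
    open mass is estimated with binomial relative error below
    ``max_rel_err``; the result is clipped to [0, 1].
    """
    obs = np.asarray(observed, float)
    op = np.asarray(open_sample, float)
    obs = obs[np.isfinite(obs)]
    op = op[np.isfinite(op)]
    if len(obs) < min_frames or len(op) < min_frames:
        warnings.warn("fewer than 1000 frames in an input sample", stacklevel=2)
    qs = np.linspace(0.5, 1.0, n_bins + 1)
    edges = np.quantile(op, qs)
    edges[-1] = np.inf
    bound = np.inf
    for lo, hi in zip(edges[:-1], edges[1:]):
        p_open_mass = np.mean((op >= lo) & (op < hi))
        if p_open_mass <= 0:
            continue
        rel_err = np.sqrt((1.0 - p_open_mass) / (len(op) * p_open_mass))
        if rel_err >= max_rel_err:
            continue
        p_obs_mass = np.mean((obs >= lo) & (obs < hi))
        bound = min(bound, p_obs_mass / p_open_mass)
    if not np.isfinite(bound):
        warnings.warn("no bins with sufficiently precise open mass; bound = 1", stacklevel=2)
        return 1.0
    return float(np.clip(bound, 0.0, 1.0))
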