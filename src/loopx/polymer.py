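"""Bead-spring (Rouse) polymer dynamics coupled to a 1D extrusion trajectory.

The chain has one bead per ``monomer_bp`` (1 kb default) connected by
harmonic springs of natural scale ``bond_length``; each extruder adds a
harmonic bond between the beads holding its two legs, updated whenever the
1D configuration changes.  Dynamics are overdamped Langevin (free-draining,
no excluded volume by default), for which the equilibrium ensemble of any
fixed bond topology is an exact Gaussian network -- a property used to draw
equilibrated initial conformations directly instead of burning in.

The time mapping is set by ``monomer_diffusion`` D (nm^2/s): the spring
relaxation rate is kappa = 3 D / b^2 and the integrator step defaults to
0.08 / kappa, comfortably inside the Euler-Maruyama stability region for
backbone-plus-extruder connectivities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial import cKDTree

from .extrusion import Trajectory1D

__all__ = [
    "PolymerParams",
    "ConformationSeries",
    "simulate_coupled",
    "contact_map",
    "p_of_s",
    "two_point_msd",
    "equilibrium_chain",
]


@dataclass
class PolymerParams:
    """Physical parameters of the coupled polymer model.

    ``bond_length`` and ``monomer_diffusion`` are calibration inputs, not
    measured constants: together they set the spatial scale of distances and
    the physical time mapping of the dynamics.
    """

    monomer_bp: int = 1000
    bond_length: float = 40.0  # nm
    monomer_diffusion: float = 2.0e4  # nm^2/s
    time_step: float | None = None  # s; None -> 0.08 * b^2 / (3 D)
    excluded_volume: str = "off"  # {"off", "soft"}
    ev_amplitude: float = 1.0  # soft-repulsion prefactor, units of kappa*nm
    contact_radius: float = 100.0  # nm, default for contact calling

    def __post_init__(self) -> None:
        if min(self.monomer_bp, self.bond_length, self.monomer_diffusion) <= 0:
            raise ValueError("monomer_bp, bond_length, monomer_diffusion must be > 0")
        if self.excluded_volume not in ("off", "soft"):
            raise ValueError("excluded_volume must be 'off' or 'soft'")

    @property
    def kappa(self) -> float:
        """Spring relaxation rate 3 D / b^2 (1/s)."""
        return 3.0 * self.monomer_diffusion / self.bond_length**2

    @property
    def dt(self) -> float:
        return self.time_step if self.time_step is not None else 0.08 / self.kappa


@dataclass
class ConformationSeries:
    """Sampled 3D conformations mirroring the 1D trajectory's sample times."""

    times: np.ndarray  # s
    coords: np.ndarray  # (n_frames, n_beads, 3) nm
    bonds: list[np.ndarray]  # per-frame (n_extruders, 2) bead index pairs
    params: PolymerParams
    monomer_bp: int = 1000
    rng_seed: int = 0

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def bead_of(self, position_bp: float) -> int:
        b = int(position_bp // self.monomer_bp)
        return min(max(b, 0), self.n_beads - 1)

    def locus_series(self, position_bp: float) -> np.ndarray:
        """(n_frames, 3) positions of the bead containing ``position_bp``."""
        return self.coords[:, self.bead_of(position_bp), :]


def equilibrium_chain(
    n_beads: int,
    bond_length: float,
    rng: np.random.Generator,
    extruder_bonds: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one exact equilibrium conformation of the harmonic bond network.

    With no extruder bonds this is a Gaussian random walk.  With bonds, the
    Boltzmann distribution is a zero-mean Gaussian whose per-axis precision
    matrix is (3/b^2) times the bond-graph Laplacian; bead 0 is pinned at the
    origin to remove the free translation mode and the remaining coordinates
    are sampled through a Cholesky factor of the reduced Laplacian.
    """
    if extruder_bonds is None or len(extruder_bonds) == 0:
        steps = rng.normal(scale=bond_length / np.sqrt(3.0), size=(n_beads - 1, 3))
        return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    lap = np.zeros((n_beads, n_beads))
    pairs = [(i, i + 1) for i in range(n_beads - 1)] + [tuple(p) for p in extruder_bonds]
    for i, j in pairs:
        lap[i, i] += 1.0
        lap[j, j] += 1.0
        lap[i, j] -= 1.0
        lap[j, i] -= 1.0
    red = lap[1:, 1:]
    c = cholesky(red, lower=True)  # red = c c^T
    z = rng.standard_normal((n_beads - 1, 3))
    # covariance per axis is (b^2/3) red^-1, so x = (b/sqrt(3)) c^-T z
    x = solve_triangular(c.T, z, lower=False) * (bond_length / np.sqrt(3.0))
    return np.vstack([np.zeros(3), x])


@njit(cache=True)
def _integrate_soft(x, n_steps, kdt, noise, bond_i, bond_j, seed, ev_amp, ev_sigma):
    """As :func:`_integrate` plus a soft pairwise repulsion.

    Repulsion displacement per step is ev_amp * kdt * (1 - r/sigma) along the
    separation vector for r < sigma.  The pair loop is O(N^2); intended for
    short chains where chain crossing matters, not for production runs.
    """
    np.random.seed(seed)
    n = x.shape[0]
    f = np.empty_like(x)
    for _ in range(n_steps):
        for i in range(n):
            for d in range(3):
                f[i, d] = 0.0
        for i in range(n - 1):
            for d in range(3):
                dxd = x[i + 1, d] - x[i, d]
                f[i, d] += dxd
                f[i + 1, d] -= dxd
        for k in range(bond_i.shape[0]):
            i = bond_i[k]
            j = bond_j[k]
            for d in range(3):
                dxd = x[j, d] - x[i, d]
                f[i, d] += dxd
                f[j, d] -= dxd
        for i in range(n):
            for j in range(i + 1, n):
                r2 = 0.0
                for d in range(3):
                    dd = x[j, d] - x[i, d]
                    r2 += dd * dd
                if r2 < ev_sigma * ev_sigma and r2 > 1e-12:
                    r = np.sqrt(r2)
                    mag = ev_amp * (1.0 - r / ev_sigma) / r
                    for d in range(3):
                        push = mag * (x[j, d] - x[i, d])
                        f[i, d] -= push
                        f[j, d] += push
        for i in range(n):
            for d in range(3):
                x[i, d] += kdt * f[i, d] + noise * np.random.standard_normal()
    return x


@njit(cache=True)
def _integrate(x, n_steps, kdt, noise, bond_i, bond_j, seed):
    """Euler-Maruyama steps for backbone + extruder harmonic springs.

    kdt = kappa * dt (dimensionless); noise = sqrt(2 D dt) in nm.
    """
    np.random.seed(seed)
    n = x.shape[0]
    f = np.empty_like(x)
    for _ in range(n_steps):
        g = np.random.standard_normal(n * 3).reshape(n, 3)
        for d in range(3):
            f[0, d] = x[1, d] - x[0, d]
            f[n - 1, d] = x[n - 2, d] - x[n - 1, d]
        for i in range(1, n - 1):
            for d in range(3):
                f[i, d] = x[i + 1, d] + x[i - 1, d] - 2.0 * x[i, d]
        for k in range(bond_i.shape[0]):
            i = bond_i[k]
            j = bond_j[k]
            for d in range(3):
                dxd = x[j, d] - x[i, d]
                f[i, d] += dxd
                f[j, d] -= dxd
        for i in range(n):
            for d in range(3):
                x[i, d] += kdt * f[i, d] + noise * g[i, d]
    return x


def _frame_bonds(traj1d: Trajectory1D, frame: int, ratio: int, n_beads: int) -> np.ndarray:
    f = traj1d.frames[frame]
    if len(f["left"]) == 0:
        return np.empty((0, 2), dtype=np.int64)
    li = np.minimum(f["left"] * ratio, n_beads - 1)
    ri = np.minimum(f["right"] * ratio, n_beads - 1)
    return np.stack([li, ri], axis=1).astype(np.int64)


def simulate_coupled(
    traj1d: Trajectory1D,
    pparams: PolymerParams,
    seed: int,
) -> ConformationSeries:
    """Integrate the polymer through the sampled 1D trajectory.

    The chain starts from an exact equilibrium draw of the first frame's bond
    network, then advances by overdamped Langevin dynamics between successive
    1D samples, with extruder bonds refreshed at every sample.  Deterministic
    for a fixed seed.
    """
    ep = traj1d.params
    if ep.lattice_unit % pparams.monomer_bp != 0:
        raise ValueError("monomer_bp must divide lattice_unit")
    ratio = ep.lattice_unit // pparams.monomer_bp
    n_beads = ep.region_length // pparams.monomer_bp
    dt = pparams.dt
    kdt = pparams.kappa * dt
    if kdt >= 0.25:
        raise ValueError(
            f"integration step too large (kappa*dt={kdt:.3f}); reduce time_step"
        )
    noise = np.sqrt(2.0 * pparams.monomer_diffusion * dt)
    soft = pparams.excluded_volume == "soft"

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    step_seeds = ss.spawn(1)[0].generate_state(max(traj1d.n_frames, 1)) % (2**31 - 1)

    bonds0 = _frame_bonds(traj1d, 0, ratio, n_beads)
    x = equilibrium_chain(n_beads, pparams.bond_length, rng, bonds0)
    n_frames = traj1d.n_frames
    coords = np.empty((n_frames, n_beads, 3))
    coords[0] = x
    bonds_list = [bonds0]
    for k in range(1, n_frames):
        span = traj1d.times[k] - traj1d.times[k - 1]
        n_steps = max(int(np.round(span / dt)), 1)
        bonds = _frame_bonds(traj1d, k - 1, ratio, n_beads)
        bi = np.ascontiguousarray(bonds[:, 0])
        bj = np.ascontiguousarray(bonds[:, 1])
        if soft:
            x = _integrate_soft(
                x, n_steps, kdt, noise, bi, bj, int(step_seeds[k]),
                pparams.ev_amplitude, pparams.bond_length,
            )
        else:
            x = _integrate(x, n_steps, kdt, noise, bi, bj, int(step_seeds[k]))
        coords[k] = x
        bonds_list.append(_frame_bonds(traj1d, k, ratio, n_beads))
    # bond-energy divergence check
    seg = np.diff(coords[-1], axis=0)
    if not np.all(np.isfinite(coords)) or np.max(np.sum(seg**2, axis=1)) > 1e6 * pparams.bond_length**2:
        raise FloatingPointError("integration diverged; use a smaller time_step")
    return ConformationSeries(
        times=traj1d.times.copy(),
        coords=coords,
        bonds=bonds_list,
        params=pparams,
        monomer_bp=pparams.monomer_bp,
        rng_seed=seed,
    )


def contact_map(
    series: ConformationSeries, bin_bp: int = 2000, radius_nm: float | None = None
) -> np.ndarray:
    """Symmetric contact-frequency matrix at ``bin_bp`` resolution.

    A contact is a bead pair within ``radius_nm``; frequencies are averaged
    over frames and normalized per bead-pair count in each bin pair.
    """
    r = radius_nm if radius_nm is not None else series.params.contact_radius
    if r <= 0:
        raise ValueError("radius must be > 0")
    n_beads = series.n_beads
    ratio = max(bin_bp // series.monomer_bp, 1)
    n_bins = int(np.ceil(n_beads / ratio))
    counts = np.zeros((n_bins, n_bins))
    n_frames = series.coords.shape[0]
    bead_bin = np.arange(n_beads) // ratio
    for f in range(n_frames):
        tree = cKDTree(series.coords[f])
        pairs = tree.query_pairs(r, output_type="ndarray")
        if len(pairs):
            bi = bead_bin[pairs[:, 0]]
            bj = bead_bin[pairs[:, 1]]
            np.add.at(counts, (bi, bj), 1.0)
            np.add.at(counts, (bj, bi), 1.0)
    # bead pairs per bin pair, then average over frames
    per_bin = np.bincount(bead_bin, minlength=n_bins).astype(float)
    norm = np.outer(per_bin, per_bin)
    np.fill_diagonal(norm, per_bin * (per_bin - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / (norm * n_frames)
    freq[~np.isfinite(freq)] = 0.0
    np.fill_diagonal(freq, 1.0)
    return freq


def p_of_s(cmap: np.ndarray, bin_bp: int = 1, log_bins: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal-averaged contact frequency versus genomic separation.

    Returns (s, p) with s in the units implied by ``bin_bp`` per matrix bin.
    """
    n = cmap.shape[0]
    if cmap.shape[0] != cmap.shape[1] or not np.allclose(cmap, cmap.T, atol=1e-12):
        raise ValueError("contact map must be square and symmetric")
    s = np.arange(1, n) * bin_bp
    p = np.array([np.mean(np.diag(cmap, k)) for k in range(1, n)])
    if log_bins:
        edges = np.unique(np.geomspace(1, n - 1, 40).astype(int))
        sb, pb = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = slice(lo - 1, hi)
            sb.append(np.sqrt(s[sel][0] * s[sel][-1]))
            pb.append(p[sel].mean())
        return np.array(sb), np.array(pb)
    return s, p


def two_point_msd(vector_series: list[np.ndarray], lags: np.ndarray) -> np.ndarray:
    """MSD of the anchor-anchor vector at the given integer frame lags.

    Each element of ``vector_series`` is an (n_frames, 3) array; NaN frames
    (invalid measurements) are ignored pairwise.
    """
    lags = np.asarray(lags, dtype=int)
    out = np.zeros(len(lags))
    cnt = np.zeros(len(lags))
    for r in vector_series:
        if r.shape[0] < 2:
            raise ValueError("each series needs >= 2 frames")
        for k, lag in enumerate(lags):
            if lag == 0 or lag >= r.shape[0]:
                continue
            d = r[lag:] - r[:-lag]
            sq = np.sum(d**2, axis=1)
            ok = np.isfinite(sq)
            out[k] += np.nansum(sq[ok])
            cnt[k] += ok.sum()
    with np.errstate(invalid="ignore"):
        msd = np.where(cnt > 0, out / np.maximum(cnt, 1), np.nan)
    msd[lags == 0] = 0.0
    return msd
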