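"""Stochastic 1D lattice model of cohesin loop extrusion with dynamic CTCF barriers.

The genomic region is discretized into lattice sites of ``lattice_unit`` bp
(1 kb by default).  Cohesin complexes ("extruders") load at random adjacent
site pairs, reel DNA symmetrically at ``motor_speed`` (each leg moves outward
at half the total speed), unbind exponentially with mean ``residence_time``,
and stall with probability ``stall_probability`` when a leg attempts to step
onto a bound CTCF site whose motif faces the approaching leg.  CTCF sites
bind and unbind dynamically so that each site's stationary occupancy equals
its ``occupancy_target``.

Time is advanced in fixed Bernoulli steps with all per-step probabilities
kept at or below 0.2, which approximates the underlying exponential rates to
within a few percent.  The heavy stepping loop is compiled with numba; the
single-step operations :func:`update_ctcf` and :func:`step_extruders` are
plain Python and operate on small configurations for inspection and testing.

Orientation convention: ``'+'`` means the motif points toward increasing
genomic coordinates and blocks legs travelling leftward (toward decreasing
coordinates); ``'-'`` blocks legs travelling rightward.  A convergent pair
flanking a TAD therefore reads ``'+'`` at the left anchor and ``'-'`` at the
right anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "ExtrusionParams",
    "CTCFSite",
    "Extruder",
    "LoopConfiguration",
    "LifetimeEvent",
    "Trajectory1D",
    "build_ctcf_landscape",
    "update_ctcf",
    "step_extruders",
    "simulate_extrusion",
]


@dataclass
class ExtrusionParams:
    """Parameters of cohesin dynamics on the lattice.

    Parameters
    ----------
    density : float
        Cohesin complexes per Mb (stationary target).
    residence_time : float
        Mean chromatin-bound lifetime of a cohesin complex, minutes.
    motor_speed : float
        Total two-sided reeling rate in kb/s; each leg moves at half this.
    stall_probability : float
        Probability of stalling on encountering a bound, blocking CTCF site.
    lattice_unit : int
        Base pairs per lattice site.
    region_length : int
        Simulated region length in bp; must be a multiple of ``lattice_unit``.
    """

    density: float
    residence_time: float
    motor_speed: float
    region_length: int
    stall_probability: float = 0.5
    lattice_unit: int = 1000

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.residence_time <= 0:
            raise ValueError("residence_time must be > 0")
        if self.motor_speed < 0:
            raise ValueError("motor_speed must be >= 0")
        if not 0.0 <= self.stall_probability <= 1.0:
            raise ValueError("stall_probability must be in [0, 1]")
        if self.lattice_unit <= 0:
            raise ValueError("lattice_unit must be > 0")
        if self.region_length % self.lattice_unit != 0:
            raise ValueError("region_length must be divisible by lattice_unit")

    @property
    def n_sites(self) -> int:
        return self.region_length // self.lattice_unit

    @property
    def n_target(self) -> float:
        """Stationary expected number of extruders (density x length)."""
        return self.density * self.region_length / 1e6


@dataclass
class CTCFSite:
    """A CTCF binding site with its own residence time and occupancy target."""

    position: int  # bp, 0-based
    orientation: str  # '+' or '-'
    residence_time: float  # minutes
    occupancy_target: float = 0.5
    bound: bool = True

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")
        if self.residence_time <= 0:
            raise ValueError("site residence_time must be > 0")
        if not 0.0 <= self.occupancy_target < 1.0:
            raise ValueError("occupancy_target must be in [0, 1)")


@dataclass
class Extruder:
    """One cohesin complex: two legs on the lattice plus stall bookkeeping.

    ``left_pin``/``right_pin`` hold the index (into the site list) of the
    CTCF molecule pinning that leg, or -1 when the leg is free.
    """

    left_leg: int
    right_leg: int
    left_pin: int = -1
    right_pin: int = -1
    load_time: float = 0.0

    def __post_init__(self) -> None:
        if self.left_leg > self.right_leg:
            raise ValueError("left_leg must be <= right_leg")

    @property
    def left_stalled(self) -> bool:
        return self.left_pin >= 0

    @property
    def right_stalled(self) -> bool:
        return self.right_pin >= 0


@dataclass
class LoopConfiguration:
    """Snapshot of all extruders (CTCF state lives in the site list)."""

    extruders: list[Extruder] = field(default_factory=list)

    def leg_sites(self) -> set[int]:
        occ: set[int] = set()
        for e in self.extruders:
            occ.add(e.left_leg)
            occ.add(e.right_leg)
        return occ


@dataclass
class LifetimeEvent:
    """A completed extruder lifetime (loaded and unloaded in-run)."""

    load_time: float
    unload_time: float
    initial_size: int  # bp
    final_size: int  # bp
    touched_boundary: bool


@dataclass
class Trajectory1D:
    """Sampled 1D extrusion trajectory.

    ``frames`` holds per-sample arrays of leg positions (lattice indices) and
    stall flags; ``ctcf_bound`` is an (n_frames, n_sites) boolean matrix.
    """

    times: np.ndarray
    frames: list[dict]
    ctcf_bound: np.ndarray
    params: ExtrusionParams
    sites: list[CTCFSite]
    rng_seed: int
    lifetimes: list[LifetimeEvent] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def extruder_counts(self) -> np.ndarray:
        return np.array([len(f["left"]) for f in self.frames])

    def legs_bp(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Leg positions of frame ``i`` in bp (site centers)."""
        u = self.params.lattice_unit
        f = self.frames[i]
        return f["left"] * u + u // 2, f["right"] * u + u // 2


def build_ctcf_landscape(
    peaks: list[tuple[int, str, float]],
    genomewide_residence: float = 2.5,
    occupancy_target: float = 0.5,
) -> list[CTCFSite]:
    """Convert ChIP-seq-like peaks into CTCF sites with local residence times.

    Each site's residence time scales linearly with its peak strength,
    normalized so the mean over the landscape equals ``genomewide_residence``
    (2.5 min by default, a genome-wide average for CTCF).

    Parameters
    ----------
    peaks : list of (position bp, orientation, strength)
        Strengths must be non-negative and not all zero.
    """
    if not peaks:
        return []
    strengths = np.array([p[2] for p in peaks], dtype=float)
    if np.any(strengths < 0):
        raise ValueError("peak strengths must be non-negative")
    mean_strength = strengths.mean()
    if mean_strength == 0:
        raise ValueError("all-zero peak strengths: invalid landscape")
    return [
        CTCFSite(
            position=int(pos),
            orientation=orient,
            residence_time=genomewide_residence * s / mean_strength,
            occupancy_target=occupancy_target,
            bound=True,
        )
        for (pos, orient, s) in peaks
    ]


def update_ctcf(sites: list[CTCFSite], dt: float, rng: np.random.Generator) -> list[CTCFSite]:
    """Advance CTCF binding states by ``dt`` seconds (in place; returns sites).

    Bound sites unbind with probability 1 - exp(-dt/tau); unbound sites bind
    with probability 1 - exp(-dt * k_on) where
    k_on = occupancy / ((1 - occupancy) * tau), giving stationary occupancy
    equal to the target.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return sites
    for s in sites:
        tau_s = s.residence_time * 60.0
        if s.bound:
            if rng.random() < 1.0 - np.exp(-dt / tau_s):
                s.bound = False
        else:
            k_on = s.occupancy_target / ((1.0 - s.occupancy_target) * tau_s)
            if rng.random() < 1.0 - np.exp(-dt * k_on):
                s.bound = True
    return sites


def _site_lattice_map(sites: list[CTCFSite], params: ExtrusionParams) -> dict[int, int]:
    out = {}
    for i, s in enumerate(sites):
        lat = s.position // params.lattice_unit
        if not 0 <= lat < params.n_sites:
            raise ValueError(f"CTCF site at {s.position} bp outside region")
        out[lat] = i
    return out


def step_extruders(
    config: LoopConfiguration,
    dt: float,
    params: ExtrusionParams,
    sites: list[CTCFSite],
    rng: np.random.Generator,
    t: float = 0.0,
    load: bool = True,
) -> LoopConfiguration:
    """Advance extruder legs, unbinding and loading by ``dt`` seconds.

    Pure-Python single step mirroring the compiled engine: legs step outward
    one lattice site with probability (motor_speed/2)*dt/lattice_unit, waiting
    (without a stall draw) if blocked by another leg or the region boundary;
    a move onto a bound, blocking CTCF site triggers a single stall draw which
    either pins the leg (until that CTCF molecule unbinds) or lets it pass.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return config
    v_leg = params.motor_speed / 2.0 * 1000.0  # bp/s
    p_move = v_leg * dt / params.lattice_unit
    if p_move > 1.0:
        raise ValueError("dt too large: a leg would move more than one site per step")
    tau_s = params.residence_time * 60.0
    p_off = 1.0 - np.exp(-dt / tau_s)
    site_at = _site_lattice_map(sites, params)
    n_sites = params.n_sites

    # unbinding
    survivors = [e for e in config.extruders if rng.random() >= p_off]

    # loading (Poisson number of events at rate N_target / tau)
    if load and params.n_target > 0:
        occ = set()
        for e in survivors:
            occ.add(e.left_leg)
            occ.add(e.right_leg)
        n_new = rng.poisson(dt * params.n_target / tau_s)
        for _ in range(n_new):
            for _attempt in range(10):
                s0 = int(rng.integers(0, n_sites - 1))
                if s0 not in occ and (s0 + 1) not in occ:
                    survivors.append(Extruder(s0, s0 + 1, load_time=t))
                    occ.add(s0)
                    occ.add(s0 + 1)
                    break

    # movement, legs in random order
    occ = {}
    for i, e in enumerate(survivors):
        occ[e.left_leg] = i
        occ[e.right_leg] = i
    legs = [(i, side) for i in range(len(survivors)) for side in (0, 1)]
    rng.shuffle(legs)
    for i, side in legs:
        e = survivors[i]
        pin = e.left_pin if side == 0 else e.right_pin
        if pin >= 0:
            if sites[pin].bound:
                continue  # still pinned
            if side == 0:
                e.left_pin = -1
            else:
                e.right_pin = -1
        if rng.random() >= p_move:
            continue
        cur = e.left_leg if side == 0 else e.right_leg
        target = cur - 1 if side == 0 else cur + 1
        if target < 0 or target >= n_sites or target in occ:
            continue  # blocked: wait, no stall draw
        j = site_at.get(target)
        if j is not None and sites[j].bound:
            blocking = sites[j].orientation == ("+" if side == 0 else "-")
            if blocking and rng.random() < params.stall_probability:
                if side == 0:
                    e.left_pin = j
                else:
                    e.right_pin = j
                continue
        del occ[cur]
        occ[target] = i
        if side == 0:
            e.left_leg = target
        else:
            e.right_leg = target
    return LoopConfiguration(extruders=survivors)


@njit(cache=True)
def _engine(
    n_steps,
    dt,
    n_sites,
    p_move,
    p_off,
    stall_p,
    load_rate_dt,  # expected loading events per step
    ctcf_at,  # lattice -> site index or -1
    site_block_plus,  # per site: True if orientation '+'
    site_p_unbind,
    site_p_bind,
    site_bound0,
    sample_steps,  # sorted step indices at which to sample
    cap,
    max_ev,
    seed,
):
    np.random.seed(seed)
    site_bound = site_bound0.copy()
    n_ctcf = site_bound.shape[0]

    left = np.full(cap, -1, np.int64)
    right = np.full(cap, -1, np.int64)
    lpin = np.full(cap, -1, np.int64)
    rpin = np.full(cap, -1, np.int64)
    load_t = np.zeros(cap)
    init_sz = np.zeros(cap, np.int64)
    touched = np.zeros(cap, np.bool_)
    active = np.zeros(cap, np.bool_)
    occ = np.full(n_sites, -1, np.int64)

    n_samples = sample_steps.shape[0]
    # flat sample output
    max_out = n_samples * cap
    out_counts = np.zeros(n_samples, np.int64)
    out_left = np.full(max_out, -1, np.int64)
    out_right = np.full(max_out, -1, np.int64)
    out_lstall = np.zeros(max_out, np.bool_)
    out_rstall = np.zeros(max_out, np.bool_)
    out_ctcf = np.zeros((n_samples, n_ctcf), np.bool_)

    # completed-lifetime log
    ev_load = np.zeros(max_ev)
    ev_unload = np.zeros(max_ev)
    ev_init = np.zeros(max_ev, np.int64)
    ev_final = np.zeros(max_ev, np.int64)
    ev_touch = np.zeros(max_ev, np.bool_)
    n_ev = 0

    leg_order = np.empty(2 * cap, np.int64)
    sample_ptr = 0

    for step in range(n_steps):
        t = step * dt

        # CTCF dynamics
        for j in range(n_ctcf):
            if site_bound[j]:
                if np.random.random() < site_p_unbind[j]:
                    site_bound[j] = False
            else:
                if np.random.random() < site_p_bind[j]:
                    site_bound[j] = True

        # extruder unbinding
        for i in range(cap):
            if active[i] and np.random.random() < p_off:
                active[i] = False
                occ[left[i]] = -1
                occ[right[i]] = -1
                if n_ev < max_ev:
                    ev_load[n_ev] = load_t[i]
                    ev_unload[n_ev] = t
                    ev_init[n_ev] = init_sz[i]
                    ev_final[n_ev] = right[i] - left[i]
                    ev_touch[n_ev] = touched[i]
                    n_ev += 1

        # loading
        n_new = np.random.poisson(load_rate_dt)
        for _ in range(n_new):
            for _attempt in range(10):
                s0 = np.random.randint(0, n_sites - 1)
                if occ[s0] == -1 and occ[s0 + 1] == -1:
                    slot = -1
                    for i in range(cap):
                        if not active[i]:
                            slot = i
                            break
                    if slot >= 0:
                        active[slot] = True
                        left[slot] = s0
                        right[slot] = s0 + 1
                        lpin[slot] = -1
                        rpin[slot] = -1
                        load_t[slot] = t
                        init_sz[slot] = 1
                        touched[slot] = False
                        occ[s0] = slot
                        occ[s0 + 1] = slot
                    break

        # movement in random leg order
        n_legs = 0
        for i in range(cap):
            if active[i]:
                leg_order[n_legs] = 2 * i
                leg_order[n_legs + 1] = 2 * i + 1
                n_legs += 2
        for k in range(n_legs - 1, 0, -1):
            j = np.random.randint(0, k + 1)
            tmp = leg_order[k]
            leg_order[k] = leg_order[j]
            leg_order[j] = tmp
        for k in range(n_legs):
            i = leg_order[k] // 2
            side = leg_order[k] % 2
            pin = lpin[i] if side == 0 else rpin[i]
            if pin >= 0:
                if site_bound[pin]:
                    continue
                if side == 0:
                    lpin[i] = -1
                else:
                    rpin[i] = -1
            if np.random.random() >= p_move:
                continue
            cur = left[i] if side == 0 else right[i]
            target = cur - 1 if side == 0 else cur + 1
            if target < 0 or target >= n_sites:
                touched[i] = True
                continue
            if occ[target] != -1:
                continue
            j = ctcf_at[target]
            if j >= 0 and site_bound[j]:
                blocking = site_block_plus[j] if side == 0 else not site_block_plus[j]
                if blocking and np.random.random() < stall_p:
                    if side == 0:
                        lpin[i] = j
                    else:
                        rpin[i] = j
                    continue
            occ[cur] = -1
            occ[target] = i
            if side == 0:
                left[i] = target
            else:
                right[i] = target

        # sampling
        if sample_ptr < n_samples and step == sample_steps[sample_ptr]:
            base = sample_ptr * cap
            c = 0
            for i in range(cap):
                if active[i]:
                    out_left[base + c] = left[i]
                    out_right[base + c] = right[i]
                    out_lstall[base + c] = lpin[i] >= 0
                    out_rstall[base + c] = rpin[i] >= 0
                    c += 1
            out_counts[sample_ptr] = c
            for j in range(n_ctcf):
                out_ctcf[sample_ptr, j] = site_bound[j]
            sample_ptr += 1

    return (
        out_counts,
        out_left,
        out_right,
        out_lstall,
        out_rstall,
        out_ctcf,
        ev_load[:n_ev],
        ev_unload[:n_ev],
        ev_init[:n_ev],
        ev_final[:n_ev],
        ev_touch[:n_ev],
    )


def choose_dt(params: ExtrusionParams, sites: list[CTCFSite], max_prob: float = 0.2) -> float:
    """Largest fixed step keeping every per-step Bernoulli probability <= max_prob."""
    candidates = [max_prob * params.residence_time * 60.0]
    v_leg = params.motor_speed / 2.0 * 1000.0
    if v_leg > 0:
        candidates.append(max_prob * params.lattice_unit / v_leg)
    for s in sites:
        tau_s = s.residence_time * 60.0
        candidates.append(max_prob * tau_s)
        if s.occupancy_target > 0:
            k_on = s.occupancy_target / ((1.0 - s.occupancy_target) * tau_s)
            candidates.append(max_prob / k_on)
    return min(candidates)


def simulate_extrusion(
    params: ExtrusionParams,
    sites: list[CTCFSite],
    duration: float,
    sample_interval: float,
    seed: int,
    burnin: float | None = None,
) -> Trajectory1D:
    """Run the lattice extrusion simulation and sample configurations.

    Parameters
    ----------
    duration : float
        Simulated seconds of sampled time (after burn-in).
    sample_interval : float
        Seconds between samples.
    burnin : float, optional
        Discarded equilibration time; defaults to 3 x residence_time.

    Returns
    -------
    Trajectory1D
        Sampled configurations; time zero is the first sample after burn-in.
    """
    if duration < sample_interval:
        raise ValueError("duration must be >= sample_interval")
    if burnin is None:
        burnin = 3.0 * params.residence_time * 60.0
    dt = choose_dt(params, sites)
    # snap dt to an exact divisor of the sample interval so the emitted
    # cadence is exactly what was requested
    dt = sample_interval / np.ceil(sample_interval / dt)
    n_sites = params.n_sites
    site_at = np.full(n_sites, -1, dtype=np.int64)
    lat_map = _site_lattice_map(sites, params)
    for lat, j in lat_map.items():
        site_at[lat] = j
    n_ctcf = len(sites)
    block_plus = np.array([s.orientation == "+" for s in sites], dtype=bool)
    p_unbind = np.empty(n_ctcf)
    p_bind = np.empty(n_ctcf)
    for j, s in enumerate(sites):
        tau_s = s.residence_time * 60.0
        p_unbind[j] = 1.0 - np.exp(-dt / tau_s)
        k_on = s.occupancy_target / ((1.0 - s.occupancy_target) * tau_s) if s.occupancy_target > 0 else 0.0
        p_bind[j] = 1.0 - np.exp(-dt * k_on)
    bound0 = np.array([s.bound for s in sites], dtype=bool)

    v_leg = params.motor_speed / 2.0 * 1000.0
    p_move = v_leg * dt / params.lattice_unit
    tau_s = params.residence_time * 60.0
    p_off = 1.0 - np.exp(-dt / tau_s)
    load_rate_dt = params.n_target * dt / tau_s
    cap = max(int(4 * params.n_target) + 8, 64)

    n_steps = int(np.ceil((burnin + duration) / dt)) + 1
    first = int(np.round(burnin / dt))
    stride = max(int(np.round(sample_interval / dt)), 1)
    sample_steps = np.arange(first, n_steps, stride, dtype=np.int64)

    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    (
        counts,
        fl,
        fr,
        fls,
        frs,
        ctcf_out,
        ev_load,
        ev_unload,
        ev_init,
        ev_final,
        ev_touch,
    ) = _engine(
        n_steps,
        dt,
        n_sites,
        p_move,
        p_off,
        params.stall_probability,
        load_rate_dt,
        site_at,
        block_plus,
        p_unbind,
        p_bind,
        bound0,
        sample_steps,
        cap,
        int(3.0 * (burnin + duration) / tau_s * max(params.n_target, 1.0)) + 1024,
        rng_seed,
    )

    frames = []
    for k in range(len(sample_steps)):
        c = counts[k]
        base = k * cap
        frames.append(
            {
                "left": fl[base : base + c].copy(),
                "right": fr[base : base + c].copy(),
                "left_stalled": fls[base : base + c].copy(),
                "right_stalled": frs[base : base + c].copy(),
            }
        )
    times = sample_steps * dt - burnin
    u = params.lattice_unit
    lifetimes = [
        LifetimeEvent(
            load_time=float(ev_load[i]),
            unload_time=float(ev_unload[i]),
            initial_size=int(ev_init[i]) * u,
            final_size=int(ev_final[i]) * u,
            touched_boundary=bool(ev_touch[i]),
        )
        for i in range(len(ev_load))
    ]
    return Trajectory1D(
        times=np.asarray(times, dtype=float),
        frames=frames,
        ctcf_bound=ctcf_out,
        params=params,
        sites=[replace(s) for s in sites],
        rng_seed=seed,
        lifetimes=lifetimes,
    )
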