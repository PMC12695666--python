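"""Shortest unextruded 1D path between loci and open/extruding/closed calls.

An extruded loop collapses the DNA between its legs: travelling "through" a
loop costs zero genomic length.  The shortest 1D path between two loci is
computed on a graph whose nodes are the loci plus every extruder leg in the
whole region, with backbone edges weighted by genomic gaps and a zero-weight
edge between the two legs of each extruder.  Loops outside the interval can
shorten the path, so the whole region is always searched.

State definitions (1D): *closed* when the path length is at most one lattice
unit; *open* when the path equals the genomic separation and no leg lies
strictly between the loci; *extruding* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .extrusion import LoopConfiguration, Trajectory1D

__all__ = ["PathResult", "shortest_path_1d", "classify_state", "loop_metrics", "processivity"]

OPEN, EXTRUDING, CLOSED = "open", "extruding", "closed"


@dataclass
class PathResult:
    length: float  # bp of unextruded DNA on the shortest path
    loops_used: int
    state: str


def _path_from_legs(
    lefts: np.ndarray, rights: np.ndarray, a: float, b: float
) -> tuple[float, int]:
    """Shortest-path length and number of loop shortcuts between a and b."""
    a, b = float(min(a, b)), float(max(a, b))
    if len(lefts) == 0:
        return b - a, 0
    pos = np.concatenate([[a, b], lefts, rights]).astype(float)
    nodes, inv = np.unique(pos, return_inverse=True)
    n = len(nodes)
    ia, ib = inv[0], inv[1]
    if ia == ib:
        return 0.0, 0
    # parallel edges keep the minimum weight (a loop shortcut beats the
    # backbone gap between the same two nodes)
    edges: dict[tuple[int, int], float] = {}
    for k in range(n - 1):
        edges[(k, k + 1)] = float(nodes[k + 1] - nodes[k])
    loop_pairs = set()
    m = len(lefts)
    for e in range(m):
        u, v = inv[2 + e], inv[2 + m + e]
        if u != v:
            key = (min(u, v), max(u, v))
            edges[key] = min(edges.get(key, np.inf), 0.0)
            loop_pairs.add(key)
    rows = [k[0] for k in edges]
    cols = [k[1] for k in edges]
    w = list(edges.values())
    g = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    dist, pred = dijkstra(g, directed=False, indices=ia, return_predecessors=True)
    length = float(dist[ib])
    # walk predecessors to count zero-weight loop edges on the path
    loops_used = 0
    cur = ib
    while cur != ia:
        prv = pred[cur]
        pair = (min(cur, prv), max(cur, prv))
        if pair in loop_pairs and np.isclose(dist[cur], dist[prv]):
            loops_used += 1
        cur = prv
    return length, loops_used


def shortest_path_1d(
    config: LoopConfiguration,
    a: float,
    b: float,
    lattice_unit: float = 1000.0,
    region_length: float | None = None,
) -> PathResult:
    """Shortest unextruded DNA path (bp) between loci ``a`` and ``b``.

    Positions are in bp.  ``lattice_unit`` sets the closed-state tolerance.
    """
    if a == b:
        raise ValueError("a and b must differ")
    if region_length is not None:
        for x in (a, b):
            if not 0 <= x <= region_length:
                raise ValueError(f"position {x} outside region")
    lefts = np.array([e.left_leg for e in config.extruders], dtype=float)
    rights = np.array([e.right_leg for e in config.extruders], dtype=float)
    length, loops_used = _path_from_legs(lefts, rights, a, b)
    state = _classify(length, loops_used, lefts, rights, a, b, lattice_unit)
    return PathResult(length=length, loops_used=loops_used, state=state)


def _classify(length, loops_used, lefts, rights, a, b, lattice_unit) -> str:
    a, b = min(a, b), max(a, b)
    if length <= lattice_unit:
        return CLOSED
    inside = np.any((lefts > a) & (lefts < b)) or np.any((rights > a) & (rights < b))
    if length == b - a and not inside:
        return OPEN
    return EXTRUDING


def classify_state(
    config: LoopConfiguration, a: float, b: float, lattice_unit: float = 1000.0
) -> str:
    return shortest_path_1d(config, a, b, lattice_unit=lattice_unit).state


def _frame_legs_bp(traj: Trajectory1D, i: int) -> tuple[np.ndarray, np.ndarray]:
    return traj.legs_bp(i)


def path_series(traj: Trajectory1D, a: float, b: float) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-frame (path length bp, loops used, state) along a trajectory."""
    u = traj.params.lattice_unit
    lengths = np.empty(traj.n_frames)
    loops = np.empty(traj.n_frames, dtype=int)
    states = []
    lo, hi = min(a, b), max(a, b)
    for i in range(traj.n_frames):
        lefts, rights = _frame_legs_bp(traj, i)
        L, k = _path_from_legs(lefts, rights, a, b)
        lengths[i] = L
        loops[i] = k
        states.append(_classify(L, k, lefts.astype(float), rights.astype(float), lo, hi, u))
    return lengths, loops, states


def loop_metrics(traj: Trajectory1D, a: float, b: float) -> dict:
    """Time-averaged path length, loops on path, and 1D state fractions."""
    lengths, loops, states = path_series(traj, a, b)
    n = len(states)
    fr = {s: states.count(s) / n for s in (OPEN, EXTRUDING, CLOSED)}
    return {
        "mean_path_bp": float(lengths.mean()),
        "mean_loops_used": float(loops.mean()),
        "state_fractions": fr,
        "n_frames": n,
    }


def processivity(traj: Trajectory1D, min_lifetimes: int = 100, exclude_boundary: bool = True) -> float:
    """Mean bp extruded per completed extruder lifetime.

    Uses only extruders that loaded and unloaded within the run; extruders
    whose legs hit the region boundary are excluded by default since their
    extrusion is truncated.
    """
    ev = [e for e in traj.lifetimes if not (exclude_boundary and e.touched_boundary)]
    if len(ev) < min_lifetimes:
        raise ValueError(f"only {len(ev)} completed lifetimes; need >= {min_lifetimes}")
    return float(np.mean([e.final_size - e.initial_size for e in ev]))
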