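
import networkx as nx
import numpy as np
import pytest

from loopx.extrusion import (
    Extruder,
    ExtrusionParams,
    LoopConfiguration,
    Trajectory1D,
    build_ctcf_landscape,
    simulate_extrusion,
)
from loopx import topology
from loopx.topology import classify_state, loop_metrics, processivity, shortest_path_1d


def brute_force_path(lefts, rights, a, b):
    """Independent oracle: exhaustive shortest path via networkx enumeration."""
    g = nx.Graph()
    nodes = sorted(set([a, b] + list(lefts) + list(rights)))
    for u, v in zip(nodes[:-1], nodes[1:]):
        g.add_edge(u, v, weight=min(v - u, g.get_edge_data(u, v, {"weight": np.inf})["weight"] if g.has_edge(u, v) else np.inf))
    for l, r in zip(lefts, rights):
        w = g.get_edge_data(l, r)
        g.add_edge(l, r, weight=0 if w is None else min(0, w["weight"]))
    best = np.inf
    for path in nx.all_simple_paths(g, a, b):
        w = sum(g[u][v]["weight"] for u, v in zip(path[:-1], path[1:]))
        best = min(best, w)
    return best


class TestShortestPath:
    def test_no_extruders_is_genomic_separation(self):
        r = shortest_path_1d(LoopConfiguration([]), 50_000, 250_000)
        assert (r.length, r.loops_used, r.state) == (200_000, 0, "open")

    def test_spanning_loop_is_closed(self):
        cfg = LoopConfiguration([Extruder(50_000, 250_000)])
        r = shortest_path_1d(cfg, 50_000, 250_000)
        assert (r.length, r.loops_used, r.state) == (0.0, 1, "closed")

    def test_nested_loop_off_path(self):
        cfg = LoopConfiguration([Extruder(100_000, 200_000), Extruder(150_000, 180_000)])
        r = shortest_path_1d(cfg, 50_000, 250_000)
        assert (r.length, r.loops_used) == (100_000, 1)
        assert r.state == "extruding"

    def test_outside_loop_can_shorten_path(self):
        # a loop spanning from upstream of a to inside (a, b) provides a shortcut
        cfg = LoopConfiguration([Extruder(10_000, 150_000)])
        r = shortest_path_1d(cfg, 50_000, 250_000)
        # a -> 10k (40k) -> loop -> 150k -> b (100k) = 140k < 200k
        assert r.length == 140_000
        assert r.loops_used == 1

    def test_position_validation(self):
        with pytest.raises(ValueError):
            shortest_path_1d(LoopConfiguration([]), 0, 0)
        with pytest.raises(ValueError):
            shortest_path_1d(LoopConfiguration([]), -5, 100, region_length=1000)

    def test_matches_brute_force_on_random_configurations(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            m = rng.integers(0, 7)
            legs = rng.choice(np.arange(0, 300) * 1000, size=2 * m, replace=False)
            legs = np.sort(legs)
            order = rng.permutation(m)
            pairs = sorted(
                [(legs[2 * i], legs[2 * i + 1]) for i in order], key=lambda p: p[0]
            )
            lefts = [p[0] for p in pairs]
            rights = [p[1] for p in pairs]
            a, b = sorted(
                rng.choice(
                    [x for x in np.arange(0, 300) * 1000 + 500], size=2, replace=False
                )
            )
            cfg = LoopConfiguration(
                [Extruder(l, r) for l, r in zip(lefts, rights)]
            )
            got = shortest_path_1d(cfg, a, b).length
            want = brute_force_path(lefts, rights, a, b)
            assert got == pytest.approx(want)

    def test_adding_a_loop_never_lengthens_the_path(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            m = rng.integers(1, 6)
            legs = np.sort(rng.choice(np.arange(400) * 1000, size=2 * m + 2, replace=False))
            base = [Extruder(int(legs[2 * i]), int(legs[2 * i + 1])) for i in range(m)]
            extra = Extruder(int(legs[-2]), int(legs[-1]))
            a, b = 50_500, 350_500
            before = shortest_path_1d(LoopConfiguration(base), a, b).length
            after = shortest_path_1d(LoopConfiguration(base + [extra]), a, b).length
            assert after <= before


class TestClassify:
    def test_empty_config_is_open(self):
        assert classify_state(LoopConfiguration([]), 1000, 99_000) == "open"

    def test_internal_loop_is_extruding(self):
        cfg = LoopConfiguration([Extruder(30_000, 60_000)])
        assert classify_state(cfg, 10_000, 90_000) == "extruding"

    def test_loop_outside_interval_leaves_state_open(self):
        cfg = LoopConfiguration([Extruder(200_000, 250_000)])
        assert classify_state(cfg, 10_000, 90_000) == "open"

    def test_path_within_lattice_unit_is_closed(self):
        cfg = LoopConfiguration([Extruder(10_000, 89_500)])
        assert classify_state(cfg, 10_000, 90_000) == "closed"


def _mini_traj(frames, lattice_unit=1000, region_length=400_000):
    params = ExtrusionParams(
        density=0, residence_time=1, motor_speed=0, region_length=region_length,
        lattice_unit=lattice_unit,
    )
    return Trajectory1D(
        times=np.arange(len(frames)) * 30.0,
        frames=frames,
        ctcf_bound=np.zeros((len(frames), 0), dtype=bool),
        params=params,
        sites=[],
        rng_seed=0,
    )


class TestLoopMetrics:
    def test_empty_trajectory_is_fully_open(self):
        frames = [
            {"left": np.array([], int), "right": np.array([], int),
             "left_stalled": np.array([], bool), "right_stalled": np.array([], bool)}
            for _ in range(5)
        ]
        m = loop_metrics(_mini_traj(frames), 50_500, 250_500)
        assert m["mean_path_bp"] == 200_000
        assert m["state_fractions"]["open"] == 1.0

    def test_hand_built_state_fractions(self):
        a, b = 50_500, 250_500
        mk = lambda l, r: {
            "left": np.array(l, int), "right": np.array(r, int),
            "left_stalled": np.zeros(len(l), bool),
            "right_stalled": np.zeros(len(l), bool),
        }
        frames = [
            mk([], []),            # open
            mk([100], [150]),      # extruding (loop inside, bead sites 100/150)
            mk([50], [250]),       # closed (spans a..b exactly)
        ]
        m = loop_metrics(_mini_traj(frames), a, b)
        fr = m["state_fractions"]
        assert fr == {"open": pytest.approx(1 / 3), "extruding": pytest.approx(1 / 3),
                      "closed": pytest.approx(1 / 3)}
        assert sum(fr.values()) == pytest.approx(1.0)


class TestProcessivity:
    def test_zero_speed_extrudes_nothing(self):
        p = ExtrusionParams(density=2, residence_time=2, motor_speed=0.0,
                            region_length=1_000_000)
        traj = simulate_extrusion(p, [], duration=90_000, sample_interval=9000, seed=1)
        assert processivity(traj) == 0.0

    def test_matches_speed_times_residence_without_obstacles(self):
        p = ExtrusionParams(density=0.5, residence_time=2, motor_speed=0.25,
                            region_length=4_000_000, stall_probability=0.0)
        traj = simulate_extrusion(p, [], duration=200_000, sample_interval=20_000, seed=2)
        assert processivity(traj) == pytest.approx(0.25 * 1000 * 120, rel=0.05)

    def test_ctcf_reduces_processivity(self):
        dense_sites = build_ctcf_landscape(
            [(x, "+" if i % 2 else "-", 5.0) for i, x in
             enumerate(range(50_000, 1_950_000, 100_000))],
            occupancy_target=0.9,
        )
        p = ExtrusionParams(density=1, residence_time=2, motor_speed=1.0,
                            region_length=2_000_000, stall_probability=1.0)
        free = simulate_extrusion(p, [], duration=60_000, sample_interval=6000, seed=3)
        blocked = simulate_extrusion(p, dense_sites, duration=60_000,
                                     sample_interval=6000, seed=3)
        assert processivity(blocked) < processivity(free)

    def test_insufficient_lifetimes_raise(self):
        p = ExtrusionParams(density=1, residence_time=30, motor_speed=0.5,
                            region_length=1_000_000)
        traj = simulate_extrusion(p, [], duration=2000, sample_interval=1000, seed=4)
        with pytest.raises(ValueError, match="lifetimes"):
            processivity(traj)
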