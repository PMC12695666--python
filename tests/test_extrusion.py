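import numpy as np
import pytest
from scipy import stats

from loopx.extrusion import (
    CTCFSite,
    Extruder,
    ExtrusionParams,
    LoopConfiguration,
    build_ctcf_landscape,
    simulate_extrusion,
    step_extruders,
    update_ctcf,
)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ExtrusionParams(density=-1, residence_time=10, motor_speed=1, region_length=1000)
        with pytest.raises(ValueError):
            ExtrusionParams(density=1, residence_time=0, motor_speed=1, region_length=1000)
        with pytest.raises(ValueError):
            ExtrusionParams(density=1, residence_time=10, motor_speed=1, region_length=1500)
        with pytest.raises(ValueError):
            ExtrusionParams(
                density=1, residence_time=10, motor_speed=1, region_length=1000,
                stall_probability=1.5,
            )

    def test_target_count(self):
        p = ExtrusionParams(density=12, residence_time=22, motor_speed=1,
                            region_length=2_600_000)
        assert p.n_target == pytest.approx(31.2)


class TestLandscape:
    def test_single_peak_gets_genomewide_residence(self):
        sites = build_ctcf_landscape([(1000, "+", 7.3)])
        assert sites[0].residence_time == pytest.approx(2.5)

    def test_empty_landscape(self):
        assert build_ctcf_landscape([]) == []

    def test_linear_scaling(self):
        sites = build_ctcf_landscape([(0, "+", 1.0), (5000, "-", 3.0)])
        assert [s.residence_time for s in sites] == pytest.approx([1.25, 3.75])
        assert [s.orientation for s in sites] == ["+", "-"]

    def test_mean_residence_preserved(self):
        rng = np.random.default_rng(0)
        strengths = rng.exponential(size=30)
        sites = build_ctcf_landscape(
            [(i * 1000, "+", s) for i, s in enumerate(strengths)]
        )
        assert np.mean([s.residence_time for s in sites]) == pytest.approx(2.5)

    def test_all_zero_strengths_rejected(self):
        with pytest.raises(ValueError, match="invalid landscape"):
            build_ctcf_landscape([(0, "+", 0.0), (100, "-", 0.0)])


class TestCTCFDynamics:
    def test_zero_dt_is_identity(self):
        sites = [CTCFSite(0, "+", 2.5, bound=True)]
        update_ctcf(sites, 0.0, np.random.default_rng(0))
        assert sites[0].bound

    def test_unbinding_probability_matches_exponential_survival(self):
        # tau = 2.5 min, dt = 2.5 min -> P(unbind) = 1 - 1/e
        rng = np.random.default_rng(1)
        n = 20_000
        unbound = 0
        for _ in range(n):
            s = [CTCFSite(0, "+", 2.5, bound=True)]
            update_ctcf(s, 150.0, rng)
            unbound += not s[0].bound
        expected = 1.0 - np.exp(-1.0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert unbound / n == pytest.approx(expected, abs=4 * se)

    def test_stationary_occupancy_equals_target(self):
        # two-state Markov chain: long-run bound fraction -> occupancy_target
        rng = np.random.default_rng(2)
        sites = [CTCFSite(i * 1000, "+", 2.5, occupancy_target=0.5) for i in range(100)]
        bound_frac = []
        for _ in range(3000):
            update_ctcf(sites, 10.0, rng)
            bound_frac.append(np.mean([s.bound for s in sites]))
        assert np.mean(bound_frac[100:]) == pytest.approx(0.5, abs=0.02)

    def test_occupancy_validation(self):
        with pytest.raises(ValueError):
            CTCFSite(0, "+", 2.5, occupancy_target=1.0)


class TestStepExtruders:
    def _params(self, speed=2.0, stall=1.0):
        # motor 2 kb/s on a 1-kb lattice with dt=1 s -> each leg moves w.p. 1
        return ExtrusionParams(
            density=0.0, residence_time=1e6, motor_speed=speed,
            region_length=100_000, stall_probability=stall,
        )

    def test_zero_dt_identity(self):
        cfg = LoopConfiguration([Extruder(10, 11)])
        out = step_extruders(cfg, 0.0, self._params(), [], np.random.default_rng(0))
        assert out.extruders[0].left_leg == 10

    def test_free_legs_advance_one_site(self):
        cfg = LoopConfiguration([Extruder(50, 51)])
        out = step_extruders(cfg, 1.0, self._params(), [], np.random.default_rng(0))
        e = out.extruders[0]
        assert (e.left_leg, e.right_leg) == (49, 52)

    def test_stall_pins_leg_until_ctcf_unbinds(self):
        sites = [CTCFSite(48_500, "+", 2.5, bound=True)]  # lattice site 48
        cfg = LoopConfiguration([Extruder(49, 60)])
        rng = np.random.default_rng(0)
        p = self._params(stall=1.0)
        out = step_extruders(cfg, 1.0, p, sites, rng)
        e = out.extruders[0]
        assert e.left_leg == 49 and e.left_stalled
        assert e.right_leg == 61  # right leg unaffected
        out = step_extruders(out, 1.0, p, sites, rng)
        assert out.extruders[0].left_leg == 49  # still pinned, no new draw
        sites[0].bound = False
        out = step_extruders(out, 1.0, p, sites, rng)
        e = out.extruders[0]
        assert e.left_leg == 48 and not e.left_stalled  # resumes through the site

    def test_pass_traverses_when_stall_probability_zero(self):
        sites = [CTCFSite(48_500, "+", 2.5, bound=True)]
        cfg = LoopConfiguration([Extruder(49, 60)])
        out = step_extruders(cfg, 1.0, self._params(stall=0.0), sites,
                             np.random.default_rng(0))
        assert out.extruders[0].left_leg == 48

    def test_nonblocking_orientation_ignored(self):
        sites = [CTCFSite(48_500, "-", 2.5, bound=True)]  # '-' blocks rightward legs
        cfg = LoopConfiguration([Extruder(49, 60)])
        out = step_extruders(cfg, 1.0, self._params(stall=1.0), sites,
                             np.random.default_rng(0))
        assert out.extruders[0].left_leg == 48

    def test_blocked_leg_waits_without_stalling(self):
        cfg = LoopConfiguration([Extruder(10, 11), Extruder(12, 13)])
        out = step_extruders(cfg, 1.0, self._params(), [], np.random.default_rng(0))
        legs = sorted(
            x for e in out.extruders for x in (e.left_leg, e.right_leg)
        )
        assert len(set(legs)) == 4  # no two legs share a site
        assert not any(e.left_stalled or e.right_stalled for e in out.extruders)

    def test_step_size_guard(self):
        cfg = LoopConfiguration([Extruder(10, 11)])
        with pytest.raises(ValueError, match="one site"):
            step_extruders(cfg, 10.0, self._params(), [], np.random.default_rng(0))


class TestSimulate:
    def test_zero_density_gives_empty_frames(self):
        p = ExtrusionParams(density=0, residence_time=5, motor_speed=1,
                            region_length=500_000)
        traj = simulate_extrusion(p, [], duration=600, sample_interval=30, seed=0)
        assert all(len(f["left"]) == 0 for f in traj.frames)

    def test_stationary_count_matches_density_times_length(self):
        p = ExtrusionParams(density=20, residence_time=3, motor_speed=0.5,
                            region_length=1_000_000)
        traj = simulate_extrusion(p, [], duration=14_400, sample_interval=30, seed=3)
        counts = traj.extruder_counts()
        # ~80 independent residence times; binomial-style tolerance of 5%
        assert counts.mean() == pytest.approx(p.n_target, rel=0.05)

    def test_lifetimes_are_exponential(self):
        # dt/tau ~ 0.003 so discretization is far below the KS resolution
        p = ExtrusionParams(density=40, residence_time=2, motor_speed=1.0,
                            region_length=1_000_000)
        traj = simulate_extrusion(p, [], duration=36_000, sample_interval=600, seed=4)
        lifetimes = np.array([e.unload_time - e.load_time for e in traj.lifetimes])
        lifetimes = lifetimes[lifetimes > 0]
        assert len(lifetimes) >= 10_000
        tau_s = p.residence_time * 60.0
        assert lifetimes.mean() == pytest.approx(tau_s, rel=0.03)
        _, pval = stats.kstest(lifetimes, "expon", args=(0, tau_s))
        assert pval > 0.01

    def test_mean_extruded_length_is_speed_times_residence(self):
        # sparse extruders, no CTCF, stall irrelevant: v*tau = 120 kb
        p = ExtrusionParams(density=0.5, residence_time=2, motor_speed=1.0,
                            region_length=4_000_000, stall_probability=0.0)
        traj = simulate_extrusion(p, [], duration=120_000, sample_interval=6000, seed=5)
        ext = np.array(
            [e.final_size - e.initial_size for e in traj.lifetimes
             if not e.touched_boundary]
        )
        assert len(ext) > 500
        expected = p.motor_speed * 1000 * p.residence_time * 60
        assert ext.mean() == pytest.approx(expected, rel=0.05)

    def test_seed_reproducibility(self):
        p = ExtrusionParams(density=10, residence_time=3, motor_speed=1,
                            region_length=500_000)
        sites = build_ctcf_landscape([(100_000, "+", 1.0), (400_000, "-", 1.0)])
        t1 = simulate_extrusion(p, sites, duration=600, sample_interval=30, seed=7)
        t2 = simulate_extrusion(p, sites, duration=600, sample_interval=30, seed=7)
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1["left"], f2["left"])
            assert np.array_equal(f1["right"], f2["right"])
        assert np.array_equal(t1.ctcf_bound, t2.ctcf_bound)

    def test_no_leg_collisions_in_sampled_frames(self, convergent_sites):
        sites, _, _ = convergent_sites
        p = ExtrusionParams(density=40, residence_time=10, motor_speed=1,
                            region_length=2_600_000)
        traj = simulate_extrusion(p, sites, duration=1200, sample_interval=60, seed=8)
        for f in traj.frames:
            legs = np.concatenate([f["left"], f["right"]])
            assert len(np.unique(legs)) == len(legs)
            assert np.all(f["left"] < f["right"])
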