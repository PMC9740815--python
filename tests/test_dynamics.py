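"""Integrator and collisional-thermostat behaviour: elastic-collision
kinematics, Maxwell sampling, NVE conservation, setpoint tracking."""

import numpy as np
import pytest

from hapthermal.constants import INTERNAL_TO_KCAL, KB_KCAL, KCAL_TO_INTERNAL
from hapthermal.dynamics import (HeatingSchedule, IntegratorConfig,
                                 ThermostatConfig, collision_delta_v,
                                 kinetic_temperature, run_linear_heating,
                                 run_nvt, sample_virtual_velocity, step)
from hapthermal.forcefield import Evaluator, ForceField, PairParams
from hapthermal.synthetic import make_velocity_ensemble
from hapthermal.system import AtomSystem


def _total_energy_series(traj, evaluator, masses):
    out = []
    for fr in range(traj.n_frames):
        pe = evaluator(traj.positions[fr], want_forces=False)[0].total
        ke = 0.5 * float(np.sum(masses[:, None] * traj.velocities[fr] ** 2)) \
            * INTERNAL_TO_KCAL
        out.append(pe + ke)
    return np.asarray(out)


class TestCollisionKinematics:
    def test_equal_masses_full_exchange(self):
        v = np.array([1.0, -2.0, 0.5])
        v0 = np.array([-0.3, 0.1, 4.0])
        np.testing.assert_allclose(collision_delta_v(v, 7.0, v0, 7.0), v0 - v)

    def test_identical_velocities_no_jump(self):
        v = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(collision_delta_v(v, 3.0, v, 5.0), 0.0)

    def test_direct_substitution(self):
        dv = collision_delta_v(np.zeros(3), 1.0, np.array([1.0, 0, 0]), 2.0)
        np.testing.assert_allclose(dv, [4.0 / 3.0, 0, 0])

    def test_two_body_energy_momentum_conserved(self):
        m, m0 = 3.0, 7.0
        v = np.array([1.0, -0.5, 2.0])
        v0 = np.array([-2.0, 0.3, 0.1])
        dv = collision_delta_v(v, m, v0, m0)
        v_after = v + dv
        # virtual partner recoil from momentum conservation
        v0_after = v0 - (m / m0) * dv
        p_before = m * v + m0 * v0
        p_after = m * v_after + m0 * v0_after
        np.testing.assert_allclose(p_before, p_after, rtol=1e-12)
        e_before = 0.5 * m * v @ v + 0.5 * m0 * v0 @ v0
        e_after = 0.5 * m * v_after @ v_after + 0.5 * m0 * v0_after @ v0_after
        assert e_before == pytest.approx(e_after, rel=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            collision_delta_v(np.zeros(3), 0.0, np.ones(3), 1.0)


class TestMaxwellSampling:
    def test_zero_temperature_zero_vector(self):
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(
            sample_virtual_velocity(0.0, 12.0, rng), np.zeros(3))

    def test_component_variance_matches_equipartition(self):
        rng = np.random.default_rng(42)
        m0, t = 18.0, 300.0
        samples = np.array([sample_virtual_velocity(t, m0, rng)
                            for _ in range(100_000)])
        expected = KB_KCAL * t * KCAL_TO_INTERNAL / m0
        for k in range(3):
            assert samples[:, k].var() == pytest.approx(expected, rel=0.02)

    def test_reproducible_for_fixed_seed(self):
        a = sample_virtual_velocity(500.0, 40.0, np.random.default_rng(9))
        b = sample_virtual_velocity(500.0, 40.0, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_velocity_ensemble_temperature(self):
        vel = make_velocity_ensemble(500.0, np.full(10_000, 22.0), seed=5)
        sys_ = AtomSystem(positions=np.zeros((10_000, 3)),
                          species=np.array(["X"] * 10_000, dtype=object),
                          masses=np.full(10_000, 22.0),
                          charges=np.zeros(10_000), box=np.eye(3) * 100,
                          velocities=vel)
        assert kinetic_temperature(sys_) == pytest.approx(500.0, rel=0.02)


class TestKineticTemperature:
    def test_zero_velocities(self, toy):
        sys_, _ = toy
        assert kinetic_temperature(sys_) == 0.0

    def test_quadratic_speed_scaling(self, toy_warm):
        sys_, _ = toy_warm
        t1 = kinetic_temperature(sys_)
        sys_.velocities *= 2.0
        assert kinetic_temperature(sys_) == pytest.approx(4.0 * t1, rel=1e-12)

    def test_empty_system_rejected(self):
        sys_ = AtomSystem(positions=np.zeros((1, 3)), species=["X"],
                          masses=[1.0], charges=[0.0], box=np.eye(3) * 10)
        sys_.positions = np.zeros((0, 3))
        sys_.species = np.array([], dtype=object)
        sys_.masses = np.array([])
        sys_.velocities = np.zeros((0, 3))
        with pytest.raises(ValueError):
            kinetic_temperature(sys_)


class TestIntegration:
    def test_nve_energy_conservation(self, toy_warm):
        """No thermostat: total energy drifts < 1e-4 relative over 10^4 steps."""
        sys_, ff = toy_warm
        cfg = IntegratorConfig(dt=5e-4, sample_interval=0.5)
        traj = run_nvt(sys_, ff, 300.0, 5.0, cfg,
                       ThermostatConfig(collision_rate=0.0), seed=3)
        e = _total_energy_series(traj, Evaluator(sys_, ff), sys_.masses)
        assert np.abs((e - e[0]) / e[0]).max() < 1e-4

    def test_nve_momentum_conserved(self, toy_warm):
        sys_, ff = toy_warm
        traj = run_nvt(sys_, ff, 300.0, 0.5,
                       IntegratorConfig(dt=5e-4, sample_interval=0.1),
                       ThermostatConfig(collision_rate=0.0), seed=3)
        p0 = (sys_.masses[:, None] * traj.velocities[0]).sum(axis=0)
        p1 = (sys_.masses[:, None] * traj.velocities[-1]).sum(axis=0)
        np.testing.assert_allclose(p0, p1, atol=1e-8)

    def test_free_particles_move_in_straight_lines(self):
        """Zero forces + zero collisions = uniform motion."""
        ff = ForceField(cutoff=5.0)
        ff.pairs[("X", "X")] = PairParams("lj12-6", 0.0, 1.0)
        sys_ = AtomSystem(positions=[[10.0, 10, 10], [30.0, 30, 30]],
                          species=["X", "X"], masses=[2.0, 3.0],
                          charges=[0.0, 0.0], box=np.eye(3) * 200,
                          velocities=[[1.0, 2.0, 0.0], [0.0, -1.0, 3.0]])
        cfg = IntegratorConfig(dt=1e-2, sample_interval=1.0)
        traj = run_nvt(sys_, ff, 0.0, 2.0, cfg,
                       ThermostatConfig(collision_rate=0.0), seed=0)
        expected = sys_.positions + 2.0 * sys_.velocities
        np.testing.assert_allclose(traj.positions[-1], expected, atol=1e-9)

    def test_same_seed_bit_identical(self, toy_warm):
        sys_, ff = toy_warm
        cfg = IntegratorConfig(dt=5e-4, sample_interval=0.1)
        a = run_nvt(sys_, ff, 600.0, 0.3, cfg, seed=11)
        b = run_nvt(sys_, ff, 600.0, 0.3, cfg, seed=11)
        for fa, fb in zip(a.positions, b.positions):
            np.testing.assert_array_equal(fa, fb)

    def test_different_seeds_differ(self, toy_warm):
        sys_, ff = toy_warm
        cfg = IntegratorConfig(dt=5e-4, sample_interval=0.1)
        a = run_nvt(sys_, ff, 600.0, 0.2, cfg, seed=1)
        b = run_nvt(sys_, ff, 600.0, 0.2, cfg, seed=2)
        assert a.n_frames == b.n_frames
        assert not np.allclose(a.positions[-1], b.positions[-1])

    def test_zero_duration_single_frame(self, toy_warm):
        sys_, ff = toy_warm
        traj = run_nvt(sys_, ff, 300.0, 0.0, IntegratorConfig(), seed=0)
        assert traj.n_frames == 1
        np.testing.assert_array_equal(traj.positions[0], sys_.positions)

    def test_single_step_function(self, toy_warm):
        sys_, ff = toy_warm
        rng = np.random.default_rng(0)
        out = step(sys_, ff, IntegratorConfig(dt=5e-4),
                   ThermostatConfig(collision_rate=0.0), 300.0, rng)
        assert out.n_atoms == sys_.n_atoms
        assert not np.allclose(out.positions, sys_.positions)
        # input untouched
        assert sys_.velocities is not out.velocities

    def test_thermostat_reaches_setpoint(self, toy_warm):
        """Mean kinetic temperature after equilibration within 3 SEM of T_ref."""
        sys_, ff = toy_warm
        t_ref = 700.0
        traj = run_nvt(sys_, ff, t_ref, 6.0,
                       IntegratorConfig(dt=5e-4, sample_interval=0.1),
                       ThermostatConfig(collision_rate=10.0), seed=21)
        tk = np.array(traj.t_kin)[20:]
        sem = tk.std(ddof=1) / np.sqrt(len(tk))
        # frames are correlated; allow a generous but still informative band
        assert abs(tk.mean() - t_ref) < max(6 * sem, 0.05 * t_ref)


class TestHeatingSchedule:
    def test_setpoint_endpoints(self):
        sched = HeatingSchedule(700.0, 0.1, 7000.0)
        assert sched(0.0) == 700.0
        assert sched(7000.0) == pytest.approx(1400.0)

    def test_out_of_range_rejected(self):
        sched = HeatingSchedule(700.0, 0.1, 100.0)
        with pytest.raises(ValueError):
            sched(200.0)

    def test_linear_heating_records_ramp(self, toy_warm):
        sys_, ff = toy_warm
        sched = HeatingSchedule(300.0, 100.0, 1.0)  # fast toy ramp
        traj = run_linear_heating(sys_, ff, sched,
                                  IntegratorConfig(dt=5e-4, sample_interval=0.25),
                                  seed=4)
        np.testing.assert_allclose(
            traj.t_ref, 300.0 + 100.0 * np.asarray(traj.times), rtol=1e-12)

    def test_zero_rate_equals_fixed_setpoint(self, toy_warm):
        sys_, ff = toy_warm
        cfg = IntegratorConfig(dt=5e-4, sample_interval=0.1)
        heat = run_linear_heating(sys_, ff, HeatingSchedule(500.0, 0.0, 0.3),
                                  cfg, seed=8)
        nvt = run_nvt(sys_, ff, 500.0, 0.3, cfg, seed=8)
        np.testing.assert_array_equal(heat.t_ref, nvt.t_ref)
        for fa, fb in zip(heat.positions, nvt.positions):
            np.testing.assert_array_equal(fa, fb)


class TestConstraints:
    def test_rigid_water_geometry_maintained(self):
        """A lone rigid water keeps its bond lengths through dynamics."""
        from hapthermal.geometry import SolvationSpec, solvate
        host = AtomSystem(positions=[[25.0, 25, 25]], species=["Ca"],
                          masses=[40.08], charges=[0.0], box=np.eye(3) * 50)
        wet = solvate(host, SolvationSpec(shell_thickness=6.0, n_waters=3), seed=2)
        import importlib.resources

        import yaml

        from hapthermal.forcefield import ForceField
        ref = importlib.resources.files("hapthermal.data") / "default_forcefield.yaml"
        ff = ForceField.from_dict(yaml.safe_load(ref.read_text()))
        wet.velocities = make_velocity_ensemble(300.0, wet.masses, seed=3)
        traj = run_nvt(wet, ff, 300.0, 0.2,
                       IntegratorConfig(dt=5e-4, sample_interval=0.05), seed=4)
        w = np.flatnonzero(wet.groups == "WAT")
        pos = traj.positions[-1]
        for k in range(0, len(w), 3):
            o, h1, h2 = w[k], w[k + 1], w[k + 2]
            assert np.linalg.norm(pos[h1] - pos[o]) == pytest.approx(0.9572, abs=1e-6)
            assert np.linalg.norm(pos[h2] - pos[o]) == pytest.approx(0.9572, abs=1e-6)
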