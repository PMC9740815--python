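"""Detachment ledger, radius of gyration, replicate averaging, onset and
melting detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapthermal.analysis import (DetachmentLedger, RgSeries, average_over_runs,
                                 detachment_series, melting_flag,
                                 min_distance_to_host, onset_temperature,
                                 radius_of_gyration, rg_series)
from hapthermal.synthetic import (ScriptedEvent, make_melting_rg_series,
                                  make_scripted_trajectory, make_toy_crystal)
from hapthermal.system import AtomSystem
from hapthermal.trajectory import Trajectory


def _random_tagged_trajectory(seed, n_frames=30, n_host=12, n_ions=3,
                              box_len=40.0, scale=18.0):
    """Random-walk trajectory with tagged diatomics for property tests."""
    rng = np.random.default_rng(seed)
    n = n_host + 2 * n_ions
    species = np.array(["B"] * n_host + ["O_I", "H_I"] * n_ions, dtype=object)
    ion_ids = np.array([-1] * n_host + [k for k in range(n_ions) for _ in (0, 1)])
    bonds = [(n_host + 2 * k, n_host + 2 * k + 1) for k in range(n_ions)]
    base = rng.uniform(5, 5 + scale, size=(n, 3))
    for k in range(n_ions):
        base[n_host + 2 * k + 1] = base[n_host + 2 * k] + [0, 0, 0.96]
    sys_ = AtomSystem(positions=base, species=species, masses=np.ones(n),
                      charges=np.zeros(n), box=np.eye(3) * box_len,
                      bonds=bonds, ion_ids=ion_ids)
    traj = Trajectory.from_system(sys_)
    pos = base.copy()
    for f in range(n_frames):
        pos = pos + rng.normal(scale=0.8, size=pos.shape)
        traj.append(pos.copy(), sys_.box, float(f))
    return traj


def _brute_force_series(traj, threshold=5.0):
    """Independent historical-OR oracle: per-frame full pair scan over all
    27 periodic images, pure python."""
    ions = sorted(set(int(i) for i in traj.ion_ids if i >= 0))
    ever = {i: False for i in ions}
    counts = []
    L = [traj.boxes[0][k] for k in range(3)]
    shifts = [i * L[0] + j * L[1] + k * L[2]
              for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        for ion in ions:
            if ever[ion]:
                continue
            ion_atoms = [a for a in range(traj.n_atoms) if traj.ion_ids[a] == ion]
            host = [a for a in range(traj.n_atoms)
                    if traj.groups[a] == "HAP" and traj.ion_ids[a] != ion]
            dmin = min(
                np.linalg.norm(pos[h] - pos[a] + s)
                for a in ion_atoms for h in host for s in shifts)
            if dmin > threshold:
                ever[ion] = True
        counts.append(sum(ever.values()))
    return counts


class TestMinDistance:
    def test_constructed_fixture_o_closer_than_h(self):
        pos = np.array([[0.0, 0, 0],      # host
                        [3.0, 0, 0],      # ion O, exactly 3 from host
                        [3.0, 0, 0.96]])  # ion H, farther
        d = min_distance_to_host(pos, np.eye(3) * 100, np.array([True] * 3),
                                 np.array([1, 2]), np.array([0]))
        assert d == pytest.approx(3.0)

    def test_minimum_image_across_boundary(self):
        """Ion near the box edge is 2 Å from a host's periodic image."""
        L = 20.0
        pos = np.array([[1.0, 10, 10], [19.0, 10, 10], [19.0, 10, 10.96]])
        d = min_distance_to_host(pos, np.eye(3) * L, np.array([True] * 3),
                                 np.array([1, 2]), np.array([0]))
        assert d == pytest.approx(2.0)

    def test_matches_exhaustive_pair_scan(self, rng):
        L = 25.0
        pos = rng.uniform(0, L, size=(10, 3))
        ion_atoms, host = np.array([0, 1]), np.arange(2, 10)
        got = min_distance_to_host(pos, np.eye(3) * L, np.array([True] * 3),
                                   ion_atoms, host)
        shifts = [np.array([i, j, k]) * L
                  for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        want = min(np.linalg.norm(pos[h] - pos[a] + s)
                   for a in ion_atoms for h in host for s in shifts)
        assert got == pytest.approx(want, rel=1e-12)

    def test_empty_host_rejected(self):
        pos = np.zeros((2, 3))
        with pytest.raises(ValueError, match="host"):
            min_distance_to_host(pos, np.eye(3) * 10, np.array([True] * 3),
                                 np.array([0, 1]), np.array([], dtype=int))

    def test_overlapping_sets_rejected(self):
        pos = np.zeros((3, 3))
        with pytest.raises(ValueError, match="disjoint"):
            min_distance_to_host(pos, np.eye(3) * 10, np.array([True] * 3),
                                 np.array([0, 1]), np.array([1, 2]))


class TestDetachmentLedger:
    def test_scripted_event_latches(self, toy):
        """Ion crossing 5 Å at frame 40 and returning at 60 counts forever."""
        sys_, _ = toy
        traj = make_scripted_trajectory(
            sys_, [ScriptedEvent(ion=1, frame=40, target_distance=8.0,
                                 returns_frame=60)], n_frames=80, seed=3)
        ledger = detachment_series(traj)
        counts = np.asarray(ledger.counts)
        assert counts[:40].max() == 0
        assert (counts[40:] == 1).all()   # including after the return at 60

    def test_two_ions_three_plateaus(self, toy):
        sys_, _ = toy
        traj = make_scripted_trajectory(
            sys_, [ScriptedEvent(ion=0, frame=10), ScriptedEvent(ion=1, frame=20)],
            n_frames=30, seed=4)
        counts = np.asarray(detachment_series(traj).counts)
        assert counts[:10].max() == 0
        assert (counts[10:20] == 1).all()
        assert (counts[20:] == 2).all()

    def test_no_events_all_zero(self, toy):
        sys_, _ = toy
        traj = make_scripted_trajectory(sys_, [], n_frames=15, seed=5)
        assert np.asarray(detachment_series(traj).counts).max() == 0

    def test_static_trajectory_constant_series(self, toy):
        sys_, _ = toy
        traj = Trajectory.from_system(sys_)
        for f in range(10):
            traj.append(sys_.positions.copy(), sys_.box, float(f))
        counts = np.asarray(detachment_series(traj).counts)
        assert (counts == counts[0]).all()

    def test_infinite_threshold_all_zero(self, toy):
        sys_, _ = toy
        traj = make_scripted_trajectory(
            sys_, [ScriptedEvent(ion=0, frame=5)], n_frames=12, seed=6)
        assert np.asarray(detachment_series(traj, threshold=np.inf).counts).max() == 0

    def test_matches_brute_force_oracle(self, toy):
        sys_, _ = toy
        traj = make_scripted_trajectory(
            sys_, [ScriptedEvent(ion=0, frame=7, returns_frame=14),
                   ScriptedEvent(ion=1, frame=11)], n_frames=20, seed=7)
        got = detachment_series(traj).counts
        assert got == _brute_force_series(traj)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_count_monotone_on_random_trajectories(self, seed):
        traj = _random_tagged_trajectory(seed)
        counts = np.asarray(detachment_series(traj).counts)
        assert (np.diff(counts) >= 0).all()

    @settings(max_examples=5, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_random_trajectories_match_oracle(self, seed):
        traj = _random_tagged_trajectory(seed, n_frames=12, n_host=8, n_ions=2)
        assert detachment_series(traj).counts == _brute_force_series(traj)

    def test_series_invariant_under_rigid_translation(self, toy):
        sys_, _ = toy
        traj = make_scripted_trajectory(
            sys_, [ScriptedEvent(ion=0, frame=6)], n_frames=12, seed=8)
        moved = Trajectory.from_system(sys_)
        for f in range(traj.n_frames):
            moved.append(traj.positions[f] + np.array([7.0, -3.0, 11.0]),
                         traj.boxes[f], traj.times[f])
        assert detachment_series(traj).counts == detachment_series(moved).counts

    def test_no_ions_rejected(self):
        sys_ = AtomSystem(positions=np.zeros((1, 3)), species=["B"],
                          masses=[1.0], charges=[0.0], box=np.eye(3) * 10)
        traj = Trajectory.from_system(sys_)
        traj.append(sys_.positions, sys_.box, 0.0)
        with pytest.raises(ValueError, match="no tagged"):
            detachment_series(traj)

    def test_ledger_validates_monotonicity(self):
        ledger = DetachmentLedger.empty(2)
        ledger.counts = [0, 1, 0]
        with pytest.raises(ValueError, match="monotone"):
            ledger.validate()


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2, 3]]), np.array([5.0])) == 0.0

    def test_two_equal_masses_closed_form(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(pos, np.ones(2)) == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        pos = rng.normal(size=(100, 3)) * 5
        m = rng.uniform(1, 20, size=100)
        com = (m[:, None] * pos).sum(axis=0) / m.sum()
        want = np.sqrt((m * ((pos - com) ** 2).sum(axis=1)).sum() / m.sum())
        assert radius_of_gyration(pos, m) == pytest.approx(want, rel=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariances_and_scaling(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(size=(12, 3))
        m = rng.uniform(0.5, 10, size=12)
        rg = radius_of_gyration(pos, m)
        # translation
        assert radius_of_gyration(pos + [3.0, -1.0, 9.0], m) == pytest.approx(rg)
        # rotation (z by 40 degrees)
        th = np.deg2rad(40)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        assert radius_of_gyration(pos @ R.T, m) == pytest.approx(rg)
        # linear coordinate scaling
        assert radius_of_gyration(2.5 * pos, m) == pytest.approx(2.5 * rg)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((3, 3)), np.ones(3),
                               selection=np.array([], dtype=int))

    def test_series_over_trajectory(self, toy):
        sys_, _ = toy
        traj = make_scripted_trajectory(sys_, [], n_frames=6, seed=2)
        series = rg_series(traj)
        assert len(series.rg) == 6
        assert (series.rg > 0).all()


class TestAveraging:
    def test_identical_series_zero_sem(self):
        s = np.arange(10.0)
        mean, sem = average_over_runs([s] * 16)
        np.testing.assert_allclose(mean, s)
        np.testing.assert_allclose(sem, 0.0)

    def test_two_point_closed_form(self):
        mean, sem = average_over_runs([np.array([0.0]), np.array([2.0])])
        assert mean[0] == pytest.approx(1.0)
        assert sem[0] == pytest.approx(1.0)   # std=sqrt(2), sem=sqrt(2)/sqrt(2)

    def test_matches_brute_force(self, rng):
        series = [rng.normal(size=20) for _ in range(7)]
        mean, sem = average_over_runs(series)
        arr = np.vstack(series)
        np.testing.assert_allclose(mean, arr.mean(axis=0))
        np.testing.assert_allclose(sem, arr.std(axis=0, ddof=1) / np.sqrt(7))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            average_over_runs([np.zeros(5), np.zeros(6)])


class TestOnset:
    def test_flat_series_no_onset(self):
        t = np.arange(800.0, 1200.0, 25.0)
        assert onset_temperature(t, np.zeros(len(t)))["onset"] is None

    def test_step_function_onset(self):
        t = np.arange(800.0, 1201.0, 25.0)
        y = np.where(t >= 1000.0, 5.0, 0.0)
        res = onset_temperature(t, y)
        assert res["onset"] == pytest.approx(1000.0, abs=50.0)

    def test_piecewise_linear_knee_recovered(self):
        t = np.arange(700.0, 1401.0, 25.0)
        knee = 1150.0
        y = np.where(t > knee, 0.05 * (t - knee), 0.0)
        res = onset_temperature(t, y, window=50.0, slope_threshold=0.02)
        assert res["onset"] is not None
        assert abs(res["onset"] - knee) <= 50.0


class TestMelting:
    def test_constant_rg_not_melted(self):
        series = RgSeries(times=np.arange(50.0), rg=np.full(50, 20.0))
        melted, t = melting_flag(series, drop_fraction=0.1)
        assert not melted and t is None

    def test_synthetic_collapse_detected_near_collapse_frame(self):
        series = make_melting_rg_series(collapse_frame=100, drop_fraction=0.3,
                                        noise=0.005, seed=1)
        melted, t = melting_flag(series, drop_fraction=0.1)
        assert melted
        assert abs(t - 100.0) < 25.0

    def test_noisy_constant_series_not_flagged(self):
        for seed in range(20):
            series = make_melting_rg_series(collapse_frame=100, drop_fraction=0.0,
                                            noise=0.01, seed=seed)
            melted, _ = melting_flag(series, drop_fraction=0.1)
            assert not melted

    def test_short_series_rejected(self):
        series = RgSeries(times=np.arange(3.0), rg=np.ones(3))
        with pytest.raises(ValueError, match="short"):
            melting_flag(series)
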