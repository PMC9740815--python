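"""Synthetic test systems: toy ionic crystals with tagged diatomics,
scripted trajectories with known detachment events, calibrated velocity
ensembles and melting-shaped radius-of-gyration series.

These generators stand in for the full crystal at desk scale: the toy
crystal is a rock-salt-like lattice of point charges with 12-6
Lennard-Jones cores, holding embedded charged O-H diatomics whose
binding energies are of order 10–100 kcal/mol — the same order as
hydroxyl removal energies from the real mineral — without claiming any
structural realism.  Every generator is deterministic under a fixed
seed, and scripted trajectories verify their own event script by
re-measuring ion-host distances after construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .analysis import DEFAULT_THRESHOLD, _host_mask, min_distance_to_host
from .constants import KB_KCAL, KCAL_TO_INTERNAL, mass_of
from .forcefield import BondParams, ForceField, PairParams, _key
from .system import GROUP_HAP, AtomSystem
from .trajectory import Trajectory

__all__ = [
    "ScriptedEvent",
    "make_toy_crystal",
    "make_scripted_trajectory",
    "make_velocity_ensemble",
    "make_melting_rg_series",
]

_LATTICE_SPACING = 2.8   # Å between neighbouring lattice sites
_HOST_CHARGE = 0.4       # |e| on host lattice ions
_OH_LENGTH = 0.96        # Å diatomic bond length


@dataclass(frozen=True)
class ScriptedEvent:
    """One scripted detachment: ``ion`` reaches ``target_distance`` from
    the host at ``frame``; if ``returns_frame`` is set the ion comes back
    to its bound position from that frame on (the ledger must still count
    it as detached — 'ever detached' semantics)."""
    ion: int
    frame: int
    target_distance: float = 8.0
    returns_frame: int | None = None


def toy_forcefield(cutoff: float = 10.0) -> ForceField:
    """Pair table for the toy crystal: generic 12-6 cores, point charges."""
    ff = ForceField(cutoff=cutoff)
    ff.pairs[_key("A", "A")] = PairParams("lj12-6", 0.15, 2.5)
    ff.pairs[_key("B", "B")] = PairParams("lj12-6", 0.15, 2.5)
    ff.pairs[_key("O_I", "O_I")] = PairParams("lj12-6", 0.15, 2.5)
    ff.pairs[_key("H_I", "H_I")] = PairParams("lj12-6", 0.01, 1.0)
    ff.bonds[_key("O_I", "H_I")] = BondParams(500.0, _OH_LENGTH)
    ff.charges = {"A": _HOST_CHARGE, "B": -_HOST_CHARGE,
                  "O_I": -_HOST_CHARGE, "H_I": 0.0}
    return ff


def make_toy_crystal(n_cells: int, n_diatomics: int, seed: int = 0,
                     vacuum_margin: float = 24.0) -> tuple[AtomSystem, ForceField]:
    """Cubic rock-salt-like ionic lattice with embedded O-H diatomics
    tagged as detachable ions; returns (system, force field).

    ``n_cells`` conventional 2×2×2-site cells are arranged in a near-cubic
    grid (8 lattice sites each, charges alternating by site parity).
    Each diatomic replaces one anion site, carrying the same net charge,
    so the crystal stays neutral and the diatomic is Coulomb-bound.
    """
    if n_cells < 1 or n_diatomics < 1:
        raise ValueError("counts must be >= 1")
    # near-cubic grid of cells
    nx = int(round(n_cells ** (1 / 3))) or 1
    while n_cells % nx:
        nx -= 1
    rest = n_cells // nx
    ny = int(round(rest ** 0.5)) or 1
    while rest % ny:
        ny -= 1
    nz = rest // ny
    dims = np.array([2 * nx, 2 * ny, 2 * nz])

    sites = np.array([(i, j, k)
                      for i in range(dims[0])
                      for j in range(dims[1])
                      for k in range(dims[2])], dtype=int)
    parity = sites.sum(axis=1) % 2
    # diatomics sit on top-surface anion sites so +z is open space
    anion_sites = np.flatnonzero((parity == 1) & (sites[:, 2] == dims[2] - 1))
    if n_diatomics > len(anion_sites):
        raise ValueError(
            f"{n_diatomics} diatomics exceed the {len(anion_sites)} available "
            "top-surface anion lattice sites")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(anion_sites, size=n_diatomics, replace=False)
    chosen_set = set(int(c) for c in chosen)

    positions, species, charges, masses = [], [], [], []
    groups, ion_ids, bonds = [], [], []
    ion = 0
    for idx, (site, par) in enumerate(zip(sites, parity)):
        r = site * _LATTICE_SPACING
        if idx in chosen_set:
            o = len(positions)
            positions.append(r)
            species.append("O_I")
            charges.append(-_HOST_CHARGE)
            masses.append(mass_of("O"))
            groups.append(GROUP_HAP)
            ion_ids.append(ion)
            positions.append(r + np.array([0.0, 0.0, _OH_LENGTH]))
            species.append("H_I")
            charges.append(0.0)
            masses.append(mass_of("H"))
            groups.append(GROUP_HAP)
            ion_ids.append(ion)
            bonds.append((o, o + 1))
            ion += 1
        else:
            positions.append(r)
            species.append("A" if par == 0 else "B")
            charges.append(_HOST_CHARGE if par == 0 else -_HOST_CHARGE)
            masses.append(mass_of("Na") if par == 0 else mass_of("Cl"))
            groups.append(GROUP_HAP)
            ion_ids.append(-1)

    positions = np.array(positions, dtype=float)
    extent = positions.max(axis=0) - positions.min(axis=0)
    box = np.diag(extent + vacuum_margin)
    positions += (np.diag(box) - extent) / 2 - positions.min(axis=0)

    system = AtomSystem(
        positions=positions, species=np.array(species, dtype=object),
        masses=np.array(masses), charges=np.array(charges), box=box,
        bonds=bonds, groups=np.array(groups, dtype=object),
        ion_ids=np.array(ion_ids),
    )
    return system, toy_forcefield()


def make_velocity_ensemble(t: float, masses: np.ndarray, n: int | None = None,
                           seed: int = 0) -> np.ndarray:
    """Maxwell-distributed velocities (Å/ps): each component Gaussian
    with variance k_B·T/mᵢ.  ``masses`` may be scalar (then ``n`` sets
    the count) or per-atom."""
    if t < 0:
        raise ValueError("temperature must be >= 0")
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    if n is not None and len(masses) == 1:
        masses = np.full(n, masses[0])
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB_KCAL * t * KCAL_TO_INTERNAL / masses)
    return sigma[:, None] * rng.standard_normal((len(masses), 3))


def _displacement_for_distance(base: AtomSystem, ion: int, target: float) -> float:
    """Rigid +z displacement of the ion giving the requested minimum
    distance to the host (bisection; distance is monotone for large z)."""
    ion_atoms = base.ion_atom_indices(ion)
    host = np.flatnonzero(_host_mask(base, ion))

    def f(dz: float) -> float:
        pos = base.positions.copy()
        pos[ion_atoms] += np.array([0.0, 0.0, dz])
        return min_distance_to_host(pos, base.box, base.pbc, ion_atoms, host) - target

    # stay under half the box so the minimum-image distance is monotone in dz
    hi = 0.45 * float(np.linalg.norm(base.box, axis=1).min())
    if f(0.0) >= 0:
        return 0.0
    if f(hi) <= 0:
        raise ValueError(
            f"target distance {target} Å unreachable inside the periodic box")
    return float(brentq(f, 0.0, hi, xtol=1e-6))


def make_scripted_trajectory(base: AtomSystem, events: list[ScriptedEvent],
                             n_frames: int, seed: int = 0,
                             jitter: float = 0.02,
                             frame_interval: float = 1.0) -> Trajectory:
    """Trajectory with detachments scripted at known frames.

    Host atoms (and unscripted ions) get i.i.d. Gaussian thermal jitter
    around their base positions; each scripted ion is rigidly displaced
    along +z so its minimum distance to the host equals the event's
    target from the event frame on (and returns to the bound position at
    ``returns_frame`` if given).  The script is self-verified by
    re-measuring distances with the detachment machinery.
    """
    ions_seen = set()
    for ev in events:
        if ev.ion in ions_seen:
            raise ValueError(f"conflicting events for ion {ev.ion}")
        ions_seen.add(ev.ion)
        if not (0 <= ev.frame < n_frames):
            raise ValueError(f"event frame {ev.frame} outside trajectory")
        if ev.returns_frame is not None and ev.returns_frame <= ev.frame:
            raise ValueError("returns_frame must be after the event frame")

    rng = np.random.default_rng(seed)
    displacements = {ev.ion: _displacement_for_distance(base, ev.ion,
                                                        ev.target_distance)
                     for ev in events}
    scripted_atoms = {ev.ion: base.ion_atom_indices(ev.ion) for ev in events}
    all_scripted = (np.concatenate(list(scripted_atoms.values()))
                    if events else np.array([], dtype=int))

    traj = Trajectory.from_system(base)
    for f in range(n_frames):
        pos = base.positions + jitter * rng.standard_normal(base.positions.shape)
        pos[all_scripted] = base.positions[all_scripted]   # no jitter on scripted ions
        for ev in events:
            out = ev.frame <= f and (ev.returns_frame is None or f < ev.returns_frame)
            if out:
                pos[scripted_atoms[ev.ion]] += np.array(
                    [0.0, 0.0, displacements[ev.ion]])
        traj.append(pos, base.box, f * frame_interval)

    # self-verification: re-measure with the detachment machinery
    for ev in events:
        host = np.flatnonzero(_host_mask(base, ev.ion))
        d_at = min_distance_to_host(traj.positions[ev.frame], base.box, base.pbc,
                                    scripted_atoms[ev.ion], host)
        if abs(d_at - ev.target_distance) > 0.2:
            raise AssertionError(
                f"scripted event for ion {ev.ion} missed its target distance: "
                f"{d_at:.3f} vs {ev.target_distance:.3f}")
        if ev.frame > 0:
            d_before = min_distance_to_host(traj.positions[ev.frame - 1], base.box,
                                            base.pbc, scripted_atoms[ev.ion], host)
            if d_before > DEFAULT_THRESHOLD:
                raise AssertionError(
                    f"ion {ev.ion} already beyond threshold before its event")
    return traj


def make_melting_rg_series(collapse_frame: int, drop_fraction: float,
                           noise: float = 0.0, seed: int = 0,
                           n_frames: int = 200, rg0: float = 20.0,
                           width: float = 5.0,
                           frame_interval: float = 1.0):
    """Plateau-then-sigmoid radius-of-gyration series emulating a melting
    collapse of relative depth ``drop_fraction`` centred at
    ``collapse_frame``, with multiplicative Gaussian noise."""
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    from .analysis import RgSeries
    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames)
    sigmoid = 1.0 / (1.0 + np.exp(-(frames - collapse_frame) / width))
    rg = rg0 * (1.0 - drop_fraction * sigmoid)
    rg = rg * (1.0 + noise * rng.standard_normal(n_frames))
    return RgSeries(times=frames * frame_interval, rg=rg, selection="toy")
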