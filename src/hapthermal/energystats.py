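"""Hydroxyl-removal energy profiles and the associated unit/uncertainty
arithmetic.

The removal scan rigidly translates one or more tagged OH ions out of
the (water-free) crystal along the c axis and records the single-point
total energy at each displacement z; no relaxation is performed, so the
scan is deterministic.  Far from the crystal the profile flattens and
the plateau-minus-bound difference is the removal energy |ΔE|.  The
downstream chain converts |ΔE| to a per-unit-cell energy |ΔE₁| (kcal/mol
and eV) and to an equivalent temperature T = |ΔE₁|/k_B.

Uncertainty model: the quantum position uncertainty of a thermal atom,
Δz = ħ/√(2·m·k_B·T), sets a coordinate blur (~0.2 Å for hydrogen at
1000 K); the steepest energy change over that blur near the crystal
surface gives the energy error Δ(E₀₁), and half of it, relative to |ΔE|,
the relative error δ.  The thermostat temperature dispersion follows
2σ² = T_ref, i.e. σ = √(T_ref/2) (an informal but stated convention,
implemented verbatim).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import EV_PER_KCAL, HBAR_SI, KB_EV, KB_SI
from .forcefield import Evaluator, ForceField
from .system import AtomSystem

__all__ = [
    "EnergyProfile",
    "RemovalResult",
    "removal_profile",
    "total_change",
    "per_cell",
    "energy_to_temperature",
    "thermostat_sigma",
    "thermal_energy",
    "coordinate_uncertainty",
    "profile_error",
    "removal_summary",
]


@dataclass
class EnergyProfile:
    """Total energy vs rigid displacement z of the removed OH ion(s)."""
    z: np.ndarray                  # Å, strictly increasing, z[0] = bound state
    energy: np.ndarray             # kcal/mol
    n_removed: int = 1
    ions: tuple = ()
    flagged: np.ndarray | None = None   # overlap-flagged grid points

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if not np.isfinite(self.energy).all():
            raise ValueError("profile energies must be finite")
        if self.flagged is None:
            self.flagged = np.zeros(len(self.z), dtype=bool)

    @property
    def e0(self) -> float:
        """Bound-state reference energy E(z=0)."""
        return float(self.energy[0])

    @property
    def delta(self) -> np.ndarray:
        """ΔE(z) = E(z) − E₀."""
        return self.energy - self.e0


@dataclass
class RemovalResult:
    """Table-row summary of one removal scenario."""
    delta_e: float          # |ΔE| total, kcal/mol
    n_cells: int
    delta_e1: float = field(init=False)      # kcal/mol per unit cell
    delta_e1_ev: float = field(init=False)   # eV per unit cell
    t_equiv: float = field(init=False)       # K
    energy_error: float | None = None        # Δ(E01), kcal/mol
    relative_error: float | None = None      # δ

    def __post_init__(self):
        self.delta_e1 = per_cell(self.delta_e, self.n_cells)
        self.delta_e1_ev = self.delta_e1 * EV_PER_KCAL
        self.t_equiv = energy_to_temperature(self.delta_e1_ev)


def removal_profile(system: AtomSystem, ff: ForceField, ions,
                    z_grid: np.ndarray,
                    direction: np.ndarray | None = None,
                    overlap_tolerance: float = 1.2) -> EnergyProfile:
    """Scan the total energy while rigidly displacing the given ion(s)
    along the c axis (or ``direction``).

    The grid must start at 0 (the bound position).  Grid points where a
    displaced ion atom comes closer than ``overlap_tolerance`` to a host
    atom are flagged but their energy is still reported.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    if z_grid[0] != 0.0:
        raise ValueError("z grid must start at the bound position z=0")
    ions = [ions] if np.isscalar(ions) else list(ions)
    moved = np.concatenate([system.ion_atom_indices(i) for i in ions])
    if direction is None:
        direction = system.box[2] / np.linalg.norm(system.box[2])
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    host = np.setdiff1d(np.arange(system.n_atoms), moved)
    work = system.copy()
    base = system.positions[moved].copy()
    evaluator = Evaluator(work, ff)
    energies = np.empty(len(z_grid))
    flagged = np.zeros(len(z_grid), dtype=bool)
    for k, z in enumerate(z_grid):
        work.positions[moved] = base + z * direction
        energies[k] = evaluator(work.positions, want_forces=False)[0].total
        if len(host):
            dmin = min(
                float(np.linalg.norm(work.positions[host] - work.positions[a],
                                     axis=1).min())
                for a in moved)
            flagged[k] = dmin < overlap_tolerance
    return EnergyProfile(z=z_grid, energy=energies, n_removed=len(ions),
                         ions=tuple(ions), flagged=flagged)


def total_change(profile: EnergyProfile, plateau_fraction: float = 0.1,
                 flatness: float = 0.01) -> float:
    """|ΔE| = |E(plateau) − E(0)|.

    The plateau is the last ``plateau_fraction`` of the grid; it must be
    flat (range below ``flatness``·|ΔE|), otherwise the grid does not
    reach the asymptote and an error advises a longer scan.
    """
    n_tail = max(2, int(np.ceil(plateau_fraction * len(profile.z))))
    tail = profile.energy[-n_tail:]
    delta = abs(float(tail.mean()) - profile.e0)
    spread = float(tail.max() - tail.min())
    if delta == 0.0 and spread == 0.0:
        return 0.0
    if spread > flatness * max(delta, 1e-12):
        raise ValueError(
            f"no plateau: tail spread {spread:.4g} exceeds {flatness:.0%} of "
            f"|ΔE|={delta:.4g}; extend the z grid")
    return delta


def per_cell(total: float, n_cells: int) -> float:
    """Energy change per unit cell, kcal/mol."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return total / n_cells


def energy_to_temperature(e1_ev: float) -> float:
    """Equivalent temperature T = E/k_B with k_B = 8.6173e-5 eV/K."""
    if e1_ev < 0:
        raise ValueError("energy must be >= 0")
    return e1_ev / KB_EV


def thermostat_sigma(t_ref: float) -> float:
    """Thermostat temperature dispersion σ = √(T_ref/2) from 2σ² = T_ref."""
    if t_ref < 0:
        raise ValueError("T_ref must be >= 0")
    return float(np.sqrt(t_ref / 2.0))


def thermal_energy(t: float) -> float:
    """Thermal energy E_T = k_B·T in eV."""
    if t < 0:
        raise ValueError("temperature must be >= 0")
    return KB_EV * t


def coordinate_uncertainty(mass_kg: float, t: float) -> float:
    """Quantum positional uncertainty Δz = ħ/√(2·m·k_B·T), in Å."""
    if mass_kg <= 0 or t <= 0:
        raise ValueError("mass and temperature must be positive")
    dz_m = HBAR_SI / np.sqrt(2.0 * mass_kg * KB_SI * t)
    return float(dz_m * 1e10)


def profile_error(profile: EnergyProfile, dz: float = 0.2,
                  window: float = 2.0,
                  surface_z: float | None = None) -> tuple[float, float]:
    """Energy error Δ(E₀₁) and relative error δ of a removal profile.

    Δ(E₀₁) is the maximum |E(z+dz) − E(z)| over the near-surface window
    [surface, surface+window]; the spread ±Δ(E₀₁)/2 relative to |ΔE|
    gives δ.  If the grid is coarser than ``dz`` the profile is linearly
    interpolated (with a warning).
    """
    z, e = profile.z, profile.energy
    if surface_z is None:
        # steepest point of the profile marks the surface region
        surface_z = float(z[:-1][np.argmax(np.abs(np.diff(e) / np.diff(z)))])
    grid_step = float(np.min(np.diff(z)))
    if grid_step > dz:
        import warnings
        warnings.warn(
            f"grid step {grid_step:.3g} Å coarser than dz={dz} Å; "
            "interpolating", stacklevel=2)
    z0 = np.arange(surface_z, min(surface_z + window, z[-1] - dz) + 1e-12,
                   min(dz, grid_step))
    if len(z0) == 0:
        z0 = np.array([surface_z])
    e_lo = np.interp(z0, z, e)
    e_hi = np.interp(z0 + dz, z, e)
    err = float(np.max(np.abs(e_hi - e_lo)))
    try:
        delta_e = total_change(profile)
    except ValueError:
        return err, float("nan")   # no plateau: δ undefined
    rel = (err / 2.0) / delta_e if delta_e > 0 else 0.0
    return err, rel


def removal_summary(delta_e: float, n_cells: int,
                    energy_error: float | None = None) -> RemovalResult:
    """Assemble the full conversion chain for one removal scenario."""
    res = RemovalResult(delta_e=delta_e, n_cells=n_cells)
    if energy_error is not None:
        res.energy_error = energy_error
        res.relative_error = (energy_error / 2.0) / delta_e if delta_e else 0.0
    return res
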