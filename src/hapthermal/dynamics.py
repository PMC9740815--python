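"""Velocity-Verlet molecular dynamics with a collisional thermostat.

Temperature control follows the stochastic-collision picture: the system
sits in a bath of virtual point particles whose velocities follow the
Maxwell distribution at the setpoint T_ref.  At Poisson-distributed
random times a virtual particle of mass m₀ elastically collides with a
system atom of mass m, changing its velocity by

    Δv = 2 m₀ / (m₀ + m) · (v₀ − v),

which follows from two-body energy and momentum conservation.  Collision
events are drawn per atom per step as Bernoulli(collision_rate·dt), the
discrete approximation of the Poisson kick process; with m₀ = m every
collision is a full velocity exchange, the fastest-equilibrating and
default choice here (the collision rate and virtual mass are tunable —
they set the coupling strength, not the stationary distribution).

Two run protocols are provided: :func:`run_nvt` at a fixed setpoint and
:func:`run_linear_heating` with T_ref(t) = T₀ + rate·t.  Rigid waters
(and other fixed-length bonds) are maintained by iterative SHAKE/RATTLE
constraint projection.  All randomness flows through a seeded generator,
so a fixed seed gives a bit-identical trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import INTERNAL_TO_KCAL, KB_KCAL, KCAL_TO_INTERNAL
from .forcefield import Evaluator, ForceField
from .system import GROUP_WATER, AtomSystem
from .trajectory import Trajectory

__all__ = [
    "ThermostatConfig",
    "HeatingSchedule",
    "IntegratorConfig",
    "IntegrationError",
    "collision_delta_v",
    "sample_virtual_velocity",
    "kinetic_temperature",
    "rigid_water_constraints",
    "step",
    "run_nvt",
    "run_linear_heating",
]


class IntegrationError(RuntimeError):
    pass


@dataclass
class ThermostatConfig:
    """Collisional-thermostat parameters.

    ``collision_rate`` is per atom per ps; ``m0`` is the virtual-particle
    mass in amu (None means "mass of the struck atom", i.e. full velocity
    exchange).
    """
    collision_rate: float = 10.0
    m0: float | None = None

    def __post_init__(self):
        if self.collision_rate < 0:
            raise ValueError("collision_rate must be >= 0")
        if self.m0 is not None and self.m0 <= 0:
            raise ValueError("m0 must be positive")


@dataclass
class HeatingSchedule:
    """Linear thermostat ramp T_ref(t) = T0 + rate·t for 0 ≤ t ≤ t_max."""
    T0: float        # K
    rate: float      # K/ps
    t_max: float     # ps

    def __call__(self, t: float) -> float:
        if not (0.0 <= t <= self.t_max + 1e-9):
            raise ValueError(f"t={t} outside schedule range [0, {self.t_max}]")
        return self.T0 + self.rate * t


@dataclass
class IntegratorConfig:
    dt: float = 5e-4                 # ps (0.5 fs; stiff O-H springs)
    sample_interval: float = 1.0     # ps between recorded frames
    constraint_tol: float = 1e-8     # Å
    max_coordinate: float = 1e6      # blow-up threshold, Å

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        steps = self.sample_interval / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("sample_interval must be a multiple of dt")


def collision_delta_v(v: np.ndarray, m: float, v0: np.ndarray, m0: float) -> np.ndarray:
    """Elastic-collision velocity jump Δv = 2m₀/(m₀+m)·(v₀ − v)."""
    if m <= 0 or m0 <= 0:
        raise ValueError("masses must be positive")
    return (2.0 * m0 / (m0 + m)) * (np.asarray(v0, dtype=float) - np.asarray(v, dtype=float))


def sample_virtual_velocity(t_ref: float, m0: float,
                            rng: np.random.Generator) -> np.ndarray:
    """One Maxwell-distributed virtual-particle velocity (Å/ps): each
    Cartesian component Gaussian with variance k_B·T_ref/m₀."""
    if t_ref < 0:
        raise ValueError("T_ref must be >= 0")
    sigma = np.sqrt(KB_KCAL * t_ref * KCAL_TO_INTERNAL / m0)
    return sigma * rng.standard_normal(3)


def kinetic_temperature(system: AtomSystem, n_constraints: int = 0) -> float:
    """Equipartition temperature T = Σ mᵢvᵢ² / (N_dof·k_B) with
    N_dof = 3N − n_constraints."""
    n = system.n_atoms
    if n == 0:
        raise ValueError("empty system")
    ndof = 3 * n - n_constraints
    ke_kcal = 0.5 * float(np.sum(system.masses[:, None] * system.velocities ** 2)) \
        * INTERNAL_TO_KCAL
    return 2.0 * ke_kcal / (ndof * KB_KCAL)


def rigid_water_constraints(system: AtomSystem) -> list[tuple[int, int, float]]:
    """Fixed-distance constraints (i, j, d) rigidifying every 3-site
    water (two O-H bonds plus the H-H distance), taken from the current
    geometry."""
    out = []
    w = np.flatnonzero(system.groups == GROUP_WATER)
    for k in range(0, len(w) - 2, 3):
        o, h1, h2 = int(w[k]), int(w[k + 1]), int(w[k + 2])
        for i, j in ((o, h1), (o, h2), (h1, h2)):
            d = float(np.linalg.norm(system.positions[j] - system.positions[i]))
            out.append((i, j, d))
    return out


def _shake(pos, masses, constraints, tol, max_iter=500):
    inv = 1.0 / masses
    for _ in range(max_iter):
        worst = 0.0
        for i, j, d in constraints:
            rij = pos[j] - pos[i]
            r = np.linalg.norm(rij)
            delta = r - d
            worst = max(worst, abs(delta))
            if abs(delta) < tol:
                continue
            u = rij / r
            wtot = inv[i] + inv[j]
            pos[i] += (inv[i] / wtot) * delta * u
            pos[j] -= (inv[j] / wtot) * delta * u
        if worst < tol:
            return
    raise IntegrationError("SHAKE failed to converge")


def _rattle(pos, vel, masses, constraints, tol, max_iter=500):
    inv = 1.0 / masses
    for _ in range(max_iter):
        worst = 0.0
        for i, j, d in constraints:
            rij = pos[j] - pos[i]
            u = rij / np.linalg.norm(rij)
            vrel = float((vel[j] - vel[i]) @ u)
            worst = max(worst, abs(vrel))
            if abs(vrel) < tol:
                continue
            g = vrel / (inv[i] + inv[j])
            vel[i] += g * inv[i] * u
            vel[j] -= g * inv[j] * u
        if worst < tol:
            return
    raise IntegrationError("RATTLE failed to converge")


def _step_inplace(pos, vel, masses, evaluator, cfg, thermostat, t_ref_now,
                  rng, constraints, f_prev, step_index):
    """One velocity-Verlet step (+SHAKE/RATTLE, + thermostat collisions);
    mutates pos/vel, returns forces at the new positions."""
    dt = cfg.dt
    acc = f_prev * (KCAL_TO_INTERNAL / masses[:, None])
    vel += 0.5 * dt * acc
    pos += dt * vel
    if constraints:
        _shake(pos, masses, constraints, cfg.constraint_tol)
    _, f_new = evaluator(pos)
    vel += 0.5 * dt * f_new * (KCAL_TO_INTERNAL / masses[:, None])
    if constraints:
        _rattle(pos, vel, masses, constraints, cfg.constraint_tol)

    if thermostat is not None and thermostat.collision_rate > 0:
        p = min(thermostat.collision_rate * dt, 1.0)
        hits = np.flatnonzero(rng.random(len(masses)) < p)
        if len(hits):
            m0s = masses[hits] if thermostat.m0 is None \
                else np.full(len(hits), thermostat.m0)
            sig = np.sqrt(KB_KCAL * t_ref_now * KCAL_TO_INTERNAL / m0s)
            v0 = sig[:, None] * rng.standard_normal((len(hits), 3))
            fac = (2.0 * m0s / (m0s + masses[hits]))[:, None]
            vel[hits] += fac * (v0 - vel[hits])
        if constraints:
            _rattle(pos, vel, masses, constraints, cfg.constraint_tol)

    if not np.isfinite(pos).all() or np.abs(pos).max() > cfg.max_coordinate:
        raise IntegrationError(f"numeric blow-up at step {step_index}")
    return f_new


def step(system: AtomSystem, ff: ForceField, cfg: IntegratorConfig,
         thermostat: ThermostatConfig | None, t: float,
         rng: np.random.Generator,
         constraints: list | None = None) -> AtomSystem:
    """Advance one timestep and return the new system (input untouched)."""
    out = system.copy()
    pos, vel, masses = out.positions, out.velocities, out.masses
    cons = constraints if constraints is not None else rigid_water_constraints(out)
    evaluator = Evaluator(out, ff)
    _, f0 = evaluator(pos)
    _step_inplace(pos, vel, masses, evaluator, cfg, thermostat, t, rng, cons, f0, 0)
    out.positions, out.velocities = pos, vel
    return out


def _run(system: AtomSystem, ff: ForceField, schedule, duration: float,
         cfg: IntegratorConfig, thermostat: ThermostatConfig | None,
         seed: int) -> Trajectory:
    cfg = cfg or IntegratorConfig()
    rng = np.random.default_rng(seed)
    work = system.copy()
    pos, vel, masses = work.positions, work.velocities, work.masses
    constraints = rigid_water_constraints(work)
    ncons = len(constraints)

    traj = Trajectory.from_system(work)
    t_ref0 = schedule(0.0)
    traj.append(pos.copy(), work.box, 0.0, t_ref0,
                kinetic_temperature(work, ncons))
    traj.velocities.append(vel.copy())

    n_steps = int(round(duration / cfg.dt))
    steps_per_frame = int(round(cfg.sample_interval / cfg.dt))
    evaluator = Evaluator(work, ff)
    _, f = evaluator(pos)
    for s in range(1, n_steps + 1):
        t_now = s * cfg.dt
        t_ref_now = schedule(min(t_now, duration))
        f = _step_inplace(pos, vel, masses, evaluator, cfg, thermostat,
                          t_ref_now, rng, constraints, f, s)
        if s % steps_per_frame == 0 or s == n_steps:
            if not traj.times or t_now > traj.times[-1]:
                work.velocities = vel
                traj.append(pos.copy(), work.box, t_now, t_ref_now,
                            kinetic_temperature(work, ncons))
                traj.velocities.append(vel.copy())
    return traj


def run_nvt(system: AtomSystem, ff: ForceField, t_ref: float, duration: float,
            cfg: IntegratorConfig | None = None,
            thermostat: ThermostatConfig | None = None,
            seed: int = 0) -> Trajectory:
    """Fixed-setpoint (NVT) run; frames recorded every sample interval.

    ``thermostat=None`` uses the default collisional thermostat; pass
    ``ThermostatConfig(collision_rate=0)`` for plain NVE dynamics."""
    if thermostat is None:
        thermostat = ThermostatConfig()
    if t_ref < 0:
        raise ValueError("T_ref must be >= 0")
    return _run(system, ff, lambda t: t_ref, duration,
                cfg or IntegratorConfig(), thermostat, seed)


def run_linear_heating(system: AtomSystem, ff: ForceField,
                       schedule: HeatingSchedule,
                       cfg: IntegratorConfig | None = None,
                       thermostat: ThermostatConfig | None = None,
                       seed: int = 0) -> Trajectory:
    """Linear-heating run: the thermostat setpoint ramps as T0 + rate·t
    and is recorded per frame."""
    if thermostat is None:
        thermostat = ThermostatConfig()
    return _run(system, ff, schedule, schedule.t_max,
                cfg or IntegratorConfig(), thermostat, seed)
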