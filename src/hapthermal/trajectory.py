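"""Trajectory container and extended-XYZ reading/writing.

A :class:`Trajectory` is an ordered set of frames at a fixed sampling
interval (1 ps by convention), each frame holding positions, the box,
the simulation time, the thermostat setpoint T_ref and the instantaneous
kinetic temperature.  Per-atom metadata (species, masses, charges,
groups, hydroxyl-ion ids) is shared across frames.

The canonical on-disk format is extended XYZ: one block per frame, a
``Lattice=...`` comment line with ``Properties`` column declarations and
``Time`` / ``T_ref`` / ``T_kin`` key-value metadata.  Bond topology is
not part of XYZ; on read, hydroxyl O–H bonds are rebuilt from the ion-id
column and water bonds from O_W/H_W/H_W triples.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .constants import mass_of
from .system import GROUP_HAP, GROUP_WATER, AtomSystem

__all__ = ["Trajectory", "write_extxyz", "read_extxyz"]


@dataclass
class Trajectory:
    species: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    groups: np.ndarray
    ion_ids: np.ndarray
    pbc: np.ndarray
    bonds: list = field(default_factory=list)
    positions: list = field(default_factory=list)   # list of (N,3)
    boxes: list = field(default_factory=list)       # list of (3,3)
    times: list = field(default_factory=list)       # ps
    t_ref: list = field(default_factory=list)       # K
    t_kin: list = field(default_factory=list)       # K
    velocities: list = field(default_factory=list)  # optional, parallel to positions

    @classmethod
    def from_system(cls, system: AtomSystem) -> "Trajectory":
        return cls(
            species=system.species.copy(), masses=system.masses.copy(),
            charges=system.charges.copy(), groups=system.groups.copy(),
            ion_ids=system.ion_ids.copy(), pbc=system.pbc.copy(),
            bonds=list(system.bonds),
        )

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def __len__(self) -> int:
        return self.n_frames

    def append(self, positions: np.ndarray, box: np.ndarray, time: float,
               t_ref: float = np.nan, t_kin: float = np.nan) -> None:
        if len(positions) != self.n_atoms:
            raise ValueError("frame atom count mismatch")
        if self.times and time <= self.times[-1]:
            raise ValueError("frame times must be strictly increasing")
        self.positions.append(np.array(positions, dtype=float))
        self.boxes.append(np.array(box, dtype=float))
        self.times.append(float(time))
        self.t_ref.append(float(t_ref))
        self.t_kin.append(float(t_kin))

    def frame_system(self, i: int, velocities: np.ndarray | None = None) -> AtomSystem:
        return AtomSystem(
            positions=self.positions[i].copy(), species=self.species.copy(),
            masses=self.masses.copy(), charges=self.charges.copy(),
            box=self.boxes[i].copy(), pbc=self.pbc.copy(),
            velocities=velocities, bonds=list(self.bonds),
            groups=self.groups.copy(), ion_ids=self.ion_ids.copy(),
        )

    def validate(self) -> None:
        t = np.asarray(self.times)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times not strictly increasing")
        for p in self.positions:
            if len(p) != self.n_atoms:
                raise ValueError("inconsistent atom count across frames")


# ----------------------------------------------------------------------
# extended-XYZ
# ----------------------------------------------------------------------

def _fmt_comment(box, pbc, time, t_ref, t_kin, with_vel, extra=None) -> str:
    lat = " ".join(f"{v:.10g}" for v in np.asarray(box).ravel())
    props = "species:S:1:pos:R:3"
    if with_vel:
        props += ":vel:R:3"
    props += ":mass:R:1:charge:R:1:group:S:1:ion_id:I:1"
    parts = [f'Lattice="{lat}"', f"Properties={props}",
             'pbc="' + " ".join("T" if p else "F" for p in pbc) + '"',
             f"Time={time:.10g}"]
    if np.isfinite(t_ref):
        parts.append(f"T_ref={t_ref:.10g}")
    if np.isfinite(t_kin):
        parts.append(f"T_kin={t_kin:.10g}")
    if extra:
        parts.extend(f"{k}={v}" for k, v in extra.items())
    return " ".join(parts)


def write_extxyz(path, traj: Trajectory, velocities: list | None = None) -> None:
    """Write all frames of a trajectory as extended XYZ."""
    with open(path, "w") as fh:
        for fi in range(traj.n_frames):
            vel = velocities[fi] if velocities is not None else None
            fh.write(f"{traj.n_atoms}\n")
            fh.write(_fmt_comment(traj.boxes[fi], traj.pbc, traj.times[fi],
                                  traj.t_ref[fi], traj.t_kin[fi],
                                  vel is not None) + "\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.positions[fi][a]
                line = f"{traj.species[a]} {x:.10f} {y:.10f} {z:.10f}"
                if vel is not None:
                    vx, vy, vz = vel[a]
                    line += f" {vx:.10f} {vy:.10f} {vz:.10f}"
                line += (f" {traj.masses[a]:.6f} {traj.charges[a]:.6f}"
                         f" {traj.groups[a]} {traj.ion_ids[a]}")
                fh.write(line + "\n")


def write_structure_extxyz(path, system: AtomSystem, time: float = 0.0) -> None:
    """Write a single structure (with velocities) as one extended-XYZ frame."""
    traj = Trajectory.from_system(system)
    traj.append(system.positions, system.box, time)
    write_extxyz(path, traj, velocities=[system.velocities])


_KV_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict:
    out = {}
    for m in _KV_RE.finditer(line):
        out[m.group(1)] = m.group(2) if m.group(2) is not None else m.group(3)
    return out


def _rebuild_bonds(species, ion_ids, groups) -> list[tuple[int, int]]:
    bonds = []
    for ion in np.unique(ion_ids[ion_ids >= 0]):
        members = np.flatnonzero(ion_ids == ion)
        if len(members) == 2:
            bonds.append((int(members[0]), int(members[1])))
    w = np.flatnonzero(groups == GROUP_WATER)
    for k in range(0, len(w) - 2, 3):
        o, h1, h2 = w[k], w[k + 1], w[k + 2]
        if str(species[o]).startswith("O") and str(species[h1]).startswith("H"):
            bonds.append((int(o), int(h1)))
            bonds.append((int(o), int(h2)))
    return bonds


def read_extxyz(path) -> Trajectory:
    """Read an extended-XYZ trajectory written by this package (or any
    file with species + positions; missing metadata gets defaults)."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos0 = 0
    while pos0 < len(lines):
        if not lines[pos0].strip():
            pos0 += 1
            continue
        try:
            n = int(lines[pos0].strip())
        except ValueError as exc:
            raise ValueError(f"malformed atom-count line {pos0 + 1}: {lines[pos0]!r}") from exc
        if pos0 + 1 + n >= len(lines) + 1:
            raise ValueError(f"truncated frame starting at line {pos0 + 1}")
        meta = _parse_comment(lines[pos0 + 1])
        rows = [lines[pos0 + 2 + k].split() for k in range(n)]
        frames.append((meta, rows))
        pos0 += 2 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")

    meta0, rows0 = frames[0]
    props = meta0.get("Properties", "species:S:1:pos:R:3")
    cols = props.split(":")
    names, widths = cols[0::3], [int(w) for w in cols[2::3]]
    offsets, off = {}, 0
    for name, w in zip(names, widths):
        offsets[name] = (off, w)
        off += w

    def col(rows, name, default=None):
        if name not in offsets:
            return default
        o, w = offsets[name]
        return [r[o:o + w] for r in rows]

    species = np.array([c[0] for c in col(rows0, "species")], dtype=object)
    groups_raw = col(rows0, "group")
    groups = (np.array([c[0] for c in groups_raw], dtype=object)
              if groups_raw else np.array([GROUP_HAP] * len(species), dtype=object))
    ion_raw = col(rows0, "ion_id")
    ion_ids = (np.array([int(c[0]) for c in ion_raw])
               if ion_raw else np.full(len(species), -1))
    pbc_str = meta0.get("pbc", "T T T").split()
    pbc = np.array([s.upper().startswith("T") for s in pbc_str])
    mass_raw = col(rows0, "mass")
    masses = (np.array([float(c[0]) for c in mass_raw]) if mass_raw
              else np.array([mass_of(str(s), default=1.0) for s in species]))
    charge_raw = col(rows0, "charge")
    charges = (np.array([float(c[0]) for c in charge_raw]) if charge_raw
               else np.zeros(len(species)))

    traj = Trajectory(species=species, masses=masses,
                      charges=charges, groups=groups,
                      ion_ids=ion_ids, pbc=pbc,
                      bonds=_rebuild_bonds(species, ion_ids, groups))
    for fi, (meta, rows) in enumerate(frames):
        if len(rows) != len(species):
            raise ValueError(f"frame {fi}: atom count changed")
        pos = np.array([[float(v) for v in c] for c in col(rows, "pos")])
        lat = meta.get("Lattice")
        box = (np.array([float(v) for v in lat.split()]).reshape(3, 3)
               if lat else np.eye(3) * 1e6)
        traj.append(pos, box, float(meta.get("Time", fi)),
                    float(meta.get("T_ref", "nan")), float(meta.get("T_kin", "nan")))
        vel = col(rows, "vel")
        if vel is not None:
            traj.velocities.append(np.array([[float(v) for v in c] for c in vel]))
    return traj
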