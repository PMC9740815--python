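"""Structure file I/O (PDB and extended XYZ), run configuration and the
replicate protocol driver.

Extended XYZ is the canonical format (exact round-trip, per-frame
metadata); PDB is provided for single structures with positions kept to
1e-3 Å, the group tag in the segment-id columns and the hydroxyl-ion id
in the B-factor column.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import average_over_runs, detachment_series
from .constants import mass_of
from .dynamics import (HeatingSchedule, IntegratorConfig, ThermostatConfig,
                       run_linear_heating, run_nvt)
from .forcefield import ForceField
from .system import GROUP_HAP, AtomSystem
from .trajectory import (Trajectory, read_extxyz, write_extxyz,
                         write_structure_extxyz)

__all__ = [
    "read_structure",
    "write_structure",
    "write_pdb",
    "read_pdb",
    "ledger_to_csv",
    "RunConfig",
    "run_protocol",
]


# ----------------------------------------------------------------------
# PDB
# ----------------------------------------------------------------------

def write_pdb(path, system: AtomSystem) -> None:
    """Single-structure PDB: group tag in segID (cols 73-76), ion id in
    the B-factor column, element symbol in cols 77-78."""
    with open(path, "w") as fh:
        a, b, c = np.linalg.norm(system.box, axis=1)
        fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1\n")
        for i in range(system.n_atoms):
            name = str(system.species[i])[:4]
            el = name.split("_")[0][:2]
            x, y, z = system.positions[i]
            seg = str(system.groups[i])[:4]
            fh.write(
                f"ATOM  {i + 1:5d} {name:<4s} MOL A{1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{float(system.ion_ids[i]):6.2f}"
                f"      {seg:<4s}{el:>2s}\n")
        fh.write("END\n")


def read_pdb(path) -> AtomSystem:
    """Parse ATOM/HETATM records back into a system.

    A missing element column is inferred from the atom name (warning
    logged); malformed records raise a parse error naming the line.
    """
    positions, species, groups, ion_ids = [], [], [], []
    box = np.eye(3) * 1e6
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(ln.startswith(("ATOM", "HETATM")) for ln in lines):
        raise ValueError(f"no ATOM records found in {path}")
    for ln_no, ln in enumerate(lines, 1):
        if ln.startswith("CRYST1"):
            a, b, c = float(ln[6:15]), float(ln[15:24]), float(ln[24:33])
            box = np.diag([a, b, c])
        if not ln.startswith(("ATOM", "HETATM")):
            continue
        try:
            name = ln[12:16].strip()
            x, y, z = float(ln[30:38]), float(ln[38:46]), float(ln[46:54])
            bfac = ln[60:66].strip()
            seg = ln[72:76].strip()
            el = ln[76:78].strip()
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed PDB record at line {ln_no}: {ln!r}") from exc
        if not el:
            el = "".join(ch for ch in name.split("_")[0] if ch.isalpha())[:2]
            warnings.warn(
                f"line {ln_no}: element column missing, inferred {el!r} "
                f"from atom name {name!r}", stacklevel=2)
        positions.append((x, y, z))
        species.append(name if name else el)
        groups.append(seg if seg else GROUP_HAP)
        ion_ids.append(int(float(bfac)) if bfac else -1)

    species_arr = np.array(species, dtype=object)
    ion_arr = np.array(ion_ids, dtype=int)
    bonds = []
    for ion in np.unique(ion_arr[ion_arr >= 0]):
        members = np.flatnonzero(ion_arr == ion)
        if len(members) == 2:
            bonds.append((int(members[0]), int(members[1])))
    return AtomSystem(
        positions=np.array(positions), species=species_arr,
        masses=np.array([mass_of(s, default=1.0) for s in species]),
        charges=np.zeros(len(species)), box=box, bonds=bonds,
        groups=np.array(groups, dtype=object), ion_ids=ion_arr,
    )


def write_structure(path, system: AtomSystem, fmt: str | None = None) -> None:
    fmt = fmt or _infer_format(path)
    if fmt == "pdb":
        write_pdb(path, system)
    elif fmt == "extxyz":
        write_structure_extxyz(path, system)
    else:
        raise ValueError(f"unknown structure format {fmt!r}")


def read_structure(path, fmt: str | None = None) -> AtomSystem:
    fmt = fmt or _infer_format(path)
    if fmt == "pdb":
        return read_pdb(path)
    if fmt == "extxyz":
        traj = read_extxyz(path)
        vel = traj.velocities[0] if traj.velocities else None
        return traj.frame_system(0, velocities=vel)
    raise ValueError(f"unknown structure format {fmt!r}")


def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".pdb":
        return "pdb"
    if suffix in (".xyz", ".extxyz"):
        return "extxyz"
    raise ValueError(f"cannot infer structure format from {path}")


def ledger_to_csv(path, ledger) -> None:
    pd.DataFrame({"time_ps": ledger.times, "t_ref_K": ledger.t_ref,
                  "count": ledger.counts}).to_csv(path, index=False)


def ledger_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ----------------------------------------------------------------------
# protocol driver
# ----------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one replicate campaign needs.

    ``protocol`` is ``fixed-T`` (one run per setpoint in ``temperatures``)
    or ``linear-heating`` (one ramp per replicate); replicate r uses seed
    ``master_seed + r``, so the aggregate report is a pure function of
    the config.
    """
    structure: str                       # path to the starting structure
    forcefield: str                      # path to the force-field YAML
    out_dir: str
    protocol: str = "fixed-T"            # "fixed-T" | "linear-heating"
    temperatures: list = field(default_factory=lambda: list(np.arange(800.0, 1176.0, 25.0)))
    t0: float = 700.0                    # linear-heating start, K
    heating_rate: float = 0.1            # K/ps
    t_max: float = 7000.0                # ps
    duration: float = 10.0               # ps per fixed-T run
    replicates: int = 1
    master_seed: int = 0
    dt: float = 5e-4                     # ps
    sample_interval: float = 1.0         # ps
    collision_rate: float = 10.0         # per atom per ps
    detach_threshold: float = 5.0        # Å

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.protocol not in ("fixed-T", "linear-heating"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        for p in (self.structure, self.forcefield):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_protocol(config: RunConfig) -> dict:
    """Execute all replicates of a protocol, writing one extended-XYZ
    trajectory and one detachment CSV per run plus an aggregate JSON
    report; existing per-run outputs are reused (resumability)."""
    from .io import read_structure  # self-import keeps monkeypatching simple
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    system = read_structure(config.structure)
    ff = ForceField.from_yaml(config.forcefield)
    cfg = IntegratorConfig(dt=config.dt, sample_interval=config.sample_interval)
    thermo = ThermostatConfig(collision_rate=config.collision_rate)

    if config.protocol == "fixed-T":
        jobs = [(f"T{int(t)}_r{r}", ("nvt", float(t)), config.master_seed + r)
                for t in config.temperatures for r in range(config.replicates)]
    else:
        jobs = [(f"heat_r{r}", ("heat", None), config.master_seed + r)
                for r in range(config.replicates)]

    report = {"protocol": config.protocol, "master_seed": config.master_seed,
              "runs": {}, "failed": []}
    series_by_key: dict = {}
    for run_id, (kind, t), seed in jobs:
        traj_path = out / f"{run_id}.extxyz"
        csv_path = out / f"{run_id}_detach.csv"
        try:
            if traj_path.exists() and csv_path.exists():
                df = pd.read_csv(csv_path)
                counts = df["count"].to_numpy()
                final = int(counts[-1])
            else:
                if kind == "nvt":
                    traj = run_nvt(system, ff, t, config.duration, cfg, thermo, seed)
                else:
                    sched = HeatingSchedule(config.t0, config.heating_rate,
                                            config.t_max)
                    traj = run_linear_heating(system, ff, sched, cfg, thermo, seed)
                write_extxyz(traj_path, traj)
                ledger = detachment_series(traj, config.detach_threshold)
                ledger_to_csv(csv_path, ledger)
                counts = np.asarray(ledger.counts)
                final = int(counts[-1])
            key = t if kind == "nvt" else "heat"
            series_by_key.setdefault(key, []).append(counts)
            report["runs"][run_id] = {"seed": seed, "final_count": final,
                                      "trajectory": str(traj_path),
                                      "detachment_csv": str(csv_path)}
        except Exception as exc:   # partial-results contract
            report["failed"].append({"run": run_id, "error": str(exc)})

    report["aggregate"] = {}
    for key, series in sorted(series_by_key.items(), key=lambda kv: str(kv[0])):
        n = min(len(s) for s in series)
        mean, sem = average_over_runs([s[:n] for s in series])
        report["aggregate"][str(key)] = {
            "mean_final_count": float(mean[-1]),
            "sem_final_count": float(sem[-1]),
            "n_runs": len(series),
        }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
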