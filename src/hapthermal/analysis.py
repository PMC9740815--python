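"""Trajectory analysis: hydroxyl detachment counting, radius-of-gyration
melting detection, replicate averaging and onset-temperature estimation.

Detachment counting works on a per-ion binary ledger V of length n (one
entry per tagged OH ion).  At each frame the minimum distance from each
ion — taken over *both* its O and H atoms, the conservative reading — to
the remaining host (hydroxyapatite) atoms is computed under the minimum
image convention; if it exceeds the threshold (5 Å by default) the ion's
entry latches to 1 and stays 1 forever.  The running sum of V is the
number of ions that have *ever* detached, a monotone non-decreasing
series regardless of ions later re-approaching the crystal.

Melting is flagged from the radius of gyration Rg(t) of the crystal
selection: Rg² · M equals the moment of inertia about the centre of
mass, so a flat slab collapsing into a globule shows a sustained drop of
Rg from its initial plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import GROUP_HAP, min_image_distance
from .trajectory import Trajectory

__all__ = [
    "DetachmentLedger",
    "RgSeries",
    "min_distance_to_host",
    "update_ledger",
    "detachment_series",
    "radius_of_gyration",
    "rg_series",
    "average_over_runs",
    "onset_temperature",
    "melting_flag",
]

DEFAULT_THRESHOLD = 5.0  # Å


@dataclass
class DetachmentLedger:
    """Binary per-ion detachment record plus its cumulative time series."""
    v: np.ndarray                 # (n_ions,) uint8, latching
    threshold: float = DEFAULT_THRESHOLD
    times: list = field(default_factory=list)
    counts: list = field(default_factory=list)   # cumulative count per frame
    t_ref: list = field(default_factory=list)

    @classmethod
    def empty(cls, n_ions: int, threshold: float = DEFAULT_THRESHOLD) -> "DetachmentLedger":
        return cls(v=np.zeros(n_ions, dtype=np.uint8), threshold=threshold)

    @property
    def count(self) -> int:
        return int(self.v.sum())

    def validate(self) -> None:
        if not np.isin(self.v, (0, 1)).all():
            raise ValueError("ledger entries must be 0 or 1")
        c = np.asarray(self.counts)
        if len(c) > 1 and np.any(np.diff(c) < 0):
            raise ValueError("cumulative count must be monotone non-decreasing")


def _host_mask(traj_or_sys, ion: int, include_other_hydroxyls: bool = True,
               include_water: bool = False) -> np.ndarray:
    groups = traj_or_sys.groups
    ion_ids = traj_or_sys.ion_ids
    mask = groups == GROUP_HAP
    if include_water:
        mask = mask | (groups != GROUP_HAP)
    mask &= ion_ids != ion
    if not include_other_hydroxyls:
        mask &= ion_ids < 0
    return mask


def min_distance_to_host(positions: np.ndarray, box: np.ndarray, pbc: np.ndarray,
                         ion_atoms: np.ndarray, host_atoms: np.ndarray) -> float:
    """Minimum-image minimum distance between an ion's atoms (O and H)
    and a host atom set."""
    if len(host_atoms) == 0:
        raise ValueError("empty host set")
    if np.intersect1d(ion_atoms, host_atoms).size:
        raise ValueError("ion atoms and host atoms must be disjoint")
    best = np.inf
    for a in ion_atoms:
        d = min_image_distance(positions[host_atoms] - positions[a], box, pbc)
        best = min(best, float(d.min()))
    return best


def update_ledger(ledger: DetachmentLedger, traj: Trajectory, frame: int,
                  include_other_hydroxyls: bool = True,
                  include_water: bool = False) -> DetachmentLedger:
    """Latch ledger entries for ions whose minimum distance to the host
    exceeds the threshold at this frame, and append the cumulative count."""
    ions = np.unique(traj.ion_ids[traj.ion_ids >= 0])
    if len(ions) != len(ledger.v):
        raise ValueError(
            f"ledger dimension {len(ledger.v)} != ion count {len(ions)}")
    pos = traj.positions[frame]
    if len(pos) != traj.n_atoms:
        raise ValueError("frame atom count mismatch")
    box = traj.boxes[frame]
    for k, ion in enumerate(ions):
        if ledger.v[k]:
            continue
        ion_atoms = np.flatnonzero(traj.ion_ids == ion)
        host = np.flatnonzero(_host_mask(traj, ion, include_other_hydroxyls,
                                         include_water))
        if min_distance_to_host(pos, box, traj.pbc, ion_atoms, host) > ledger.threshold:
            ledger.v[k] = 1
    ledger.times.append(traj.times[frame])
    ledger.counts.append(ledger.count)
    ledger.t_ref.append(traj.t_ref[frame])
    return ledger


def detachment_series(traj: Trajectory, threshold: float = DEFAULT_THRESHOLD,
                      include_other_hydroxyls: bool = True,
                      include_water: bool = False) -> DetachmentLedger:
    """Run the detachment-counting algorithm over a whole trajectory."""
    n_ions = len(np.unique(traj.ion_ids[traj.ion_ids >= 0]))
    if n_ions == 0:
        raise ValueError("trajectory has no tagged OH ions")
    ledger = DetachmentLedger.empty(n_ions, threshold)
    for f in range(traj.n_frames):
        update_ledger(ledger, traj, f, include_other_hydroxyls, include_water)
    ledger.validate()
    return ledger


# ----------------------------------------------------------------------
# radius of gyration / melting
# ----------------------------------------------------------------------

@dataclass
class RgSeries:
    times: np.ndarray   # ps
    rg: np.ndarray      # Å
    selection: str = "HAP"


def radius_of_gyration(positions: np.ndarray, masses: np.ndarray,
                       selection: np.ndarray | None = None) -> float:
    """Mass-weighted RMS distance from the centre of mass:
    Rg = sqrt(Σ mᵢ|rᵢ − r_com|² / Σ mᵢ)."""
    if selection is not None:
        positions = positions[selection]
        masses = masses[selection]
    if len(positions) == 0:
        raise ValueError("empty selection")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    com = np.average(positions, axis=0, weights=masses)
    return float(np.sqrt(np.average(np.sum((positions - com) ** 2, axis=1),
                                    weights=masses)))


def rg_series(traj: Trajectory, selection: np.ndarray | None = None,
              tag: str = "HAP") -> RgSeries:
    if selection is None:
        selection = np.flatnonzero(traj.groups == GROUP_HAP)
    rg = np.array([radius_of_gyration(traj.positions[f], traj.masses, selection)
                   for f in range(traj.n_frames)])
    return RgSeries(times=np.asarray(traj.times, dtype=float), rg=rg, selection=tag)


# ----------------------------------------------------------------------
# replicate statistics
# ----------------------------------------------------------------------

def average_over_runs(series: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and standard error over equal-length replicate series."""
    arr = [np.asarray(s, dtype=float) for s in series]
    lengths = {len(a) for a in arr}
    if len(lengths) != 1:
        raise ValueError(f"series lengths differ: {sorted(lengths)}")
    stacked = np.vstack(arr)
    mean = stacked.mean(axis=0)
    m = len(arr)
    sem = (stacked.std(axis=0, ddof=1) / np.sqrt(m)) if m > 1 else np.zeros_like(mean)
    return mean, sem


def onset_temperature(t_ref: np.ndarray, mean_counts: np.ndarray,
                      window: float = 50.0,
                      slope_threshold: float = 0.02) -> dict:
    """Smallest setpoint temperature where the sliding-window slope of
    the mean detachment curve exceeds ``slope_threshold`` (ions/K).

    Returns {"onset": K or None, "window": K, "slope_threshold": ions/K}.
    """
    t = np.asarray(t_ref, dtype=float)
    y = np.asarray(mean_counts, dtype=float)
    if len(t) != len(y) or len(t) < 2:
        raise ValueError("need matched series of length >= 2")
    order = np.argsort(t)
    t, y = t[order], y[order]
    for i in range(len(t)):
        sel = (t >= t[i]) & (t <= t[i] + window)
        if sel.sum() < 2:
            continue
        slope = np.polyfit(t[sel], y[sel], 1)[0]
        if slope > slope_threshold:
            return {"onset": float(t[i]), "window": window,
                    "slope_threshold": slope_threshold}
    return {"onset": None, "window": window, "slope_threshold": slope_threshold}


def melting_flag(series: RgSeries, drop_fraction: float = 0.1,
                 plateau_frames: int = 5, smooth_frames: int = 5) -> tuple[bool, float | None]:
    """Flag a sustained relative Rg collapse of at least ``drop_fraction``
    below the initial plateau; returns (melted, collapse time or None).

    The initial plateau is the mean of the first ``plateau_frames``
    frames and the series is boxcar-smoothed over ``smooth_frames``
    before thresholding, so isolated noise spikes do not trigger."""
    rg = np.asarray(series.rg, dtype=float)
    times = np.asarray(series.times, dtype=float)
    if len(rg) < plateau_frames + 1:
        raise ValueError(
            f"series too short for a {plateau_frames}-frame plateau window")
    plateau = rg[:plateau_frames].mean()
    kernel = np.ones(smooth_frames) / smooth_frames
    smoothed = np.convolve(rg, kernel, mode="valid")
    t_smooth = times[smooth_frames - 1:]
    below = smoothed <= plateau * (1.0 - drop_fraction)
    if not below.any():
        return False, None
    return True, float(t_smooth[int(np.argmax(below))])
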