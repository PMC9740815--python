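"""Atomistic system container and periodic-geometry helpers.

An :class:`AtomSystem` stores Cartesian coordinates in Å, velocities in
Å/ps, masses in amu and charges in units of the elementary charge, plus a
bond list, a periodic box (3×3 matrix of row cell vectors with per-axis
periodic flags) and group bookkeeping: every atom belongs to a group
(``"HAP"`` or ``"WAT"``) and hydroxyl ions additionally carry a
non-negative integer ion id shared by their O and H atoms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

GROUP_HAP = "HAP"
GROUP_WATER = "WAT"

__all__ = [
    "AtomSystem",
    "GROUP_HAP",
    "GROUP_WATER",
    "min_image_displacement",
    "min_image_distance",
]


def _neighbor_shifts(pbc: np.ndarray) -> np.ndarray:
    """Integer lattice shifts (−1, 0, 1) on the periodic axes only."""
    ranges = [(-1, 0, 1) if p else (0,) for p in pbc]
    return np.array(list(itertools.product(*ranges)), dtype=float)


def min_image_displacement(dr: np.ndarray, box: np.ndarray, pbc: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) for raw displacement(s) ``dr``.

    Exact for any (possibly triclinic) cell: fractional coordinates are
    wrapped by rounding and the result refined over the 27 neighbouring
    images, which recovers the true minimum even for strongly skewed
    cells (hexagonal γ=120° included).  Non-periodic axes are left alone.
    """
    dr = np.asarray(dr, dtype=float)
    pbc = np.asarray(pbc, dtype=bool)
    if not pbc.any():
        return dr
    single = dr.ndim == 1
    dr2 = np.atleast_2d(dr)
    frac = np.linalg.solve(box.T, dr2.T).T
    frac[:, pbc] -= np.round(frac[:, pbc])
    base = frac @ box
    if _is_orthorhombic(box):
        out = base
    else:
        shifts = _neighbor_shifts(pbc) @ box
        cand = base[:, None, :] + shifts[None, :, :]
        best = np.argmin(np.einsum("ijk,ijk->ij", cand, cand), axis=1)
        out = cand[np.arange(len(base)), best]
    return out[0] if single else out


def min_image_distance(dr: np.ndarray, box: np.ndarray, pbc: np.ndarray) -> np.ndarray:
    d = min_image_displacement(dr, box, pbc)
    return np.linalg.norm(d, axis=-1)


def _is_orthorhombic(box: np.ndarray) -> bool:
    return bool(np.allclose(box, np.diag(np.diagonal(box))))


@dataclass
class AtomSystem:
    positions: np.ndarray            # (N, 3) Å
    species: np.ndarray              # (N,) str labels
    masses: np.ndarray               # (N,) amu
    charges: np.ndarray              # (N,) e
    box: np.ndarray                  # (3, 3) row cell vectors, Å
    pbc: np.ndarray = field(default_factory=lambda: np.array([True, True, True]))
    velocities: np.ndarray | None = None
    bonds: list[tuple[int, int]] = field(default_factory=list)
    groups: np.ndarray | None = None   # (N,) "HAP" | "WAT"
    ion_ids: np.ndarray | None = None  # (N,) int, −1 = not a hydroxyl-ion atom

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.species = np.asarray(self.species, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3, 3)
        self.pbc = np.asarray(self.pbc, dtype=bool).reshape(3)
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        if self.groups is None:
            self.groups = np.array([GROUP_HAP] * n, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.ion_ids is None:
            self.ion_ids = np.full(n, -1, dtype=int)
        self.ion_ids = np.asarray(self.ion_ids, dtype=int)
        self.bonds = [(int(i), int(j)) for i, j in self.bonds]
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_ions(self) -> int:
        """Number of tagged hydroxyl (OH) ions."""
        ids = self.ion_ids[self.ion_ids >= 0]
        return len(np.unique(ids))

    def validate(self) -> None:
        n = self.n_atoms
        for name in ("species", "masses", "charges", "groups", "ion_ids"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if self.velocities.shape != (n, 3):
            raise ValueError("velocities shape mismatch")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j})")
        # every tagged ion must be exactly one bonded O–H pair
        bond_set = {frozenset(b) for b in self.bonds}
        for ion in np.unique(self.ion_ids[self.ion_ids >= 0]):
            members = np.flatnonzero(self.ion_ids == ion)
            if len(members) != 2:
                raise ValueError(
                    f"OH-ion tag {ion} covers {len(members)} atoms, expected an O-H pair"
                )
            if frozenset(map(int, members)) not in bond_set:
                raise ValueError(f"OH-ion tag {ion} atoms are not bonded")
            elems = sorted(s.split("_")[0] for s in self.species[members])
            if elems != ["H", "O"]:
                raise ValueError(f"OH-ion tag {ion} is not an O-H pair: {elems}")

    def copy(self) -> "AtomSystem":
        return AtomSystem(
            positions=self.positions.copy(),
            species=self.species.copy(),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            box=self.box.copy(),
            pbc=self.pbc.copy(),
            velocities=self.velocities.copy(),
            bonds=list(self.bonds),
            groups=self.groups.copy(),
            ion_ids=self.ion_ids.copy(),
        )

    def ion_atom_indices(self, ion: int) -> np.ndarray:
        idx = np.flatnonzero(self.ion_ids == ion)
        if len(idx) == 0:
            raise KeyError(f"no atoms tagged with ion id {ion}")
        return idx

    def displacement(self, ri: np.ndarray, rj: np.ndarray) -> np.ndarray:
        """Minimum-image displacement(s) rj − ri under this system's box."""
        return min_image_displacement(np.asarray(rj) - np.asarray(ri), self.box, self.pbc)

    def min_pair_distance(self, exclude_bonded: bool = True) -> float:
        """Smallest interatomic minimum-image distance (brute-force N²)."""
        n = self.n_atoms
        if n < 2:
            return np.inf
        bonded = {frozenset(b) for b in self.bonds} if exclude_bonded else set()
        best = np.inf
        for i in range(n - 1):
            d = min_image_distance(
                self.positions[i + 1:] - self.positions[i], self.box, self.pbc
            )
            for k, dist in enumerate(d):
                if frozenset((i, i + 1 + k)) in bonded:
                    continue
                best = min(best, float(dist))
        return best


def merge(a: AtomSystem, b: AtomSystem) -> AtomSystem:
    """Concatenate two systems sharing a's box; b's ion ids are re-offset."""
    off = a.n_ions
    b_ions = b.ion_ids.copy()
    b_ions[b_ions >= 0] += off
    na = a.n_atoms
    return AtomSystem(
        positions=np.vstack([a.positions, b.positions]),
        species=np.concatenate([a.species, b.species]),
        masses=np.concatenate([a.masses, b.masses]),
        charges=np.concatenate([a.charges, b.charges]),
        box=a.box.copy(),
        pbc=a.pbc.copy(),
        velocities=np.vstack([a.velocities, b.velocities]),
        bonds=list(a.bonds) + [(i + na, j + na) for i, j in b.bonds],
        groups=np.concatenate([a.groups, b.groups]),
        ion_ids=np.concatenate([a.ion_ids, b_ions]),
    )
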