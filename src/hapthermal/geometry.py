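"""Hydroxyapatite cell construction: unit cell, supercell replication,
water solvation shells and vacuum headspace.

Hydroxyapatite, Ca₁₀(PO₄)₆(OH)₂, crystallises in the hexagonal ordered
phase P6₃ with a 44-atom unit cell (a = b = 9.417 Å, c = 6.875 Å,
γ = 120°) containing two channel hydroxyl ions stacked along c.  The
default 44-site basis ships as a YAML data file
(``data/hap_p63_basis.yaml``) derived from standard apatite
crystallography; it is configuration, not a hard-coded truth — tests
assert counts and stoichiometry, not specific coordinates.

The hexagonal cell is handled as a general triclinic box (3×3 row-vector
matrix); all coordinates are Cartesian Å with 0-based atom indices.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import mass_of
from .system import GROUP_HAP, GROUP_WATER, AtomSystem, merge

__all__ = [
    "UnitCellSpec",
    "SolvationSpec",
    "default_unit_cell_spec",
    "build_unit_cell",
    "replicate",
    "solvate",
    "expand_box",
    "OVERLAP_TOLERANCE",
]

#: Minimum allowed non-bonded interatomic distance at construction, Å.
#: Below the shortest covalent bond treated here (O–H ≈ 0.96 Å is a
#: bonded exception).
OVERLAP_TOLERANCE = 1.2

#: Water density used by n_waters="auto", g/cm³.
WATER_DENSITY = 0.997

_WATER_OH = 0.9572     # rigid 3-site O–H length, Å
_WATER_HOH = 104.52    # H–O–H angle, degrees
_WATER_MASS_G = (2 * 1.008 + 15.999) / 6.02214076e23  # grams per molecule


@dataclass
class UnitCellSpec:
    """Declarative description of one hexagonal HAP unit cell."""

    a: float = 9.417
    b: float = 9.417
    c: float = 6.875
    gamma: float = 120.0
    #: list of (species, (fx, fy, fz), charge)
    basis: list[tuple[str, tuple[float, float, float], float]] = field(default_factory=list)
    oh_orientation: str = "ordered"   # "ordered" | "disordered"

    def validate(self) -> None:
        if len(self.basis) != 44:
            raise ValueError(
                f"invariant violated: basis must hold 44 atoms, got {len(self.basis)}"
            )
        o_h = [b for b in self.basis if b[0] == "O_H"]
        h_o = [b for b in self.basis if b[0] == "H_O"]
        if len(o_h) != 2 or len(h_o) != 2:
            raise ValueError(
                "invariant violated: basis must contain exactly 2 hydroxyl O-H "
                f"pairs (found {len(o_h)} O_H, {len(h_o)} H_O)"
            )
        for sp, frac, _q in self.basis:
            if not all(0.0 <= f < 1.0 for f in frac):
                raise ValueError(
                    f"invariant violated: fractional coordinate of {sp} outside [0,1): {frac}"
                )
        if self.oh_orientation not in ("ordered", "disordered"):
            raise ValueError(f"unknown oh_orientation {self.oh_orientation!r}")

    def cell_vectors(self) -> np.ndarray:
        g = np.deg2rad(self.gamma)
        return np.array([
            [self.a, 0.0, 0.0],
            [self.b * np.cos(g), self.b * np.sin(g), 0.0],
            [0.0, 0.0, self.c],
        ])


def default_unit_cell_spec(oh_orientation: str = "ordered") -> UnitCellSpec:
    """Load the shipped P6₃ HAP basis."""
    ref = importlib.resources.files("hapthermal.data") / "hap_p63_basis.yaml"
    doc = yaml.safe_load(ref.read_text())
    basis = [(s["species"], tuple(s["frac"]), float(s["charge"])) for s in doc["basis"]]
    return UnitCellSpec(
        a=doc["a"], b=doc["b"], c=doc["c"], gamma=doc["gamma"],
        basis=basis, oh_orientation=oh_orientation,
    )


def build_unit_cell(spec: UnitCellSpec | None = None) -> AtomSystem:
    """Build one 44-atom hexagonal HAP unit cell with tagged OH ions.

    With ``oh_orientation="ordered"`` both hydroxyl O→H vectors are
    parallel to c (the polar P6₃ arrangement); ``"disordered"`` flips
    every second hydroxyl, mimicking the P6₃/m statistical phase.
    """
    if spec is None:
        spec = default_unit_cell_spec()
    spec.validate()
    box = spec.cell_vectors()

    species = [b[0] for b in spec.basis]
    frac = np.array([b[1] for b in spec.basis], dtype=float)
    charges = np.array([b[2] for b in spec.basis], dtype=float)

    # pair each hydroxyl O with its nearest hydroxyl H (fractional c-distance)
    o_idx = [i for i, s in enumerate(species) if s == "O_H"]
    h_idx = [i for i, s in enumerate(species) if s == "H_O"]
    pairs: list[tuple[int, int]] = []
    remaining = list(h_idx)
    for oi in o_idx:
        dz = [abs(((frac[hi, 2] - frac[oi, 2]) + 0.5) % 1.0 - 0.5) for hi in remaining]
        hi = remaining.pop(int(np.argmin(dz)))
        pairs.append((oi, hi))

    if spec.oh_orientation == "disordered":
        # flip the orientation of every second hydroxyl: mirror H through O
        for k, (oi, hi) in enumerate(pairs):
            if k % 2 == 1:
                dz = ((frac[hi, 2] - frac[oi, 2]) + 0.5) % 1.0 - 0.5
                frac[hi, 2] = (frac[oi, 2] - dz) % 1.0

    pos = frac @ box
    masses = np.array([mass_of(s) for s in species])
    ion_ids = np.full(44, -1, dtype=int)
    bonds = []
    for ion, (oi, hi) in enumerate(pairs):
        ion_ids[oi] = ion_ids[hi] = ion
        bonds.append((oi, hi))

    system = AtomSystem(
        positions=pos, species=np.array(species, dtype=object), masses=masses,
        charges=charges, box=box, bonds=bonds,
        groups=np.array([GROUP_HAP] * 44, dtype=object), ion_ids=ion_ids,
    )
    mind = system.min_pair_distance()
    if mind < OVERLAP_TOLERANCE:
        raise ValueError(
            f"invariant violated: atoms closer than overlap tolerance "
            f"({mind:.3f} Å < {OVERLAP_TOLERANCE} Å)"
        )
    return system


def replicate(cell: AtomSystem, nx: int, ny: int, nz: int) -> AtomSystem:
    """Tile a cell into an nx×ny×nz supercell.

    Atom count scales as N·nx·ny·nz and every copy's hydroxyl ions get
    fresh ion ids, so a 4×4×2 supercell of the default cell has 1408
    atoms and 64 tagged OH ions.
    """
    if min(nx, ny, nz) < 1:
        raise ValueError(f"replication factors must be >= 1, got ({nx}, {ny}, {nz})")
    n = cell.n_atoms
    n_ion = cell.n_ions
    reps = [(i, j, k) for i in range(nx) for j in range(ny) for k in range(nz)]
    shifts = np.array(reps, dtype=float) @ cell.box

    positions = (cell.positions[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    tile = len(reps)
    ion_ids = np.tile(cell.ion_ids, tile)
    offsets = np.repeat(np.arange(tile) * n_ion, n)
    ion_ids = np.where(ion_ids >= 0, ion_ids + offsets, -1)
    bonds = [(i + r * n, j + r * n) for r in range(tile) for i, j in cell.bonds]

    box = cell.box * np.array([[nx], [ny], [nz]], dtype=float)
    return AtomSystem(
        positions=positions,
        species=np.tile(cell.species, tile),
        masses=np.tile(cell.masses, tile),
        charges=np.tile(cell.charges, tile),
        box=box, pbc=cell.pbc.copy(),
        velocities=np.tile(cell.velocities, (tile, 1)),
        bonds=bonds,
        groups=np.tile(cell.groups, tile),
        ion_ids=ion_ids,
    )


@dataclass
class SolvationSpec:
    """Water shell parameters: rigid 3-site molecules in a shell of
    ``shell_thickness`` Å around the solute bounding surface."""

    shell_thickness: float = 15.0
    n_waters: int | str = "auto"
    o_charge: float = -0.834
    h_charge: float = 0.417

    def resolve_count(self, solute_extent: np.ndarray) -> int:
        if self.n_waters != "auto":
            return int(self.n_waters)
        lo, hi = solute_extent
        inner = np.prod(hi - lo)
        outer = np.prod(hi - lo + 2 * self.shell_thickness)
        vol_cm3 = (outer - inner) * 1e-24
        return int(round(vol_cm3 * WATER_DENSITY / _WATER_MASS_G))


def _water_template() -> np.ndarray:
    """O at origin, two H in the xz plane."""
    half = np.deg2rad(_WATER_HOH / 2)
    return np.array([
        [0.0, 0.0, 0.0],
        [_WATER_OH * np.sin(half), 0.0, _WATER_OH * np.cos(half)],
        [-_WATER_OH * np.sin(half), 0.0, _WATER_OH * np.cos(half)],
    ])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def solvate(system: AtomSystem, spec: SolvationSpec, seed: int,
            max_tries_per_water: int = 200, min_distance: float = 2.4) -> AtomSystem:
    """Surround a solute with rigid 3-site waters placed by rejection
    sampling in the shell; deterministic for a fixed seed.

    ``min_distance`` is the closest allowed O–heavy-atom approach during
    packing (a packing criterion, looser than the hard overlap
    tolerance).  Raises a placement error reporting the achieved count
    if the requested number cannot be placed.
    """
    lo = system.positions.min(axis=0)
    hi = system.positions.max(axis=0)
    n_req = spec.resolve_count(np.array([lo, hi]))
    if n_req == 0:
        return system.copy()

    rng = np.random.default_rng(seed)
    template = _water_template()
    t = spec.shell_thickness

    placed_o: list[np.ndarray] = []
    coords: list[np.ndarray] = []
    # coarse occupancy grid over solute atoms for overlap checks
    solute_pos = system.positions
    for _ in range(n_req):
        ok = False
        for _try in range(max_tries_per_water):
            p = rng.uniform(lo - t, hi + t)
            # must lie in the shell, not inside the solute bounding core
            if np.all(p > lo) and np.all(p < hi):
                continue
            d = np.linalg.norm(solute_pos - p, axis=1)
            if d.min() < min_distance:
                continue
            if placed_o:
                dw = np.linalg.norm(np.array(placed_o) - p, axis=1)
                if dw.min() < min_distance:
                    continue
            rot = _random_rotation(rng)
            coords.append(template @ rot.T + p)
            placed_o.append(p)
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place requested waters without overlap: "
                f"achieved {len(placed_o)} of {n_req}"
            )

    n_w = len(coords)
    wpos = np.vstack(coords)
    water = AtomSystem(
        positions=wpos,
        species=np.array(["O_W", "H_W", "H_W"] * n_w, dtype=object),
        masses=np.array([mass_of("O"), mass_of("H"), mass_of("H")] * n_w),
        charges=np.array([spec.o_charge, spec.h_charge, spec.h_charge] * n_w),
        box=system.box.copy(), pbc=system.pbc.copy(),
        bonds=[(3 * i, 3 * i + 1) for i in range(n_w)]
              + [(3 * i, 3 * i + 2) for i in range(n_w)],
        groups=np.array([GROUP_WATER] * (3 * n_w), dtype=object),
    )
    return merge(system, water)


def expand_box(system: AtomSystem, margin: float | np.ndarray) -> AtomSystem:
    """Add vacuum headspace: lengthen each cell vector by ``margin`` Å
    (scalar or per-axis) without touching coordinates.

    Applying a margin of m₁ then m₂ equals one margin of m₁+m₂.
    """
    margin = np.asarray(margin, dtype=float) * np.ones(3)
    if np.any(margin < 0):
        raise ValueError(f"margin must be non-negative, got {margin}")
    out = system.copy()
    lengths = np.linalg.norm(system.box, axis=1)
    scale = (lengths + margin) / lengths
    out.box = system.box * scale[:, None]
    return out
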