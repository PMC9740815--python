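"""Config-driven molecular-mechanics energies and forces.

Implements the interaction model the simulations use: point-charge
Coulomb electrostatics plus 12-6 and 9-6 Lennard-Jones pair potentials,
with harmonic bond and angle terms, evaluated under the minimum-image
convention with a plain shifted cutoff.

Parameter values live in a YAML config (see :func:`ForceField.from_yaml`);
the shipped default set is generic and charge-balanced — it is a
configuration artefact, not a fitted force field, and nothing
quantitative downstream depends on its specific numbers.

Conventions
-----------
* 12-6 form:  U(r) = 4ε[(σ/r)¹² − (σ/r)⁶], minimum −ε at r = 2^(1/6)σ.
* 9-6 form:   U(r) = ε[2(r₀/r)⁹ − 3(r₀/r)⁶], minimum −ε at r = r₀
  (the class-II convention; ``sigma`` stores r₀).
* Coulomb:    U(r) = k_C q₁q₂ / r, k_C = 332.0637 kcal·Å/(mol·e²).
* Bonds:      U = k (r − r₀)², angles U = k (θ − θ₀)² (θ in radians).
* Nonbonded pairs separated by one (1-2) or two (1-3) bonds are excluded.
* Both LJ and Coulomb are shifted so U(cutoff) = 0 (energies continuous;
  a documented deviation from Ewald-based production MD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import COULOMB_K
from .system import AtomSystem, min_image_displacement

__all__ = [
    "PairParams",
    "BondParams",
    "AngleParams",
    "ForceField",
    "EnergyBreakdown",
    "lj_energy",
    "coulomb_energy",
    "total_energy",
    "forces",
]

FORM_LJ126 = "lj12-6"
FORM_LJ96 = "lj9-6"


@dataclass(frozen=True)
class PairParams:
    form: str          # "lj12-6" | "lj9-6"
    epsilon: float     # kcal/mol
    sigma: float       # Å (r0 for the 9-6 form)

    def __post_init__(self):
        if self.form not in (FORM_LJ126, FORM_LJ96):
            raise ValueError(f"unknown LJ form {self.form!r}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class BondParams:
    k: float    # kcal/(mol·Å²)
    r0: float   # Å


@dataclass(frozen=True)
class AngleParams:
    k: float        # kcal/(mol·rad²)
    theta0: float   # degrees


def lj_energy(r: float | np.ndarray, p: PairParams) -> float | np.ndarray:
    """Lennard-Jones pair energy at separation r (Å), kcal/mol."""
    if np.any(np.asarray(r) <= 0):
        raise ValueError("separation must be positive")
    if p.form == FORM_LJ126:
        x6 = (p.sigma / r) ** 6
        return 4.0 * p.epsilon * (x6 * x6 - x6)
    x3 = (p.sigma / r) ** 3
    return p.epsilon * (2.0 * x3 ** 3 - 3.0 * x3 ** 2)


def _lj_dEdr(r: np.ndarray, p: PairParams) -> np.ndarray:
    if p.form == FORM_LJ126:
        x6 = (p.sigma / r) ** 6
        return -(24.0 * p.epsilon / r) * (2.0 * x6 * x6 - x6)
    x3 = (p.sigma / r) ** 3
    return -(18.0 * p.epsilon / r) * (x3 ** 3 - x3 ** 2)


def coulomb_energy(q1: float, q2: float, r: float | np.ndarray,
                   k: float = COULOMB_K) -> float | np.ndarray:
    """Point-charge Coulomb energy, kcal/mol (charges in e, r in Å)."""
    if np.any(np.asarray(r) <= 0):
        raise ValueError("separation must be positive")
    return k * q1 * q2 / r


@dataclass
class EnergyBreakdown:
    coulomb: float = 0.0
    lj: float = 0.0
    bond: float = 0.0
    angle: float = 0.0

    @property
    def total(self) -> float:
        return self.coulomb + self.lj + self.bond + self.angle


def _key(*species: str) -> tuple:
    return tuple(sorted(str(s) for s in species))


@dataclass
class ForceField:
    pairs: dict = field(default_factory=dict)    # _key(s1,s2) -> PairParams
    bonds: dict = field(default_factory=dict)    # _key(s1,s2) -> BondParams
    angles: dict = field(default_factory=dict)   # (end,center,end) -> AngleParams
    charges: dict = field(default_factory=dict)  # species -> e (optional map)
    coulomb_k: float = COULOMB_K
    cutoff: float = 10.0
    shift: bool = True

    # -- parameter resolution -----------------------------------------
    def pair_params(self, s1: str, s2: str) -> PairParams:
        """Resolve a species pair, falling back to Lorentz–Berthelot
        mixing of the self pairs; explicit entries override mixing."""
        k = _key(s1, s2)
        if k in self.pairs:
            return self.pairs[k]
        p1 = self.pairs.get(_key(s1, s1))
        p2 = self.pairs.get(_key(s2, s2))
        if p1 is None or p2 is None:
            raise KeyError(f"no pair parameters resolvable for species pair ({s1}, {s2})")
        if p1.form != p2.form:
            raise KeyError(
                f"cannot mix LJ forms {p1.form}/{p2.form} for ({s1}, {s2}); "
                "provide an explicit pair entry"
            )
        mixed = PairParams(p1.form, float(np.sqrt(p1.epsilon * p2.epsilon)),
                           0.5 * (p1.sigma + p2.sigma))
        self.pairs[k] = mixed
        return mixed

    def bond_params(self, s1: str, s2: str) -> BondParams | None:
        return self.bonds.get(_key(s1, s2))

    def angle_params(self, s_end1: str, s_center: str, s_end2: str) -> AngleParams | None:
        e1, e2 = sorted((s_end1, s_end2))
        return self.angles.get((e1, s_center, e2))

    # -- serialisation -------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "ForceField":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "ForceField":
        ff = cls(
            coulomb_k=float(doc.get("coulomb_k", COULOMB_K)),
            cutoff=float(doc.get("cutoff", 10.0)),
            shift=bool(doc.get("shift", True)),
            charges={k: float(v) for k, v in doc.get("charges", {}).items()},
        )
        for e in doc.get("pairs", []):
            s1, s2 = e["species"]
            ff.pairs[_key(s1, s2)] = PairParams(
                e.get("form", FORM_LJ126), float(e["epsilon"]), float(e["sigma"]))
        for e in doc.get("bonds", []):
            s1, s2 = e["species"]
            ff.bonds[_key(s1, s2)] = BondParams(float(e["k"]), float(e["r0"]))
        for e in doc.get("angles", []):
            s1, sc, s2 = e["species"]
            e1, e2 = sorted((s1, s2))
            ff.angles[(e1, sc, e2)] = AngleParams(float(e["k"]), float(e["theta0"]))
        return ff

    def to_dict(self) -> dict:
        return {
            "coulomb_k": self.coulomb_k,
            "cutoff": self.cutoff,
            "shift": self.shift,
            "charges": dict(self.charges),
            "pairs": [{"species": list(k), "form": p.form,
                       "epsilon": p.epsilon, "sigma": p.sigma}
                      for k, p in self.pairs.items()],
            "bonds": [{"species": list(k), "k": b.k, "r0": b.r0}
                      for k, b in self.bonds.items()],
            "angles": [{"species": [k[0], k[1], k[2]], "k": a.k, "theta0": a.theta0}
                       for k, a in self.angles.items()],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------

def _exclusions(system: AtomSystem) -> dict[int, np.ndarray]:
    """Nonbonded exclusions as i -> sorted array of excluded j>i:
    bonded (1-2) and next-neighbour (1-3) pairs."""
    pairs = {frozenset(b) for b in system.bonds}
    adj: dict[int, list[int]] = {}
    for i, j in system.bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    for c, nbrs in adj.items():
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                pairs.add(frozenset((nbrs[a], nbrs[b])))
    by_i: dict[int, list[int]] = {}
    for p in pairs:
        i, j = sorted(p)
        by_i.setdefault(i, []).append(j)
    return {i: np.array(sorted(v)) for i, v in by_i.items()}


def _angle_triples(system: AtomSystem) -> list[tuple[int, int, int]]:
    adj: dict[int, list[int]] = {}
    for i, j in system.bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    triples = []
    for c, nbrs in sorted(adj.items()):
        nbrs = sorted(nbrs)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                triples.append((nbrs[a], c, nbrs[b]))
    return triples


def _species_tables(system: AtomSystem, ff: ForceField):
    """Per-species-pair parameter matrices for vectorised evaluation."""
    uniq, sidx = np.unique(system.species.astype(str), return_inverse=True)
    ns = len(uniq)
    eps = np.zeros((ns, ns))
    sig = np.ones((ns, ns))
    form96 = np.zeros((ns, ns), dtype=bool)
    for a in range(ns):
        for b in range(a, ns):
            p = ff.pair_params(uniq[a], uniq[b])
            eps[a, b] = eps[b, a] = p.epsilon
            sig[a, b] = sig[b, a] = p.sigma
            form96[a, b] = form96[b, a] = p.form == FORM_LJ96
    return sidx, eps, sig, form96


def _pair_energy_arrays(r, eps, sig, form96, shift_lj, qq, coulomb_k, cutoff, shift):
    """Vectorised pair energies and dE/dr for mixed-form arrays."""
    x = sig / r
    x6 = x ** 6
    e12 = 4.0 * eps * (x6 * x6 - x6)
    d12 = -(24.0 * eps / r) * (2.0 * x6 * x6 - x6)
    x3 = x ** 3
    e96 = eps * (2.0 * x3 ** 3 - 3.0 * x3 ** 2)
    d96 = -(18.0 * eps / r) * (x3 ** 3 - x3 ** 2)
    e_lj = np.where(form96, e96, e12)
    d_lj = np.where(form96, d96, d12)
    e_c = coulomb_k * qq / r
    d_c = -e_c / r
    if shift:
        e_lj = e_lj - shift_lj
        e_c = e_c - coulomb_k * qq / cutoff
    inside = r < cutoff
    return (np.where(inside, e_lj, 0.0), np.where(inside, e_c, 0.0),
            np.where(inside, d_lj + d_c, 0.0))


def _shift_table(eps, sig, form96, cutoff):
    x = sig / cutoff
    x6 = x ** 6
    e12 = 4.0 * eps * (x6 * x6 - x6)
    x3 = x ** 3
    e96 = eps * (2.0 * x3 ** 3 - 3.0 * x3 ** 2)
    return np.where(form96, e96, e12)




class Evaluator:
    """Vectorised energy/force engine bound to one system topology.

    Species tables, exclusion masks and bonded parameter lists are
    resolved once at construction; subsequent calls only need new
    positions, which makes repeated evaluation (MD steps, rigid scans)
    cheap.  Pair interactions are computed over full N×N blocks with
    the minimum-image convention applied axis-wise for orthorhombic
    cells and via fractional wrapping plus a 27-image refinement for
    triclinic ones.
    """

    def __init__(self, system: AtomSystem, ff: ForceField, block: int = 512):
        self.ff = ff
        self.n = system.n_atoms
        if self.n == 0:
            raise ValueError("empty system")
        self.block = block
        self.species = system.species.astype(str)
        self.charges = system.charges.copy()
        self.pbc = system.pbc.copy()
        self.set_box(system.box)

        sidx, eps_t, sig_t, form_t = _species_tables(system, ff)
        self.sidx = sidx
        self.eps_t, self.sig_t, self.form_t = eps_t, sig_t, form_t
        self.shift_t = _shift_table(eps_t, sig_t, form_t, ff.cutoff)

        self.excl_mask = np.zeros((self.n, self.n), dtype=bool)
        np.fill_diagonal(self.excl_mask, True)
        for i, js in _exclusions(system).items():
            self.excl_mask[i, js] = True
            self.excl_mask[js, i] = True

        self.bond_terms = []
        for i, j in system.bonds:
            bp = ff.bond_params(self.species[i], self.species[j])
            if bp is not None:
                self.bond_terms.append((i, j, bp.k, bp.r0))
        self.angle_terms = []
        if ff.angles:
            for ia, ic, ib in _angle_triples(system):
                ap = ff.angle_params(self.species[ia], self.species[ic],
                                     self.species[ib])
                if ap is not None:
                    self.angle_terms.append((ia, ic, ib, ap.k,
                                             np.deg2rad(ap.theta0)))

    def set_box(self, box: np.ndarray) -> None:
        self.box = np.asarray(box, dtype=float).reshape(3, 3)
        if self.pbc.any():
            half_min = 0.5 * min(np.linalg.norm(self.box[k])
                                 for k in range(3) if self.pbc[k])
            if self.ff.cutoff >= half_min + 1e-9:
                raise ValueError(
                    f"cutoff {self.ff.cutoff} Å must be below half the smallest "
                    f"periodic box length ({half_min:.3f} Å)")
        self._ortho = bool(np.allclose(self.box, np.diag(np.diagonal(self.box))))
        self._inv_box = np.linalg.inv(self.box)
        if not self._ortho:
            from .system import _neighbor_shifts
            self._shifts = _neighbor_shifts(self.pbc) @ self.box

    def _mic(self, dr: np.ndarray) -> np.ndarray:
        """Minimum-image displacement for an (..., 3) array."""
        if not self.pbc.any():
            return dr
        if self._ortho:
            L = np.diagonal(self.box)
            for k in range(3):
                if self.pbc[k]:
                    dr[..., k] -= L[k] * np.round(dr[..., k] / L[k])
            return dr
        frac = dr @ self._inv_box
        frac[..., self.pbc] -= np.round(frac[..., self.pbc])
        base = frac @ self.box
        cand = base[..., None, :] + self._shifts
        d2 = np.einsum("...ks,...ks->...k", cand, cand)
        best = np.argmin(d2, axis=-1)
        return np.take_along_axis(cand, best[..., None, None], axis=-2)[..., 0, :]

    def __call__(self, positions: np.ndarray,
                 want_forces: bool = True) -> tuple[EnergyBreakdown, np.ndarray]:
        n, ff = self.n, self.ff
        pos = np.asarray(positions, dtype=float)
        q = self.charges
        breakdown = EnergyBreakdown()
        f = np.zeros((n, 3))

        for lo in range(0, n, self.block):
            hi = min(lo + self.block, n)
            dr = self._mic(pos[None, :, :] - pos[lo:hi, None, :])
            r = np.linalg.norm(dr, axis=-1)
            mask = self.excl_mask[lo:hi]
            if np.any((r <= 1e-12) & ~mask):
                bi, bj = np.argwhere((r <= 1e-12) & ~mask)[0]
                raise ValueError(f"coincident atoms {lo + bi} and {bj}")
            r = np.where(mask, np.inf, r)
            a = self.sidx[lo:hi, None]
            b = self.sidx[None, :]
            e_lj, e_c, dEdr = _pair_energy_arrays(
                r, self.eps_t[a, b], self.sig_t[a, b], self.form_t[a, b],
                self.shift_t[a, b], q[lo:hi, None] * q[None, :],
                ff.coulomb_k, ff.cutoff, ff.shift)
            breakdown.lj += 0.5 * float(e_lj.sum())       # ordered pairs counted twice
            breakdown.coulomb += 0.5 * float(e_c.sum())
            if want_forces:
                w = np.where(np.isfinite(r), dEdr / r, 0.0)
                f[lo:hi] += np.einsum("ij,ijk->ik", w, dr)

        for i, j, k, r0 in self.bond_terms:
            dv = self._mic((pos[j] - pos[i]).copy())
            r = float(np.linalg.norm(dv))
            breakdown.bond += k * (r - r0) ** 2
            if want_forces:
                fij = -(2.0 * k * (r - r0) / r) * dv
                f[j] += fij
                f[i] -= fij

        for ia, ic, ib, k, th0 in self.angle_terms:
            u = self._mic((pos[ia] - pos[ic]).copy())
            v = self._mic((pos[ib] - pos[ic]).copy())
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            cth = float(np.clip(u @ v / (nu * nv), -1.0, 1.0))
            th = np.arccos(cth)
            breakdown.angle += k * (th - th0) ** 2
            if want_forces:
                sth = np.sqrt(max(1.0 - cth * cth, 1e-12))
                dEdth = 2.0 * k * (th - th0)
                fa = dEdth * (v / (nu * nv) - cth * u / nu ** 2) / sth
                fb = dEdth * (u / (nu * nv) - cth * v / nv ** 2) / sth
                f[ia] += fa
                f[ib] += fb
                f[ic] -= fa + fb
        return breakdown, f


def total_energy(system: AtomSystem, ff: ForceField) -> EnergyBreakdown:
    """Potential-energy breakdown (kcal/mol) under minimum image + cutoff."""
    breakdown, _ = Evaluator(system, ff)(system.positions, want_forces=False)
    return breakdown


def forces(system: AtomSystem, ff: ForceField) -> np.ndarray:
    """Analytic per-atom forces, kcal/(mol·Å)."""
    _, f = Evaluator(system, ff)(system.positions)
    return f
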