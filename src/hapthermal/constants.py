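"""Physical constants and unit conversions.

Internal unit system: length Å, time ps, mass amu, energy kcal/mol,
charge e, temperature K.  In these units 1 kcal/mol = 418.4 amu·Å²/ps²
(exactly, given 1 cal = 4.184 J and 1 amu·Å²/ps² = 10 J/mol).
"""

#: Boltzmann constant, eV/K.
KB_EV = 8.6173e-5

#: kcal/mol per eV.
KCAL_PER_EV = 1.0 / 0.0433641

#: eV per kcal/mol.
EV_PER_KCAL = 0.0433641

#: Boltzmann constant, kcal/(mol·K).
KB_KCAL = KB_EV * KCAL_PER_EV

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_K = 332.0637

#: kcal/mol expressed in amu·Å²/ps² (force/acceleration conversion).
KCAL_TO_INTERNAL = 418.4

#: amu·Å²/ps² expressed in kcal/mol.
INTERNAL_TO_KCAL = 1.0 / KCAL_TO_INTERNAL

#: Reduced Planck constant, J·s.
HBAR_SI = 1.0545718e-34

#: Boltzmann constant, J/K.
KB_SI = 1.380649e-23

#: Atomic masses, amu (element symbol -> mass).
ATOMIC_MASSES = {
    "H": 1.008,
    "O": 15.999,
    "P": 30.974,
    "Ca": 40.078,
    "Na": 22.990,
    "Cl": 35.453,
}


def mass_of(species: str, default: float | None = None) -> float:
    """Mass of a species label.

    Labels may carry role suffixes separated by ``_`` (``O_H`` is the
    hydroxyl oxygen, ``H_O`` the hydroxyl hydrogen); the element is the
    prefix before the first underscore.  ``default`` (if given) is
    returned for species missing from the table instead of raising.
    """
    element = species.split("_")[0]
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        if default is not None:
            return default
        raise KeyError(f"no atomic mass known for species {species!r}") from None
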