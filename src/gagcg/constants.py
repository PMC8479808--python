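"""Physical constants shared across the package (AMBER-style units)."""

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 0.0019872041

#: Coulomb prefactor in AMBER convention, kcal Å mol^-1 e^-2
COULOMB_KCAL = 332.0636

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 300.0

#: Debye length prefactor for aqueous solution near 298 K:
#: kappa^-1 [nm] = 0.304 / sqrt(I [mol/L]), i.e. 3.04 Å at 1 M.
DEBYE_PREFACTOR_A = 3.04


def debye_length(ionic_strength: float) -> float:
    """Debye screening length in Å for a 1:1 electrolyte in water.

    Uses the standard room-temperature rule kappa^-1[nm] = 0.304/sqrt(I);
    at physiological ionic strength (0.15 M) this gives ~7.85 Å.
    Returns ``inf`` for zero ionic strength (unscreened Coulomb limit).
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if ionic_strength == 0:
        return float("inf")
    return DEBYE_PREFACTOR_A / ionic_strength**0.5
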