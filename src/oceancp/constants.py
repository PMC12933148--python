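"""Physical constants and unit conversions used throughout the package.

All concentrations are mol m^-3, rates s^-1, volumes m^3 and depths
positive-down metres unless a function says otherwise.  Globally
integrated element fluxes are reported in Pg element per year using the
molar masses below; the conversion chain is
mol m^-3 s^-1 * m^3 -> mol s^-1 -> Pg y^-1.
"""

#: seconds in a Julian year (365.25 d)
SECONDS_PER_YEAR = 365.25 * 86400.0

#: molar mass of carbon, g mol^-1
MOLAR_MASS_C = 12.011

#: molar mass of phosphorus, g mol^-1
MOLAR_MASS_P = 30.974

#: one Sverdrup in m^3 s^-1
SVERDRUP = 1.0e6

#: mean Earth radius, m
EARTH_RADIUS = 6.371e6

#: grams per petagram
GRAMS_PER_PG = 1.0e15

MOLAR_MASS = {"C": MOLAR_MASS_C, "P": MOLAR_MASS_P}


def mol_per_s_to_pg_per_year(flux_mol_s: float, element: str) -> float:
    """Convert a molar flux (mol s^-1) to Pg element per year."""
    return flux_mol_s * MOLAR_MASS[element] * SECONDS_PER_YEAR / GRAMS_PER_PG


def pg_per_year_to_mol_per_s(flux_pg_y: float, element: str) -> float:
    """Convert Pg element per year to mol s^-1."""
    return flux_pg_y * GRAMS_PER_PG / (MOLAR_MASS[element] * SECONDS_PER_YEAR)
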