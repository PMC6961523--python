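"""Physical constants and unit conversions used throughout the package.

Unit conventions
----------------
* carbon stocks/fluxes: g C m^-2, g C m^-2 day^-1
* nutrient stocks/fluxes: mmol m^-2, mmol m^-2 day^-1
* dissolved concentrations: mmol m^-3
* diffusivities: m^2 s^-1 internally, converted to m^2 day^-1 only at the
  time-stepping boundary (``SECONDS_PER_DAY`` is the single conversion point)
* depths: metres, positive downward from the sediment-water interface
* time: days in the simulator; years inside :mod:`shelfbed.massbalance`
"""

#: g C per mol C — the single molar-mass constant for C unit conversion.
C_MOLAR_MASS = 12.011

#: seconds per day; the one place m^2/s -> m^2/day happens.
SECONDS_PER_DAY = 86400.0

#: model calendar: no leap days.
DAYS_PER_YEAR = 365

#: canonical marine organic-matter molar stoichiometry C:N:P = 106:16:1.
REDFIELD_C_TO_N = 106.0 / 16.0
REDFIELD_C_TO_P = 106.0
REDFIELD_N_TO_P = 16.0

#: mmol C per g C.
MMOL_C_PER_G = 1000.0 / C_MOLAR_MASS

#: M2 and S2 tidal constituent periods (hours).
M2_PERIOD_HOURS = 12.4206
S2_PERIOD_HOURS = 12.0

#: von Karman constant.
VON_KARMAN = 0.41


def g_c_to_mmol(g_c: float) -> float:
    """Convert a carbon mass (g C) to mmol C."""
    return g_c * MMOL_C_PER_G


def mmol_to_g_c(mmol_c: float) -> float:
    """Convert mmol C to g C."""
    return mmol_c / MMOL_C_PER_G
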