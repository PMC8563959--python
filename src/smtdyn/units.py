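"""Unit conversions used at reporting boundaries.

Internally all rates live in SI-like units (mol m^-3 yr^-1, fluxes in
mol m^-2 yr^-1, depths in meters). Literature values for volumetric AOM
rates are quoted in nmol cm^-3 d^-1; these helpers convert between the
two, using a 365.25-day year throughout.
"""

DAYS_PER_YEAR = 365.25

#: 1 mol m^-3 yr^-1 expressed in nmol cm^-3 d^-1 (= 1000 / 365.25)
MOL_M3_YR_PER_NMOL_CM3_D = DAYS_PER_YEAR / 1000.0


def mol_m3_yr_to_nmol_cm3_d(rate):
    """mol m^-3 yr^-1 -> nmol cm^-3 d^-1 (factor 2.7379...)."""
    return rate * (1000.0 / DAYS_PER_YEAR)


def nmol_cm3_d_to_mol_m3_yr(rate):
    """nmol cm^-3 d^-1 -> mol m^-3 yr^-1 (factor 0.36525)."""
    return rate * (DAYS_PER_YEAR / 1000.0)


def cm_to_m(depth_cm):
    return depth_cm / 100.0


def m_to_cm(depth_m):
    return depth_m * 100.0
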