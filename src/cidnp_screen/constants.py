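"""Physical constants used by the geminate-polarization formula.

Values come from CODATA via :mod:`scipy.constants` and are frozen here so
every part of the pipeline (and its tests) agrees on them bit-exactly.
"""

from dataclasses import dataclass

import scipy.constants as _const

#: Bohr magneton over the reduced Planck constant, rad s^-1 T^-1.
MU_B_OVER_HBAR: float = _const.physical_constants["Bohr magneton"][0] / _const.hbar

#: Conversion from MHz to angular frequency, rad s^-1 per MHz.
MHZ_TO_RAD_S: float = 2.0 * _const.pi * 1e6

#: Default scale for stored q_value columns: Q [rad^3 s^-3] / Q_SCALE keeps
#: the feature near unity for a_iso ~ 1 MHz, |dg| ~ 1e-3, B0 ~ 14 T.
Q_SCALE: float = 1e21


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the constants entering Q."""

    mu_B_over_hbar: float = MU_B_OVER_HBAR
    mhz_to_rad_s: float = MHZ_TO_RAD_S


CODATA = PhysicalConstants()
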