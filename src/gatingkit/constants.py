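"""Physical constants and the thermodynamic scale for voltage-gating analysis.

All voltage-dependent equilibria in this package are parameterized by the
thermal voltage RT/F, which sets how many millivolts correspond to one unit of
thermal energy per elementary charge.  At a typical room-temperature oocyte
recording (22 degC, 295.15 K) RT/F is about 25.4 mV.  Gating free energies are
reported in kcal/mol using the Faraday constant expressed as
23.061 kcal mol^-1 V^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Faraday constant, kcal mol^-1 V^-1 (used for zFVd free energies).
F_KCAL_PER_MOL_V = 23.061
#: Faraday constant, C mol^-1.
F_C_PER_MOL = 96485.33212
#: Gas constant, kcal mol^-1 K^-1.
R_KCAL_PER_MOL_K = 1.98720425864083e-3
#: Elementary charge, C.
E0_COULOMB = 1.602176634e-19


class InvalidParameterError(ValueError):
    """Raised when a physically meaningless parameter value is supplied."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Temperature and the fundamental constants used throughout.

    Parameters
    ----------
    temperature_K:
        Absolute temperature of the recording, in kelvin.  Defaults to
        295.15 K (22 degC), a typical room-temperature oocyte experiment.
    """

    temperature_K: float = 295.15
    F_kcal: float = F_KCAL_PER_MOL_V
    F_coulomb: float = F_C_PER_MOL
    R_kcal: float = R_KCAL_PER_MOL_K
    e0: float = E0_COULOMB

    def __post_init__(self) -> None:
        for name in ("temperature_K", "F_kcal", "F_coulomb", "R_kcal", "e0"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")

    @property
    def rt_f_mV(self) -> float:
        """Thermal voltage RT/F in millivolts (~25.4 mV at 295.15 K)."""
        return 1000.0 * self.R_kcal * self.temperature_K / self.F_kcal


DEFAULT_CONSTANTS = PhysicalConstants()
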