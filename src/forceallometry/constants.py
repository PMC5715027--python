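"""Physical constants and the International Standard Atmosphere model.

The troposphere density law is

    rho(h) = rho0 * (1 - L*h/T0) ** (g*M/(R*L) - 1)

valid for 0 <= h < 11 km. All constants are configurable through
:class:`Atmosphere` because field studies sometimes prefer site-calibrated
sea-level values.
"""

from __future__ import annotations

from dataclasses import dataclass

#: standard gravity, m s^-2; used for weight = mass * g everywhere
#: (elevation dependence of g is < 0.2% over the sampled range).
STANDARD_GRAVITY = 9.80665

#: ceiling of the ISA troposphere layer, metres.
TROPOSPHERE_TOP = 11000.0


@dataclass(frozen=True)
class Atmosphere:
    """International Standard Atmosphere constants (SI units)."""

    rho0: float = 1.225        # sea-level density, kg m^-3
    T0: float = 288.15         # sea-level temperature, K
    lapse_rate: float = 0.0065  # tropospheric lapse rate L, K m^-1
    g: float = STANDARD_GRAVITY
    molar_mass: float = 0.0289644   # dry air, kg mol^-1
    gas_constant: float = 8.31446   # J mol^-1 K^-1

    @property
    def exponent(self) -> float:
        """g*M/(R*L) - 1, the density exponent of the troposphere law."""
        return (self.g * self.molar_mass
                / (self.gas_constant * self.lapse_rate)) - 1.0


ISA = Atmosphere()
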