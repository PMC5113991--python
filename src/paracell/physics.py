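"""Physical constants and thermodynamic context for transepithelial electrophysiology."""

from __future__ import annotations

from dataclasses import dataclass

#: CODATA 2018 molar gas constant, J mol^-1 K^-1
GAS_CONSTANT = 8.31446261815324
#: CODATA 2018 Faraday constant, C mol^-1
FARADAY = 96485.33212


@dataclass(frozen=True)
class PhysicalContext:
    """Temperature and constants entering the constant-field (GHK) relations.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Default 310.15 K (37 degC, the
        incubation temperature of the measurements).
    gas_constant, faraday : float
        R and F; overridable only for cross-checking against sources that
        used rounded constants.
    """

    temperature: float = 310.15
    gas_constant: float = GAS_CONSTANT
    faraday: float = FARADAY

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature} K")

    @property
    def thermal_voltage(self) -> float:
        """RT/F in volts (~0.02672 V at 310.15 K)."""
        return self.gas_constant * self.temperature / self.faraday

    @property
    def rt_over_f2(self) -> float:
        """RT/F^2 in V mol C^-1; the factor converting conductance to permeability*concentration."""
        return self.gas_constant * self.temperature / self.faraday**2


#: Context at 37 degC with CODATA constants; used throughout unless overridden.
BODY_TEMP = PhysicalContext()
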