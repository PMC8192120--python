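"""Physical constants used throughout the kinetic calculations."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic constants for rate scaling and current conversion.

    Attributes
    ----------
    F : float
        Faraday constant, C·mol⁻¹.
    R : float
        Gas constant, J·K⁻¹·mol⁻¹.
    T : float
        Absolute temperature, K (room temperature by default).
    NA : float
        Avogadro constant, mol⁻¹.
    """

    F: float = 96485.0
    R: float = 8.314
    T: float = 293.0
    NA: float = 6.022e23

    @property
    def RT(self) -> float:
        """Thermal energy per mole, J·mol⁻¹."""
        return self.R * self.T

    @property
    def beta_half(self) -> float:
        """F/(2RT), the symmetric-barrier voltage scaling factor, V⁻¹."""
        return self.F / (2.0 * self.R * self.T)


DEFAULT_CONSTANTS = PhysicalConstants()
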