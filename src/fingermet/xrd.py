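"""Bragg d-spacing from a low-angle diffraction peak.

A single closed form: d = n·λ / (2·sin θ), with 2θ in degrees and λ in
nm (default Cu Kα, 0.15406 nm — the standard laboratory source for
low-angle XRD; a different instrument wavelength can be passed in).
A low-angle reflection near 2θ ≈ 0.5° corresponds to a mesoscale
periodicity of tens of nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

CU_K_ALPHA_NM = 0.15406


@dataclass(frozen=True)
class DiffractionPeak:
    two_theta: float  # degrees
    wavelength: float = CU_K_ALPHA_NM  # nm
    order: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.two_theta < 180:
            raise ValueError("two_theta must be in (0, 180) degrees")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def bragg_spacing(peak: DiffractionPeak | float, wavelength: float = CU_K_ALPHA_NM,
                  order: int = 1) -> float:
    """Lattice spacing d in nm for a diffraction peak at ``two_theta`` degrees."""
    if not isinstance(peak, DiffractionPeak):
        peak = DiffractionPeak(float(peak), wavelength, order)
    theta = math.radians(peak.two_theta / 2.0)
    return peak.order * peak.wavelength / (2.0 * math.sin(theta))
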