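"""Core-shell overlayer thickness from XPS attenuation.

For a thin shell attenuating the core photoelectron signal, the shell
thickness follows T = L_film · cos(θ) · ln(1 + R), with L_film the
electron attenuation length of the measured photoelectrons (1.02 nm for
Au-4f, 1.05 nm for Pt-4f), θ the take-off/scattering angle and R the
dimensionless overlayer parameter (set to the mean core diameter value,
3, in the Au-core/Pt-shell system analysed here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: electron attenuation lengths, nm
L_FILM_AU = 1.02
L_FILM_PT = 1.05


@dataclass(frozen=True)
class ShellParams:
    l_film: float = L_FILM_AU  # nm
    theta: float = 0.0  # degrees
    r_overlayer: float = 3.0  # dimensionless

    def __post_init__(self) -> None:
        if self.l_film <= 0:
            raise ValueError("l_film must be positive")
        if not 0.0 <= self.theta < 90.0:
            raise ValueError("theta must lie in [0, 90) degrees")
        if self.r_overlayer < 0:
            raise ValueError("r_overlayer must be non-negative")


def shell_thickness(params: ShellParams) -> float:
    """Shell thickness in nm: ``l_film · cos(θ) · ln(1 + R)``."""
    return params.l_film * math.cos(math.radians(params.theta)) * math.log1p(
        params.r_overlayer
    )
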