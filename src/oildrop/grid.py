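"""Spectral grids and trophic water classification.

Wavelengths are vacuum wavelengths in nanometres, restricted to the
visible window 400-700 nm used throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VIS_MIN = 400.0
VIS_MAX = 700.0

#: Bands named by the standard ocean-color ratio/difference/index analytics.
NAMED_BANDS: tuple[int, ...] = (
    410, 420, 440, 443, 445, 490, 550, 555, 560, 650, 665, 670, 675, 680,
)

#: Default 27-band visible grid: the 14 named analytic bands plus a
#: near-uniform fill of the 400-700 nm window.
DEFAULT_WAVELENGTHS: tuple[float, ...] = (
    400, 410, 420, 430, 440, 443, 445, 460, 475, 490, 505, 520, 535, 550,
    555, 560, 575, 590, 605, 620, 635, 650, 665, 670, 675, 680, 700,
)


@dataclass(frozen=True)
class SpectralGrid:
    """A strictly increasing set of visible wavelengths (nm)."""

    wavelengths: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_WAVELENGTHS, dtype=float)
    )

    def __post_init__(self) -> None:
        wl = np.atleast_1d(np.asarray(self.wavelengths, dtype=float))
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < VIS_MIN or wl[-1] > VIS_MAX:
            raise ValueError(
                f"wavelengths must lie within [{VIS_MIN:g}, {VIS_MAX:g}] nm"
            )
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size

    def __iter__(self):
        return iter(self.wavelengths)

    def index_of(self, wavelength: float, tol: float = 5.0) -> int:
        """Index of the grid band nearest ``wavelength`` within ``tol`` nm."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[i] - wavelength) > tol:
            raise KeyError(
                f"no band within {tol:g} nm of {wavelength:g} nm on this grid"
            )
        return i


# Trophic class thresholds in mg Chl-a / m^3.
OLIGOTROPHIC_MAX = 0.1
MESOTROPHIC_MAX = 1.67


@dataclass(frozen=True)
class TrophicScenario:
    """An open-ocean (Case-1) water column described by its Chl-a level.

    Parameters
    ----------
    chl:
        Chlorophyll-a concentration in mg/m^3, assumed vertically uniform.
    """

    chl: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.chl) or self.chl <= 0:
            raise ValueError("chl must be a positive, finite concentration")

    @property
    def trophic_class(self) -> str:
        if self.chl <= OLIGOTROPHIC_MAX:
            return "oligotrophic"
        if self.chl <= MESOTROPHIC_MAX:
            return "mesotrophic"
        return "eutrophic"
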