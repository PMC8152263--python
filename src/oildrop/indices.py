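"""Ocean-color analytics on R_rs spectra.

Band ratios and band differences feed the classic blue-to-green empirical
chlorophyll algorithms; the color index CI measures the signed distance of
the green-band R_rs from a linear baseline drawn between the blue and red
bands and is negative for most clear ocean waters. Relative differences
and fold changes quantify how dispersed-oil pollution perturbs each
metric against the unpolluted background.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mc import RrsResult

BAND_TOL_NM = 5.0


def _value_at(rrs: RrsResult, wavelength: float) -> float:
    i = rrs.grid.index_of(wavelength, tol=BAND_TOL_NM)
    return float(rrs.rrs[i])


def band_ratio(rrs: RrsResult, lam1: float, lam2: float) -> float:
    """R_rs(lam1) / R_rs(lam2) with nearest-band lookup (5 nm tolerance).

    Returns NaN (with a warning) when the denominator is non-positive.
    """
    num = _value_at(rrs, lam1)
    den = _value_at(rrs, lam2)
    if den <= 0:
        warnings.warn(
            f"band ratio {lam1:g}/{lam2:g} undefined: non-positive denominator",
            stacklevel=2,
        )
        return float("nan")
    return num / den


def band_difference(rrs: RrsResult, lam1: float, lam2: float) -> float:
    """R_rs(lam1) - R_rs(lam2) in sr^-1."""
    return _value_at(rrs, lam1) - _value_at(rrs, lam2)


def color_index(
    rrs: RrsResult, lam_blue: float, lam_green: float, lam_red: float
) -> float:
    """Color index in sr^-1.

    CI = R_rs(green) - [R_rs(blue)
         + (green - blue)/(red - blue) * (R_rs(red) - R_rs(blue))],
    i.e. the departure of the green band from the blue-red linear baseline.
    Vanishes identically for spectra affine in wavelength.
    """
    if not lam_blue < lam_green < lam_red:
        raise ValueError("bands must satisfy blue < green < red")
    rb = _value_at(rrs, lam_blue)
    rg = _value_at(rrs, lam_green)
    rr = _value_at(rrs, lam_red)
    frac = (lam_green - lam_blue) / (lam_red - lam_blue)
    return rg - (rb + frac * (rr - rb))


def relative_difference(polluted: float, natural: float) -> float:
    """Percentage change of a metric against the unpolluted background.

    100 * (polluted - natural) / |natural|; the absolute-value denominator
    keeps the sign of the change itself (a CI moving from -3.11e-3 to
    -5.95e-3 is a -91% change; to +0.67e-3, a +121% change).
    """
    if natural == 0:
        warnings.warn("relative difference undefined for a zero baseline",
                      stacklevel=2)
        return float("nan")
    return 100.0 * (polluted - natural) / abs(natural)


def fold_change(
    polluted: RrsResult, natural: RrsResult, band_range: tuple[float, float]
) -> float:
    """Mean of per-band polluted/natural R_rs ratios over a wavelength range."""
    if not np.array_equal(polluted.grid.wavelengths, natural.grid.wavelengths):
        raise ValueError("spectra must share one grid")
    wl = natural.grid.wavelengths
    lo, hi = band_range
    mask = (wl >= lo) & (wl <= hi)
    if not mask.any():
        raise ValueError(f"no grid bands inside [{lo:g}, {hi:g}] nm")
    return float(np.mean(polluted.rrs[mask] / natural.rrs[mask]))


#: Conventional visible sub-ranges for fold-change summaries (nm).
BLUE_RANGE = (400.0, 510.0)
GREEN_RANGE = (510.0, 590.0)
RED_RANGE = (590.0, 700.0)

#: Band pairs conventionally examined as ratios and differences.
RATIO_PAIRS = ((410, 560), (440, 550), (490, 550), (550, 680), (420, 665))
DIFFERENCE_PAIRS = ((550, 440), (665, 440), (680, 490))

#: Blue/green/red triplets used for the color index.
CI_TRIPLETS = (
    (440, 555, 670), (440, 555, 675), (440, 550, 670), (440, 550, 675),
    (445, 555, 670), (445, 555, 675), (445, 550, 670), (445, 550, 675),
)


@dataclass(frozen=True)
class BandMetrics:
    """All standard metrics evaluated on one R_rs spectrum."""

    ratios: dict = field(default_factory=dict)
    differences: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)

    @classmethod
    def from_rrs(cls, rrs: RrsResult, ratio_pairs=RATIO_PAIRS,
                 difference_pairs=DIFFERENCE_PAIRS,
                 ci_triplets=CI_TRIPLETS) -> "BandMetrics":
        ratios, diffs, cis = {}, {}, {}
        for l1, l2 in ratio_pairs:
            try:
                ratios[(l1, l2)] = band_ratio(rrs, l1, l2)
            except KeyError:
                pass
        for l1, l2 in difference_pairs:
            try:
                diffs[(l1, l2)] = band_difference(rrs, l1, l2)
            except KeyError:
                pass
        for lb, lg, lr in ci_triplets:
            try:
                cis[(lb, lg, lr)] = color_index(rrs, lb, lg, lr)
            except KeyError:
                pass
        return cls(ratios=ratios, differences=diffs, ci=cis)
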