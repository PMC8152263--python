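"""Case-1 bio-optical model: IOPs of open-ocean water from Chl-a.

Absorption is the sum of pure-water (Pope & Fry tabulation), phytoplankton
particle (power law in Chl-a with a tabulated spectral shape) and CDOM
(exponential tied to the particle absorption at 440 nm) components.
Scattering is pure seawater (power law in wavelength) plus particulate
scattering (Loisel/Morel power law in Chl-a with a Chl-dependent spectral
slope). The phase function is a scattering-weighted mixture of the
pure-seawater form and a Fournier-Forand particle phase function whose
backscatter fraction follows the Morel Case-1 particulate b_bp/b_p law.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .grid import SpectralGrid, TrophicScenario
from .phase import (
    PhaseFunction,
    default_angle_grid,
    ff_mu_for_backscatter,
    fournier_forand,
    mix,
    rayleigh_seawater,
)


@dataclass(frozen=True)
class WaterModelConfig:
    """Tunable constants of the Case-1 water model (all exposed)."""

    # pure seawater scattering power law b_w(l) = b0 * (l0 / l)^gamma
    bw_ref: float = 0.00193  # 1/m at the reference wavelength
    bw_ref_wavelength: float = 550.0  # nm
    bw_gamma: float = 4.32

    # CDOM: a_g(l) = f_c * a_p(l_ref) * exp(-S (l - l_ref))
    cdom_fraction: float = 0.2
    cdom_slope: float = 0.014  # 1/nm
    cdom_ref_wavelength: float = 440.0  # nm

    # particulate scattering b_p(l) = B * chl^p * (l / l0)^v(chl)
    bp_coeff: float = 0.416
    bp_exponent: float = 0.766
    bp_ref_wavelength: float = 550.0

    # particulate backscattering ratio b_bp/b_p(chl)
    bbp_offset: float = 0.002
    bbp_scale: float = 0.01
    ff_index: float = 1.08  # relative index of the Fournier-Forand shape


DEFAULT_CONFIG = WaterModelConfig()


def _load_table(name: str) -> np.ndarray:
    with resources.files("oildrop.data").joinpath(name).open("rb") as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


_POPE_FRY = _load_table("pope_fry_1997.csv")
_CHL_ABS = _load_table("chl_specific_absorption.csv")


def pure_water_absorption(grid: SpectralGrid) -> np.ndarray:
    """Clear natural water absorption (1/m), interpolated from the
    embedded Pope & Fry table (linear between 5-nm nodes)."""
    wl = grid.wavelengths
    tab_wl, tab_a = _POPE_FRY[:, 0], _POPE_FRY[:, 1]
    if wl[0] < tab_wl[0] or wl[-1] > tab_wl[-1]:
        raise ValueError(
            f"wavelengths outside the tabulated range "
            f"[{tab_wl[0]:g}, {tab_wl[-1]:g}] nm"
        )
    return np.interp(wl, tab_wl, tab_a)


def pure_water_scattering(
    grid: SpectralGrid, config: WaterModelConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Pure seawater scattering b_w(l) = b0 * (l0/l)^gamma (1/m)."""
    wl = grid.wavelengths
    return config.bw_ref * (config.bw_ref_wavelength / wl) ** config.bw_gamma


def _check_chl(chl: float) -> None:
    if not np.isfinite(chl) or chl < 0:
        raise ValueError("chl must be a finite non-negative concentration")


def particle_absorption(grid: SpectralGrid, chl: float) -> np.ndarray:
    """Phytoplankton particle absorption a_p(l) = A(l) * chl^E(l) (1/m)."""
    _check_chl(chl)
    wl = grid.wavelengths
    A = np.interp(wl, _CHL_ABS[:, 0], _CHL_ABS[:, 1])
    E = np.interp(wl, _CHL_ABS[:, 0], _CHL_ABS[:, 2])
    if chl == 0:
        return np.zeros_like(wl)
    return A * chl**E


def cdom_absorption(
    grid: SpectralGrid, chl: float, config: WaterModelConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """CDOM absorption, exponential and tied to a_p at the reference band."""
    _check_chl(chl)
    ref = SpectralGrid(np.array([config.cdom_ref_wavelength]))
    ap_ref = particle_absorption(ref, chl)[0]
    wl = grid.wavelengths
    return (
        config.cdom_fraction
        * ap_ref
        * np.exp(-config.cdom_slope * (wl - config.cdom_ref_wavelength))
    )


def bp_spectral_slope(chl: float) -> float:
    """Morel Chl-dependent spectral exponent v(chl) of particulate scattering.

    v = 0.5*(log10 chl - 0.3) clipped to [-1, 0]; v = 0 for chl >= 2.
    Negative v makes b_p increase toward the blue for clear waters.
    """
    if chl >= 2.0:
        return 0.0
    return float(np.clip(0.5 * (np.log10(chl) - 0.3), -1.0, 0.0))


def particle_scattering(
    grid: SpectralGrid, chl: float, config: WaterModelConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Particulate scattering b_p(l) = B * chl^p * (l/l0)^v(chl) (1/m)."""
    _check_chl(chl)
    wl = grid.wavelengths
    if chl == 0:
        return np.zeros_like(wl)
    v = bp_spectral_slope(chl)
    return (
        config.bp_coeff
        * chl**config.bp_exponent
        * (wl / config.bp_ref_wavelength) ** v
    )


def particulate_backscatter_ratio(
    chl: float, config: WaterModelConfig = DEFAULT_CONFIG
) -> float:
    """Case-1 particulate backscattering ratio b_bp/b_p as a function of Chl."""
    return config.bbp_offset + config.bbp_scale * (0.5 - 0.25 * np.log10(chl))


def water_phase_function(
    chl: float,
    wavelength: float,
    config: WaterModelConfig = DEFAULT_CONFIG,
    angles_deg: np.ndarray | None = None,
) -> PhaseFunction:
    """Bulk water phase function at one wavelength.

    Mixture of the pure-seawater shape (1 + 0.835 cos^2) and a
    Fournier-Forand particle shape, weighted by the scattering fractions
    b_w/b_tot and b_p/b_tot.
    """
    if not np.isfinite(chl) or chl <= 0:
        raise ValueError("chl must be positive for a bulk phase function")
    if angles_deg is None:
        angles_deg = default_angle_grid()
    g = SpectralGrid(np.array([float(wavelength)]))
    bw = pure_water_scattering(g, config)[0]
    bp = particle_scattering(g, chl, config)[0]
    p_sw = rayleigh_seawater(angles_deg)
    mu = ff_mu_for_backscatter(
        particulate_backscatter_ratio(chl, config), n=config.ff_index,
        angles_deg=angles_deg,
    )
    p_part = fournier_forand(angles_deg, n=config.ff_index, mu=mu)
    return mix([p_sw, p_part], np.array([bw, bp]))


@dataclass(frozen=True)
class WaterIOPs:
    """Assembled inherent optical properties of a Case-1 water body."""

    grid: SpectralGrid
    a_water: np.ndarray
    b_water: np.ndarray
    a_particle: np.ndarray
    a_cdom: np.ndarray
    b_particle: np.ndarray
    pf: list[PhaseFunction] = field(repr=False)
    chl: float = 0.0

    @property
    def a_tot(self) -> np.ndarray:
        return self.a_water + self.a_particle + self.a_cdom

    @property
    def b_tot(self) -> np.ndarray:
        return self.b_water + self.b_particle

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "wavelength_nm": self.grid.wavelengths,
                "a_water": self.a_water,
                "a_particle": self.a_particle,
                "a_cdom": self.a_cdom,
                "a_tot": self.a_tot,
                "b_water": self.b_water,
                "b_particle": self.b_particle,
                "b_tot": self.b_tot,
            }
        )


def build_water_iops(
    trophic: TrophicScenario,
    grid: SpectralGrid | None = None,
    config: WaterModelConfig = DEFAULT_CONFIG,
    angles_deg: np.ndarray | None = None,
) -> WaterIOPs:
    """Assemble all water IOP components for one trophic scenario."""
    if grid is None:
        grid = SpectralGrid()
    if angles_deg is None:
        angles_deg = default_angle_grid()
    chl = trophic.chl
    bw = pure_water_scattering(grid, config)
    bp = particle_scattering(grid, chl, config)

    p_sw = rayleigh_seawater(angles_deg)
    mu = ff_mu_for_backscatter(
        particulate_backscatter_ratio(chl, config), n=config.ff_index,
        angles_deg=angles_deg,
    )
    p_part = fournier_forand(angles_deg, n=config.ff_index, mu=mu)
    pfs = [
        mix([p_sw, p_part], np.array([bw[i], bp[i]])) for i in range(len(grid))
    ]
    return WaterIOPs(
        grid=grid,
        a_water=pure_water_absorption(grid),
        b_water=bw,
        a_particle=particle_absorption(grid, chl),
        a_cdom=cdom_absorption(grid, chl, config),
        b_particle=bp,
        pf=pfs,
        chl=chl,
    )
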