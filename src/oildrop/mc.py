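"""Monte Carlo radiative transfer in a wind-roughened, layered ocean.

Produces remote sensing reflectance at 0+ (water-leaving radiance over
downwelling irradiance just above the surface) for a sun-plus-diffuse-sky
illumination, a Cox-Munk rough surface, a two-layer water column (oil
dispersed in a surface mixed layer over clean water) and a weakly
reflecting Lambertian bottom deep enough not to matter.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernel import trace_wavelength
from .grid import SpectralGrid
from .mie import OilIOPs, seawater_refractive_index
from .phase import PhaseFunction
from .water import WaterIOPs

#: Cox-Munk total mean-square slope: sigma^2 = 0.003 + 0.00512 W (W in m/s).
COX_MUNK_INTERCEPT = 0.003
COX_MUNK_SLOPE = 0.00512

RR_THRESHOLD = 1e-4
RR_SURVIVAL = 0.1

_N_ICDF = 8192


def default_sky_diffuse_fraction(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Fraction of downwelling irradiance that is diffuse sky light.

    Smooth clear-sky spectral curve from 0.35 at 400 nm to 0.15 at 700 nm
    (molecular scattering makes the blue sky relatively more diffuse).
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    return 0.35 - 0.20 * (wl - 400.0) / 300.0


@dataclass(frozen=True)
class Scenario:
    """Boundary conditions of one simulated reflectance experiment."""

    sun_zenith: float = 30.0  # degrees from zenith
    wind_speed: float = 5.0  # m/s
    receiver_half_angle: float = 3.5  # degrees around nadir viewing
    ocean_depth: float = 1000.0  # m
    mixed_layer_depth: float = 30.0  # m, oil-bearing surface layer
    oil_ppm: float = 1.0  # volume concentration in the mixed layer
    bottom_mirror: float = 0.02  # specular bottom reflection probability
    bottom_diffuse: float = 0.08  # Lambertian bottom reflection probability
    sky_diffuse_fraction: object = None  # callable grid -> fractions, or None
    n_photons: int = 1_000_000  # per wavelength (desk-scale default)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bottom_mirror", "bottom_diffuse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.bottom_mirror + self.bottom_diffuse > 1.0:
            raise ValueError("bottom reflection probabilities exceed 1")
        if self.ocean_depth <= 0 or self.mixed_layer_depth <= 0:
            raise ValueError("depths must be positive")
        if self.mixed_layer_depth > self.ocean_depth:
            raise ValueError("mixed layer cannot be deeper than the ocean")
        if not 0.0 <= self.sun_zenith < 90.0:
            raise ValueError("sun zenith must lie in [0, 90) degrees")
        if self.wind_speed < 0:
            raise ValueError("wind speed must be >= 0")
        if self.n_photons <= 0:
            raise ValueError("photon budget must be positive")
        if self.oil_ppm < 0:
            raise ValueError("oil concentration must be >= 0")

    def slope_variance(self) -> float:
        return COX_MUNK_INTERCEPT + COX_MUNK_SLOPE * self.wind_speed


@dataclass(frozen=True)
class Layer:
    """One optically homogeneous slab with per-component scatterers."""

    z_top: float
    z_bot: float
    a: np.ndarray  # total absorption per wavelength (1/m)
    b_water: np.ndarray
    b_oil: np.ndarray
    pf_water: list[PhaseFunction] = field(repr=False)
    pf_oil: list[PhaseFunction] | None = field(repr=False, default=None)

    @property
    def b(self) -> np.ndarray:
        return self.b_water + self.b_oil


@dataclass(frozen=True)
class LayeredMedium:
    grid: SpectralGrid
    layers: list[Layer]

    def __post_init__(self) -> None:
        zs = 0.0
        for lay in self.layers:
            if lay.z_top != zs:
                raise ValueError("layers must be contiguous from the surface")
            if lay.z_bot <= lay.z_top:
                raise ValueError("layer bottom must lie below its top")
            zs = lay.z_bot


def mix_iops(
    water: WaterIOPs, oil: OilIOPs | None, scenario: Scenario
) -> LayeredMedium:
    """Combine water and (optional) oil IOPs into the layered column.

    Oil occupies the surface mixed layer only, rescaled linearly to
    ``scenario.oil_ppm``; below it the column is clean water.
    """
    grid = water.grid
    if oil is not None and not np.array_equal(
        grid.wavelengths, oil.grid.wavelengths
    ):
        raise ValueError("water and oil IOPs are on different spectral grids")

    nw = len(grid)
    if oil is None or scenario.oil_ppm == 0.0:
        layers = [
            Layer(
                z_top=0.0,
                z_bot=scenario.ocean_depth,
                a=water.a_tot,
                b_water=water.b_tot,
                b_oil=np.zeros(nw),
                pf_water=water.pf,
            )
        ]
        return LayeredMedium(grid=grid, layers=layers)

    oil = oil.scaled(scenario.oil_ppm)
    top = Layer(
        z_top=0.0,
        z_bot=scenario.mixed_layer_depth,
        a=water.a_tot + oil.a_oil,
        b_water=water.b_tot,
        b_oil=oil.b_oil,
        pf_water=water.pf,
        pf_oil=oil.pf,
    )
    deep = Layer(
        z_top=scenario.mixed_layer_depth,
        z_bot=scenario.ocean_depth,
        a=water.a_tot,
        b_water=water.b_tot,
        b_oil=np.zeros(nw),
        pf_water=water.pf,
    )
    return LayeredMedium(grid=grid, layers=[top, deep])


def fresnel_reflectance(incidence_angle_deg: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance at a dielectric interface.

    ``n_rel`` is the refractive index of the far side relative to the side
    the photon travels in; ``n_rel`` < 1 (upward photons in water) shows
    total internal reflection beyond the critical angle.
    """
    if not 0.0 <= incidence_angle_deg <= 90.0:
        raise ValueError("incidence angle must lie in [0, 90] degrees")
    if n_rel <= 0:
        raise ValueError("relative index must be positive")
    ci = math.cos(math.radians(incidence_angle_deg))
    si2 = 1.0 - ci * ci
    st2 = si2 / n_rel**2
    if st2 >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - st2)
    rs = (ci - n_rel * ct) / (ci + n_rel * ct)
    rp = (ct - n_rel * ci) / (ct + n_rel * ci)
    return 0.5 * (rs * rs + rp * rp)


def sample_surface_slope(
    wind_speed: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Cox-Munk wave-slope samples (isotropic variant).

    Returns an array of shape (size, 2) of (s_x, s_y) facet slopes drawn
    from a zero-mean Gaussian with total variance 0.003 + 0.00512 W.
    """
    if wind_speed < 0:
        raise ValueError("wind speed must be >= 0")
    sigma2 = COX_MUNK_INTERCEPT + COX_MUNK_SLOPE * wind_speed
    return rng.normal(0.0, math.sqrt(sigma2 / 2.0), size=(size, 2))


@dataclass(frozen=True)
class RrsResult:
    """Remote sensing reflectance spectrum with Monte Carlo diagnostics."""

    grid: SpectralGrid
    rrs: np.ndarray  # sr^-1
    stderr: np.ndarray  # Monte Carlo standard error of rrs, sr^-1
    budget: dict  # per-wavelength energy-budget fractions
    n_photons: int
    seed: int
    eu_ed_ratio: np.ndarray | None = None  # E_u(0-)/E_d ratio diagnostic

    def to_dataframe(self):
        import pandas as pd

        d = {
            "wavelength_nm": self.grid.wavelengths,
            "rrs_sr^-1": self.rrs,
            "stderr_sr^-1": self.stderr,
        }
        for key, val in self.budget.items():
            d[f"budget_{key}"] = val
        return pd.DataFrame(d)


def _wavelength_seed(seed: int, i: int) -> int:
    return int((seed * 7919 + i * 104729 + 12345) % (2**31 - 1))


def simulate_rrs(
    scenario: Scenario,
    medium: LayeredMedium,
    grid: SpectralGrid | None = None,
) -> RrsResult:
    """Run the Monte Carlo transport for every wavelength of the medium.

    R_rs is the tallied water-leaving radiance within the receiver cone
    divided by the downwelling irradiance above the surface (the launched
    photon flux per unit area).
    """
    if grid is None:
        grid = medium.grid
    if not np.array_equal(grid.wavelengths, medium.grid.wavelengths):
        raise ValueError("requested grid does not match the medium grid")
    if any(
        not np.all(np.isfinite(lay.a)) or not np.all(np.isfinite(lay.b))
        for lay in medium.layers
    ):
        raise FloatingPointError("non-finite IOPs in the medium")

    nw = len(grid)
    sky_fn = scenario.sky_diffuse_fraction or default_sky_diffuse_fraction
    f_diff = np.asarray(sky_fn(grid.wavelengths), dtype=float)

    sigma2 = scenario.slope_variance()
    sun = math.radians(scenario.sun_zenith)
    cos_rec = math.cos(math.radians(scenario.receiver_half_angle))
    d_omega = 2.0 * math.pi * (1.0 - cos_rec)

    top = medium.layers[0]
    deep = medium.layers[-1]
    two_layer = len(medium.layers) > 1
    z1 = top.z_bot if two_layer else scenario.ocean_depth
    z2 = deep.z_bot

    rrs = np.empty(nw)
    stderr = np.empty(nw)
    eu = np.empty(nw)
    budget = {
        "absorbed_column": np.empty(nw),
        "absorbed_bottom": np.empty(nw),
        "water_leaving": np.empty(nw),
        "surface_lost": np.empty(nw),
    }

    for i, wl in enumerate(grid.wavelengths):
        n_med = seawater_refractive_index(wl)
        icdf_w = top.pf_water[i].inverse_cdf_cos(_N_ICDF)
        if top.pf_oil is not None:
            icdf_o = top.pf_oil[i].inverse_cdf_cos(_N_ICDF)
            fw1 = (
                top.b_water[i] / top.b[i] if top.b[i] > 0 else 1.0
            )
        else:
            icdf_o = icdf_w
            fw1 = 1.0
        fw2 = 1.0

        out = trace_wavelength(
            scenario.n_photons,
            _wavelength_seed(scenario.seed, i),
            math.sin(sun),
            math.cos(sun),
            float(f_diff[i]),
            sigma2,
            n_med,
            cos_rec,
            z1,
            z2,
            float(top.a[i]),
            float(top.b[i]),
            float(fw1),
            float(deep.a[i]),
            float(deep.b[i]),
            float(fw2),
            icdf_w,
            icdf_o,
            scenario.bottom_mirror,
            scenario.bottom_diffuse,
            RR_THRESHOLD,
            RR_SURVIVAL,
        )
        sum_c, sum_c2, w_leave, w_lost, w_abs, w_bot, w_up = out
        n = scenario.n_photons
        mean = sum_c / n
        var = max(sum_c2 - n * mean * mean, 0.0) / max(n - 1, 1)
        rrs[i] = mean / d_omega
        stderr[i] = math.sqrt(var / n) / d_omega
        eu[i] = w_up / n
        budget["absorbed_column"][i] = w_abs / n
        budget["absorbed_bottom"][i] = w_bot / n
        budget["water_leaving"][i] = w_leave / n
        budget["surface_lost"][i] = w_lost / n

    return RrsResult(
        grid=grid,
        rrs=rrs,
        stderr=stderr,
        budget=budget,
        n_photons=scenario.n_photons,
        seed=scenario.seed,
        eu_ed_ratio=eu,
    )


def with_photons(scenario: Scenario, n_photons: int, seed: int | None = None) -> Scenario:
    """Convenience copy with a new photon budget (and optionally seed)."""
    kw = {"n_photons": int(n_photons)}
    if seed is not None:
        kw["seed"] = int(seed)
    return replace(scenario, **kw)
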