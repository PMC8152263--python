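"""Synthetic optical templates for three dispersed-oil archetypes.

The archetypes emulate the statistical structure of laboratory
characterizations of a biodiesel (BD), a cylinder lubricant (CL) and a
North Sea crude (FL):

* real refractive index: a smooth 4th-order polynomial of wavelength,
  confined to [1.45, 1.53] over the visible range, with normal dispersion
  (higher index in the blue);
* imaginary index: exponentially decreasing with wavelength for CL and FL,
  the FL amplitude two orders of magnitude above CL (strongly absorbing
  crude vs. a clear refined product); a three-bump polynomial-like shape
  for BD;
* droplet volume size distributions: 2-3 mode log-normal mixtures with the
  main volume-density mode at 5 um (BD, FL) or 7 um (CL) and negligible
  volume above ~100 um, as produced by mechanical dispersion of oil in
  water.

All numeric constants here are SYNTHETIC SURROGATES, calibrated once so
that the dispersed-oil impact ordering on clear-ocean IOPs (crude-oil
absorption impact far above the others; scattering impacts of all three
comparable and large at 1 ppm) and the directional ocean-color responses
are respected. They are not measured oil properties.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import SpectralGrid
from .mie import ComplexIndexSpectrum, SizeDistribution

OIL_KINDS = ("BD", "CL", "FL")

N_MIN, N_MAX = 1.45, 1.53


@dataclass(frozen=True)
class OilTemplate:
    """Parameter set generating one oil archetype.

    n_poly: polynomial coefficients (ascending order) in the scaled
        wavelength u = (lambda - 550)/150, 5 entries (4th order).
    k_model: ("exp", amplitude, decay_nm) for CL/FL-style exponentials or
        ("bumps", base, (center_nm...), (amplitude...), width_nm) for BD.
    psd_modes: tuples (nominal mode diameter um, geometric sd, volume fraction);
        the nominal diameter is the peak of the volume density dV/dD.
    """

    kind: str
    n_poly: tuple[float, ...]
    k_model: tuple
    psd_modes: tuple[tuple[float, float, float], ...]
    seed: int = 0


# Calibration constants, versioned surrogates (see module docstring).
_TEMPLATES: dict[str, OilTemplate] = {
    "BD": OilTemplate(
        kind="BD",
        n_poly=(1.468, -0.0235, 0.0035, 0.0, 0.002),
        k_model=("bumps", 1.0e-6, (435.0, 520.0, 655.0), (5.0e-5, 3.0e-5, 1.5e-5), 25.0),
        psd_modes=((0.9, 1.4, 0.05), (5.0, 1.5, 0.80), (13.0, 1.45, 0.15)),
    ),
    "CL": OilTemplate(
        kind="CL",
        n_poly=(1.495, -0.012, 0.004, 0.0008, -0.0008),
        k_model=("exp", 2.2e-5, 120.0),
        psd_modes=((2.0, 1.4, 0.05), (7.0, 1.5, 0.62), (30.0, 1.5, 0.33)),
    ),
    "FL": OilTemplate(
        kind="FL",
        n_poly=(1.515, -0.013, 0.005, 0.001, -0.001),
        k_model=("exp", 2.2e-3, 120.0),
        psd_modes=((1.0, 1.4, 0.08), (5.0, 1.5, 0.72), (20.0, 1.5, 0.20)),
    ),
}


def get_template(kind: str) -> OilTemplate:
    try:
        return _TEMPLATES[kind]
    except KeyError:
        raise ValueError(f"unknown oil kind {kind!r}; expected one of {OIL_KINDS}")


def _eval_k(template: OilTemplate, wl: np.ndarray) -> np.ndarray:
    model = template.k_model
    if model[0] == "exp":
        _, amp, decay = model
        return amp * np.exp(-(wl - 400.0) / decay)
    if model[0] == "bumps":
        _, base, centers, amps, width = model
        k = np.full_like(wl, base, dtype=float)
        for c, a in zip(centers, amps):
            k += a * np.exp(-((wl - c) ** 2) / (2.0 * width**2))
        return k
    raise ValueError(f"unknown imaginary-index model {model[0]!r}")


def make_oil_index(kind: str, grid: SpectralGrid | None = None) -> ComplexIndexSpectrum:
    """Deterministic complex refractive-index spectrum for one oil kind."""
    if grid is None:
        grid = SpectralGrid()
    template = get_template(kind)
    wl = grid.wavelengths
    u = (wl - 550.0) / 150.0
    n = np.polynomial.polynomial.polyval(u, np.asarray(template.n_poly))
    n = np.clip(n, N_MIN, N_MAX)
    k = _eval_k(template, wl)
    return ComplexIndexSpectrum(grid=grid, n=n, k=k)


def make_psd(
    kind: str,
    total_ppm: float = 1.0,
    n_bins: int = 48,
    d_range_um: tuple[float, float] = (0.25, 120.0),
) -> SizeDistribution:
    """Multi-mode log-normal volume size distribution scaled to total_ppm.

    Each mode is a log-normal in diameter whose *density* peak dV/dD sits at
    the nominal mode diameter (the log-normal median is shifted by
    exp(ln^2 sigma_g) to place the density mode where stated).
    """
    return psd_from_template(
        get_template(kind), total_ppm=total_ppm, n_bins=n_bins,
        d_range_um=d_range_um,
    )


def jitter_template(template: OilTemplate, seed: int) -> OilTemplate:
    """Seeded multiplicative perturbation (<= 10%) of a template, for
    robustness sweeps. The real-index polynomial constant is nudged within
    the allowed [1.45, 1.53] band; k amplitude and PSD mode fractions are
    scaled by up to +/-10% (fractions renormalized)."""
    rng = np.random.default_rng(seed)

    def wiggle() -> float:
        return 1.0 + 0.1 * (2.0 * rng.random() - 1.0)

    model = template.k_model
    if model[0] == "exp":
        k_model = ("exp", model[1] * wiggle(), model[2])
    else:
        _, base, centers, amps, width = model
        k_model = ("bumps", base, centers, tuple(a * wiggle() for a in amps), width)

    fracs = np.array([m[2] * wiggle() for m in template.psd_modes])
    fracs /= fracs.sum()
    psd_modes = tuple(
        (m[0], m[1], float(f)) for m, f in zip(template.psd_modes, fracs)
    )

    n0 = float(np.clip(template.n_poly[0] + 0.002 * (2 * rng.random() - 1), 1.452, 1.528))
    n_poly = (n0,) + tuple(template.n_poly[1:])
    return replace(
        template, n_poly=n_poly, k_model=k_model, psd_modes=psd_modes, seed=seed
    )


def index_from_template(
    template: OilTemplate, grid: SpectralGrid | None = None
) -> ComplexIndexSpectrum:
    """Complex index spectrum from an explicit (possibly jittered) template."""
    if grid is None:
        grid = SpectralGrid()
    wl = grid.wavelengths
    u = (wl - 550.0) / 150.0
    n = np.clip(
        np.polynomial.polynomial.polyval(u, np.asarray(template.n_poly)), N_MIN, N_MAX
    )
    return ComplexIndexSpectrum(grid=grid, n=n, k=_eval_k(template, wl))


def psd_from_template(
    template: OilTemplate,
    total_ppm: float = 1.0,
    n_bins: int = 48,
    d_range_um: tuple[float, float] = (0.25, 120.0),
) -> SizeDistribution:
    """Size distribution from an explicit (possibly jittered) template.

    Each mode is a log-normal in diameter whose *density* peak dV/dD sits
    at the nominal mode diameter (the log-normal median is shifted by
    exp(ln^2 sigma_g) so the density mode lands where stated).
    """
    if not np.isfinite(total_ppm) or total_ppm <= 0:
        raise ValueError("total_ppm must be positive")
    d = np.geomspace(*d_range_um, n_bins)
    rho = np.zeros_like(d)
    for mode_d, sg, frac in template.psd_modes:
        lnsg = np.log(sg)
        median = mode_d * np.exp(lnsg**2)
        rho += (
            frac
            / (d * lnsg * np.sqrt(2 * np.pi))
            * np.exp(-((np.log(d) - np.log(median)) ** 2) / (2 * lnsg**2))
        )
    rho *= total_ppm / np.trapezoid(rho, d)
    return SizeDistribution(diameters=d, density=rho, total_ppm=total_ppm)
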