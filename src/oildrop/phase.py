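"""Scattering phase functions: construction, normalization, sampling.

Convention used repo-wide: a phase function p(theta) is the volume
scattering function normalized so that

    integral_0^pi p(theta) * 2*pi*sin(theta) dtheta = 1,

i.e. p is an angular probability density per steradian (azimuthally
symmetric scattering).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

NORMALIZATION_TOL = 1e-3


def default_angle_grid() -> np.ndarray:
    """Scattering-angle grid in degrees: 0-180 at 0.5 deg, log-dense < 5 deg.

    The forward diffraction peak of large droplets dominates sampling
    accuracy, hence the logarithmic refinement near 0.
    """
    fine = np.geomspace(0.01, 5.0, 64)
    coarse = np.arange(5.5, 180.0, 0.5)
    return np.concatenate(([0.0], fine, coarse, [180.0]))


@dataclass(frozen=True)
class PhaseFunction:
    """Tabulated azimuthally symmetric phase function.

    Parameters
    ----------
    angles:
        Scattering angles theta in degrees on [0, 180], strictly increasing.
    values:
        Probability density per steradian at each angle; non-negative.
    """

    angles: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ang = np.asarray(self.angles, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if ang.ndim != 1 or ang.shape != val.shape:
            raise ValueError("angles and values must be matching 1-D arrays")
        if ang[0] < 0 or ang[-1] > 180 or np.any(np.diff(ang) <= 0):
            raise ValueError("angles must be strictly increasing on [0, 180]")
        if np.any(~np.isfinite(val)) or np.any(val < 0):
            raise ValueError("phase function values must be finite and >= 0")
        object.__setattr__(self, "angles", ang)
        object.__setattr__(self, "values", val)

    # -- integral diagnostics -------------------------------------------------
    def integral(self) -> float:
        """The solid-angle integral (should be 1)."""
        th = np.radians(self.angles)
        return float(np.trapezoid(self.values * 2 * np.pi * np.sin(th), th))

    def is_normalized(self, tol: float = NORMALIZATION_TOL) -> bool:
        return abs(self.integral() - 1.0) <= tol

    def normalized(self) -> "PhaseFunction":
        return PhaseFunction(self.angles, self.values / self.integral())

    def backscatter_fraction(self) -> float:
        """Fraction of scattered power directed into theta > 90 deg."""
        ang = self.angles
        if 90.0 not in ang:  # insert an interpolated node at exactly 90 deg
            v90 = np.interp(90.0, ang, self.values)
            i = int(np.searchsorted(ang, 90.0))
            ang = np.insert(ang, i, 90.0)
            val = np.insert(self.values, i, v90)
        else:
            val = self.values
        th = np.radians(ang)
        w = val * 2 * np.pi * np.sin(th)
        back = np.trapezoid(w[ang >= 90.0], th[ang >= 90.0])
        return float(back / self.integral())

    def forward_fraction(self, max_angle_deg: float) -> float:
        """Integrated probability of scattering below ``max_angle_deg``."""
        th = np.radians(self.angles)
        w = self.values * 2 * np.pi * np.sin(th)
        mask = self.angles <= max_angle_deg
        return float(np.trapezoid(w[mask], th[mask]) / self.integral())

    def mean_cosine(self) -> float:
        th = np.radians(self.angles)
        w = self.values * 2 * np.pi * np.sin(th)
        return float(np.trapezoid(w * np.cos(th), th) / np.trapezoid(w, th))

    # -- sampling -------------------------------------------------------------
    def cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative distribution F(theta) on the angle grid, F in [0, 1]."""
        th = np.radians(self.angles)
        w = self.values * 2 * np.pi * np.sin(th)
        F = np.concatenate(([0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(th))))
        return self.angles, F / F[-1]

    def inverse_cdf_cos(self, n: int = 8192) -> np.ndarray:
        """cos(theta) at ``n`` uniform quantile levels, for inverse-CDF draws."""
        ang, F = self.cdf()
        F = np.maximum.accumulate(F)  # guard against flat-segment jitter
        u = np.linspace(0.0, 1.0, n)
        theta = np.interp(u, F, ang)
        return np.cos(np.radians(theta))


def sample_scattering(
    pf: PhaseFunction, rng: np.random.Generator, size: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (theta_deg, phi_rad) pairs from a tabulated phase function.

    theta by inverse-CDF on the tabulated density, phi uniform on [0, 2*pi).
    """
    ang, F = pf.cdf()
    F = np.maximum.accumulate(F)
    u = rng.random(size)
    theta = np.interp(u, F, ang)
    phi = rng.random(size) * 2 * np.pi
    return theta, phi


# -- analytic shapes ----------------------------------------------------------

def rayleigh_seawater(angles_deg: np.ndarray) -> PhaseFunction:
    """Pure-seawater phase function, proportional to 1 + 0.835 cos^2(theta)."""
    th = np.radians(np.asarray(angles_deg, dtype=float))
    # normalization: int (1 + 0.835 c^2) dOmega = 4*pi*(1 + 0.835/3)
    norm = 4 * np.pi * (1 + 0.835 / 3.0)
    return PhaseFunction(angles_deg, (1 + 0.835 * np.cos(th) ** 2) / norm)


def isotropic(angles_deg: np.ndarray) -> PhaseFunction:
    return PhaseFunction(
        angles_deg, np.full(np.asarray(angles_deg).shape, 1 / (4 * np.pi))
    )


def fournier_forand(
    angles_deg: np.ndarray, n: float = 1.08, mu: float = 3.5
) -> PhaseFunction:
    """Fournier-Forand particle phase function.

    Closed-form phase function for an ensemble of spheres with a Junge
    (hyperbolic) size distribution of slope ``mu`` and relative refractive
    index ``n``; the standard analytic surrogate for oceanic particulate
    scattering. Returned normalized to unit solid-angle integral.
    """
    ang = np.asarray(angles_deg, dtype=float)
    th = np.radians(ang)
    nu = (3.0 - mu) / 2.0
    s2 = np.sin(th / 2.0) ** 2
    delta = 4.0 / (3.0 * (n - 1.0) ** 2) * s2
    d180 = 4.0 / (3.0 * (n - 1.0) ** 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        term = (
            nu * (1 - delta)
            - (1 - delta**nu)
            + (delta * (1 - delta**nu) - nu * (1 - delta)) / s2
        )
        p = term / (4 * np.pi * (1 - delta) ** 2 * delta**nu)
    p += (
        (1 - d180**nu)
        / (16 * np.pi * (d180 - 1) * d180**nu)
        * (3 * np.cos(th) ** 2 - 1)
    )
    # theta = 0 is an integrable singularity; extend from the first finite node
    bad = ~np.isfinite(p)
    if bad.any():
        first_ok = np.argmin(bad)
        p[bad] = p[first_ok]
    p = np.maximum(p, 0.0)
    pf = PhaseFunction(ang, p)
    return pf.normalized()


def ff_mu_for_backscatter(
    bb_fraction: float, n: float = 1.08, angles_deg: np.ndarray | None = None
) -> float:
    """Solve for the Fournier-Forand slope ``mu`` giving a target b_b/b.

    The backscatter fraction is evaluated by numerical integration of the
    constructed phase function (robust against closed-form convention slips).
    """
    if angles_deg is None:
        angles_deg = default_angle_grid()

    def f(mu: float) -> float:
        return fournier_forand(angles_deg, n=n, mu=mu).backscatter_fraction() - bb_fraction

    lo, hi = 3.01, 3.99
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"target backscatter fraction {bb_fraction:g} outside the "
            f"reachable range [{min(flo, fhi) + bb_fraction:g}, "
            f"{max(flo, fhi) + bb_fraction:g}] for n={n:g}"
        )
    return float(brentq(f, lo, hi, xtol=1e-6))


def mix(pfs: list[PhaseFunction], weights: np.ndarray) -> PhaseFunction:
    """Weighted mixture of phase functions sharing one angle grid."""
    w = np.asarray(weights, dtype=float)
    if len(pfs) != w.size:
        raise ValueError("one weight per phase function required")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    ang = pfs[0].angles
    for pf in pfs[1:]:
        if pf.angles.shape != ang.shape or not np.allclose(pf.angles, ang):
            raise ValueError("phase functions must share the angle grid")
    w = w / w.sum()
    vals = sum(wi * pf.values for wi, pf in zip(w, pfs))
    return PhaseFunction(ang, vals)
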