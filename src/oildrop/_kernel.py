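"""Numba photon-transport kernel (one wavelength per call).

Geometry: plane-parallel, horizontally homogeneous; z in metres, positive
downward, 0 at the mean sea surface. Directions are unit vectors; uz > 0
moves a photon downward. Weighted (semi-analog) transport: absorption
attenuates the photon weight at each interaction, Russian roulette
terminates low-weight histories; surviving histories inject/withdraw the
compensating weight from the column-absorption tally so the energy budget
sums to exactly the launched weight on every run.

The receiver is nadir-viewing just above the surface: transmitted photons
whose air-side direction lies within the receiver half-angle of zenith
accumulate into the radiance tally. Photons reflected at the air-water
interface on entry never enter the water and are tagged surface-lost, so
surface-reflected sky/sun light is excluded from R_rs by construction.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_MAX_FACET_TRIES = 20


@njit(cache=True)
def _fresnel(ci: float, ct: float, n1: float, n2: float) -> float:
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def trace_wavelength(
    n_photons: int,
    seed: int,
    sun_ux: float,
    sun_uz: float,
    f_diffuse: float,
    sigma2: float,
    n_water: float,
    cos_receiver: float,
    z1: float,
    z2: float,
    a1: float,
    b1: float,
    fw1: float,
    a2: float,
    b2: float,
    fw2: float,
    icdf_w: np.ndarray,
    icdf_o: np.ndarray,
    bottom_mirror: float,
    bottom_diffuse: float,
    rr_threshold: float,
    rr_survival: float,
):
    """Trace ``n_photons`` histories; returns radiance and budget tallies.

    Returns (sum_cone, sum_cone_sq, leaving, surface_lost, absorbed_column,
    absorbed_bottom, upwelling_incident).
    """
    np.random.seed(seed)
    nu = icdf_w.shape[0]
    slope_sd = np.sqrt(sigma2 / 2.0) if sigma2 > 0.0 else 0.0

    sum_c = 0.0
    sum_c2 = 0.0
    w_leave = 0.0
    w_lost = 0.0
    w_abs = 0.0
    w_bot = 0.0
    w_up_inc = 0.0

    for _ in range(n_photons):
        # --- launch direction (direct beam or cardioid diffuse sky) ---------
        if np.random.random() < f_diffuse:
            # photon flux onto a horizontal surface from radiance
            # L ~ (1 + 2 cos t): pdf(mu) ~ mu (1 + 2 mu), exact mixture
            if np.random.random() < 3.0 / 7.0:
                mu = np.sqrt(np.random.random())
            else:
                mu = np.random.random() ** (1.0 / 3.0)
            phi = 2.0 * np.pi * np.random.random()
            st = np.sqrt(1.0 - mu * mu)
            ux = st * np.cos(phi)
            uy = st * np.sin(phi)
            uz = mu
        else:
            ux = sun_ux
            uy = 0.0
            uz = sun_uz
        w = 1.0
        cone = 0.0

        # --- refraction into the water across the wind-roughened surface ---
        alive = False
        for _try in range(_MAX_FACET_TRIES):
            if slope_sd > 0.0:
                sx = np.random.normal() * slope_sd
                sy = np.random.normal() * slope_sd
            else:
                sx = 0.0
                sy = 0.0
            fn = np.sqrt(1.0 + sx * sx + sy * sy)
            nx = -sx / fn
            ny = -sy / fn
            nz = -1.0 / fn  # facet normal points up (into the air)
            ci = -(ux * nx + uy * ny + uz * nz)
            if ci <= 1e-9:
                continue  # facet back side, resample
            eta = 1.0 / n_water
            st2 = eta * eta * (1.0 - ci * ci)
            ct = np.sqrt(1.0 - st2)
            if np.random.random() < _fresnel(ci, ct, 1.0, n_water):
                ux += 2.0 * ci * nx
                uy += 2.0 * ci * ny
                uz += 2.0 * ci * nz
                if uz < 0.0:
                    break  # reflected back to the sky: excluded from R_rs
                # reflected but still heading down: try the next facet
                continue
            ux = eta * ux + (eta * ci - ct) * nx
            uy = eta * uy + (eta * ci - ct) * ny
            uz = eta * uz + (eta * ci - ct) * nz
            un = np.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= un
            uy /= un
            uz /= un
            if uz > 0.0:
                alive = True
            break
        if not alive:
            w_lost += w
            continue

        z = 0.0
        tau = -np.log(np.random.random())

        # --- transport ------------------------------------------------------
        while alive:
            # current layer (boundary membership decided by travel direction)
            in_top = z < z1 or (z == z1 and uz < 0.0)
            if in_top:
                a = a1
                b = b1
                fw = fw1
            else:
                a = a2
                b = b2
                fw = fw2
            c = a + b

            if uz > 0.0:
                zb = z1 if in_top and z1 < z2 else z2
            elif uz < 0.0:
                zb = 0.0 if in_top else z1
            else:
                zb = -1.0  # horizontal: never reaches a boundary
            if zb >= 0.0:
                s_bound = (zb - z) / uz
                tau_bound = c * s_bound
            else:
                tau_bound = 1e300

            if tau <= tau_bound:
                # interaction inside the current layer
                z += uz * tau / c
                omega = b / c
                w_abs += w * (1.0 - omega)
                w *= omega
                if w <= 0.0:
                    alive = False
                    break
                # pick scatterer component by its share of b, draw the angle
                table = icdf_w if np.random.random() < fw else icdf_o
                uu = np.random.random() * (nu - 1)
                i0 = int(uu)
                if i0 >= nu - 1:
                    i0 = nu - 2
                fr = uu - i0
                cmu = table[i0] + (table[i0 + 1] - table[i0]) * fr
                phi = 2.0 * np.pi * np.random.random()
                smu = np.sqrt(max(0.0, 1.0 - cmu * cmu))
                cp = np.cos(phi)
                sp = np.sin(phi)
                if uz > 0.99999 or uz < -0.99999:
                    sign = 1.0 if uz > 0.0 else -1.0
                    ux = smu * cp
                    uy = smu * sp
                    uz = sign * cmu
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    tx = smu * (ux * uz * cp - uy * sp) / den + ux * cmu
                    ty = smu * (uy * uz * cp + ux * sp) / den + uy * cmu
                    tz = -smu * cp * den + uz * cmu
                    ux = tx
                    uy = ty
                    uz = tz
                # Russian roulette with budget-exact compensation
                if w < rr_threshold:
                    if np.random.random() < rr_survival:
                        w_abs -= w * (1.0 / rr_survival - 1.0)
                        w /= rr_survival
                    else:
                        w_abs += w
                        alive = False
                        break
                tau = -np.log(np.random.random())
                continue

            # boundary reached before the interaction
            tau -= tau_bound
            z = zb
            if uz < 0.0 and zb == 0.0:
                # attempt to exit through the rough surface
                w_up_inc += w
                exited = False
                for _try in range(_MAX_FACET_TRIES):
                    if slope_sd > 0.0:
                        sx = np.random.normal() * slope_sd
                        sy = np.random.normal() * slope_sd
                    else:
                        sx = 0.0
                        sy = 0.0
                    fn = np.sqrt(1.0 + sx * sx + sy * sy)
                    nx = -sx / fn
                    ny = -sy / fn
                    nz = -1.0 / fn
                    ci = ux * nx + uy * ny + uz * nz  # > 0 for upward photons
                    if ci <= 1e-9:
                        continue
                    st2 = n_water * n_water * (1.0 - ci * ci)
                    if st2 >= 1.0:
                        refl = 1.0  # total internal reflection
                        ct = 0.0
                    else:
                        ct = np.sqrt(1.0 - st2)
                        refl = _fresnel(ci, ct, n_water, 1.0)
                    if np.random.random() < refl:
                        ux -= 2.0 * ci * nx
                        uy -= 2.0 * ci * ny
                        uz -= 2.0 * ci * nz
                        if uz > 0.0:
                            break  # back down into the water column
                        continue  # still upward: next facet
                    # transmission to the air side; the facet normal points
                    # up (with the photon), so it enters with a minus sign
                    tx = n_water * ux - (n_water * ci - ct) * nx
                    ty = n_water * uy - (n_water * ci - ct) * ny
                    tz = n_water * uz - (n_water * ci - ct) * nz
                    tn = np.sqrt(tx * tx + ty * ty + tz * tz)
                    tz /= tn
                    w_leave += w
                    if -tz >= cos_receiver:
                        cone = w
                    exited = True
                    break
                else:
                    # pathological facet sequence: drop the history
                    w_lost += w
                    exited = True
                if exited:
                    alive = False
                continue
            if uz > 0.0 and zb >= z2:
                r = np.random.random()
                if r < bottom_mirror:
                    uz = -uz
                elif r < bottom_mirror + bottom_diffuse:
                    mu = np.sqrt(np.random.random())
                    phi = 2.0 * np.pi * np.random.random()
                    st = np.sqrt(1.0 - mu * mu)
                    ux = st * np.cos(phi)
                    uy = st * np.sin(phi)
                    uz = -mu
                else:
                    w_bot += w
                    alive = False
                continue
            # internal layer interface: IOPs change, direction does not
            continue

        sum_c += cone
        sum_c2 += cone * cone

    return sum_c, sum_c2, w_leave, w_lost, w_abs, w_bot, w_up_inc
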