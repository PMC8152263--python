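"""Independent brute-force Lorenz-Mie series oracle for cross-checks.

Deliberately coded on a different route than the package implementation:
the Mie coefficients are evaluated from the explicit Riccati-Bessel ratio
formulas, with the complex-argument spherical Bessel functions obtained by
Miller's downward recurrence normalized against the closed-form j_0, and
the real-argument Riccati-Bessel functions taken from scipy. The package
uses the logarithmic-derivative formulation instead; agreement between the
two is a genuine two-route check.
"""
from __future__ import annotations

import numpy as np
from scipy.special import riccati_jn, riccati_yn


def oracle_efficiencies(x: float, m: complex) -> tuple[float, float]:
    """(q_ext, q_sca) of a homogeneous sphere by the explicit series."""
    m = complex(m)
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    mx = m * x

    # complex-argument spherical Bessel j_n by Miller downward recurrence
    nstart = nmax + 40
    j = np.zeros(nstart + 2, dtype=complex)
    j[nstart + 1] = 0.0
    j[nstart] = 1e-30
    for n in range(nstart, 0, -1):
        j[n - 1] = (2 * n + 1) / mx * j[n] - j[n + 1]
    j *= (np.sin(mx) / mx) / j[0]

    psi_m = mx * j[: nmax + 1]
    ns = np.arange(1, nmax + 1)
    dpsi_m = mx * j[0:nmax] - ns / mx * psi_m[1:]

    psi, dpsi = riccati_jn(nmax, x)
    chi, dchi = riccati_yn(nmax, x)
    chi, dchi = -chi, -dchi
    xi = psi - 1j * chi
    dxi = dpsi - 1j * dchi

    pm = psi_m[1:]
    a = (m * pm * dpsi[1:] - psi[1:] * dpsi_m) / (m * pm * dxi[1:] - xi[1:] * dpsi_m)
    b = (pm * dpsi[1:] - m * psi[1:] * dpsi_m) / (pm * dxi[1:] - m * xi[1:] * dpsi_m)

    tn = 2 * ns + 1
    q_ext = 2.0 / x**2 * float(np.sum(tn * (a + b).real))
    q_sca = 2.0 / x**2 * float(np.sum(tn * (np.abs(a) ** 2 + np.abs(b) ** 2)))
    return q_ext, q_sca
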