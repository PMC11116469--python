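"""Mie scattering efficiencies for homogeneous spheres.

Implements the standard partial-wave (Lorenz–Mie) series for a
non-absorbing sphere of relative refractive index m = n_p/n0 and size
parameter x = pi * d * n0 / lambda0. The a_n, b_n coefficients use
Riccati–Bessel functions built from scipy's spherical Bessel routines;
series truncation follows the Wiscombe criterion
N = x + 4 x^(1/3) + 2.

Only real refractive indices are supported — proteins are effectively
non-absorbing at the red DLS wavelength this package targets.
"""

from __future__ import annotations

import numpy as np
from scipy.special import spherical_jn, spherical_yn

__all__ = ["mie_efficiencies", "scattering_cross_section", "rayleigh_qsca"]


def _n_terms(x: float) -> int:
    return int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2))


def mie_efficiencies(x: float, m: float) -> tuple[float, float]:
    """Scattering and extinction efficiencies (Q_sca, Q_ext) of a sphere.

    Parameters
    ----------
    x : float
        Size parameter 2*pi*r*n0/lambda0 (> 0).
    m : float
        Relative refractive index n_p/n0 (> 0, real).
    """
    if x <= 0:
        raise ValueError("size parameter must be positive")
    if m <= 0:
        raise ValueError("relative refractive index must be positive")
    nmax = _n_terms(x)
    n = np.arange(1, nmax + 1)

    # Riccati-Bessel psi_n(z) = z j_n(z), chi_n(z) = -z y_n(z)
    jx = spherical_jn(n, x)
    jpx = spherical_jn(n, x, derivative=True)
    yx = spherical_yn(n, x)
    ypx = spherical_yn(n, x, derivative=True)
    psi_x = x * jx
    psi_x_p = jx + x * jpx
    chi_x = -x * yx
    chi_x_p = -yx - x * ypx
    xi_x = psi_x - 1j * chi_x
    xi_x_p = psi_x_p - 1j * chi_x_p

    mx = m * x
    jmx = spherical_jn(n, mx)
    jpmx = spherical_jn(n, mx, derivative=True)
    psi_mx = mx * jmx
    psi_mx_p = jmx + mx * jpmx

    a = (m * psi_mx_p * psi_x - psi_mx * psi_x_p) / (m * psi_mx_p * xi_x - psi_mx * xi_x_p)
    b = (psi_mx_p * psi_x - m * psi_mx * psi_x_p) / (psi_mx_p * xi_x - m * psi_mx * xi_x_p)

    two_n_plus_1 = 2 * n + 1
    qsca = (2.0 / x**2) * np.sum(two_n_plus_1 * (np.abs(a) ** 2 + np.abs(b) ** 2))
    qext = (2.0 / x**2) * np.sum(two_n_plus_1 * np.real(a + b))
    return float(qsca), float(qext)


def rayleigh_qsca(x: float, m: float) -> float:
    """Small-particle (dipole) limit Q_sca = (8/3) x^4 |(m^2-1)/(m^2+2)|^2."""
    lorentz = (m**2 - 1.0) / (m**2 + 2.0)
    return (8.0 / 3.0) * x**4 * lorentz**2


def scattering_cross_section(
    d_nm: float, wavelength_nm: float, n_particle: float, n_medium: float
) -> float:
    """Total scattering cross-section (nm^2) of a sphere of diameter d.

    Used as the per-particle scattered-intensity proxy when converting
    intensity-weighted size distributions to number weights.
    """
    if d_nm <= 0:
        raise ValueError("diameter must be positive")
    x = np.pi * d_nm * n_medium / wavelength_nm
    qsca, _ = mie_efficiencies(x, n_particle / n_medium)
    return qsca * np.pi * (d_nm / 2.0) ** 2
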