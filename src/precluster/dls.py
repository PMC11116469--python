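"""Dynamic light scattering: instrument model, Stokes–Einstein conversions,
single-exponential correlation fits, intensity-to-number size-distribution
inversion (Rayleigh d^6 rule or full Mie cross-sections) and cluster-size
estimation from hydrodynamic diameters.

The intensity autocorrelation of a monodisperse scatterer population is

    G(tau) = 1 + b * exp(-2 * D_t * q^2 * tau)

with instrument constant b, translational diffusion coefficient D_t and
scattering vector q = 4 pi n0 / lambda0 * sin(theta/2). D_t maps to a
hydrodynamic radius through the Stokes-Einstein relation
D_t = k_B T / (6 pi eta R_h), and sizes are reported as hydrodynamic
diameters d_H = 2 R_h.

Clusters are modelled as spheres packed with monomers at a packing
fraction p, giving an occupancy n = p (d_H / d_monomer)^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize as lm_minimize

from .containers import ClusterSizeHistogram, CorrelationCurve, SizeDistribution
from .mie import scattering_cross_section

__all__ = [
    "BOLTZMANN",
    "DLSInstrument",
    "scattering_vector",
    "stokes_einstein",
    "diameter_from_diffusion",
    "fit_monoexponential",
    "MonoexpFit",
    "intensity_to_number",
    "number_to_intensity",
    "cluster_size_from_dh",
    "cluster_histogram",
    "histogram_dh",
]

BOLTZMANN = 1.381e-23  # J/K


@dataclass
class DLSInstrument:
    """Optical and solvent parameters of a backscattering DLS instrument.

    Defaults correspond to a 632.8 nm laser detected at 173 degrees in
    aqueous buffer near room temperature.
    """

    wavelength_nm: float = 632.8
    scattering_angle_deg: float = 173.0
    n_medium: float = 1.33
    temperature_K: float = 298.15
    viscosity_Pa_s: float = 0.89e-3
    n_particle: float = 1.45  # typical protein; used only by Mie inversion

    def __post_init__(self) -> None:
        if not (0 < self.scattering_angle_deg < 180):
            raise ValueError("scattering angle must lie in (0, 180) degrees")
        if min(self.wavelength_nm, self.n_medium, self.temperature_K, self.viscosity_Pa_s) <= 0:
            raise ValueError("wavelength, refractive index, temperature and viscosity must be positive")


def scattering_vector(instrument: DLSInstrument) -> float:
    """Magnitude of the scattering vector q in 1/nm."""
    theta = np.deg2rad(instrument.scattering_angle_deg)
    return 4.0 * np.pi * instrument.n_medium / instrument.wavelength_nm * np.sin(theta / 2.0)


def stokes_einstein(instrument: DLSInstrument, d_h_nm: float | np.ndarray) -> float | np.ndarray:
    """Translational diffusion coefficient (m^2/s) of a sphere of
    hydrodynamic diameter d_H (nm)."""
    d = np.asarray(d_h_nm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("hydrodynamic diameter must be positive")
    r_h_m = d * 1e-9 / 2.0
    out = BOLTZMANN * instrument.temperature_K / (6.0 * np.pi * instrument.viscosity_Pa_s * r_h_m)
    return float(out) if np.isscalar(d_h_nm) else out


def diameter_from_diffusion(instrument: DLSInstrument, d_t: float | np.ndarray) -> float | np.ndarray:
    """Inverse Stokes-Einstein: hydrodynamic diameter (nm) from D_t (m^2/s)."""
    dt = np.asarray(d_t, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("diffusion coefficient must be positive")
    r_h_m = BOLTZMANN * instrument.temperature_K / (6.0 * np.pi * instrument.viscosity_Pa_s * dt)
    out = 2.0 * r_h_m * 1e9
    return float(out) if np.isscalar(d_t) else out


@dataclass
class MonoexpFit:
    d_t: float  # m^2/s
    b: float
    d_h: float  # nm
    chi2_red: float


def fit_monoexponential(curve: CorrelationCurve, instrument: DLSInstrument) -> MonoexpFit:
    """Weighted least-squares fit of G(tau) = 1 + b exp(-2 D q^2 tau).

    Lags are interpreted in milliseconds. Raises on curves with no decay.
    """
    if curve.kind != "intensity":
        raise ValueError("monoexponential DLS fit requires an intensity-kind curve")
    if len(curve) < 5:
        raise ValueError("need at least 5 points spanning the decay")
    y = curve.values - 1.0
    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        raise ValueError("curve is flat: no decay to fit")
    q_per_m = scattering_vector(instrument) * 1e9  # 1/m
    tau_s = curve.lags * 1e-3
    w = np.sqrt(curve.weights())

    # log-slope start: slope of ln(y) over the positive early part
    pos = y > max(y.max() * 1e-3, 0.0)
    slope = np.polyfit(tau_s[pos], np.log(y[pos]), 1)[0]
    d0 = max(-slope / (2.0 * q_per_m**2), 1e-16)

    params = Parameters()
    params.add("b", value=max(y.max(), 1e-6), min=1e-12)
    params.add("log10_D", value=np.log10(d0), min=-18, max=-6)

    def residual(p):
        model = p["b"].value * np.exp(-2.0 * 10 ** p["log10_D"].value * q_per_m**2 * tau_s)
        return (model - y) * w

    res = lm_minimize(residual, params)
    if not res.success:
        raise RuntimeError("monoexponential fit failed to converge")
    d_t = 10 ** res.params["log10_D"].value
    chi2_red = float(np.sum(res.residual**2) / max(len(curve) - 2, 1))
    return MonoexpFit(d_t=d_t, b=float(res.params["b"].value),
                      d_h=float(diameter_from_diffusion(instrument, d_t)), chi2_red=chi2_red)


def _scatter_intensity(d_h: np.ndarray, instrument: DLSInstrument, method: str) -> np.ndarray:
    if method == "rayleigh":
        return d_h**6
    if method == "mie":
        return np.array(
            [
                scattering_cross_section(d, instrument.wavelength_nm, instrument.n_particle, instrument.n_medium)
                for d in d_h
            ]
        )
    raise ValueError("method must be 'rayleigh' or 'mie'")


def intensity_to_number(
    dist: SizeDistribution, instrument: DLSInstrument, method: str = "mie"
) -> SizeDistribution:
    """Convert an intensity-weighted size distribution to number weights.

    Number weights are intensity weights divided by the per-particle
    scattered intensity — the d^6 dipole rule for ``method="rayleigh"`` or
    the full Mie scattering cross-section at the instrument wavelength for
    ``method="mie"`` (the hydrodynamic diameter is identified with the
    optical sphere diameter, an approximation). Output is renormalized to
    unit sum.
    """
    if dist.weighting != "intensity":
        raise ValueError("input distribution must be intensity-weighted")
    intensity = _scatter_intensity(dist.d_h, instrument, method)
    if np.any((intensity == 0) & (dist.weights > 0)):
        raise ValueError("zero scattering intensity at a bin with nonzero weight")
    number = np.where(dist.weights > 0, dist.weights / intensity, 0.0)
    number /= number.sum()
    return SizeDistribution(dist.d_h, number, weighting="number", bin_width=dist.bin_width)


def number_to_intensity(
    dist: SizeDistribution, instrument: DLSInstrument, method: str = "mie"
) -> SizeDistribution:
    """Inverse of :func:`intensity_to_number` (unit-sum intensity weights)."""
    if dist.weighting != "number":
        raise ValueError("input distribution must be number-weighted")
    intensity_per = _scatter_intensity(dist.d_h, instrument, method)
    w = dist.weights * intensity_per
    w /= w.sum()
    return SizeDistribution(dist.d_h, w, weighting="intensity", bin_width=dist.bin_width)


def cluster_size_from_dh(
    d_h: float | np.ndarray, monomer_d: float, p: float, rounded: bool = False
) -> float | np.ndarray:
    """Number of molecules in a spherical cluster of diameter d_H.

    n = p * (d_H / d_monomer)^3, with packing fraction p in (0, 0.74]
    (0.74 crystalline, 0.64 random close packing, 0.33 condensate-like).
    ``rounded=True`` applies round-half-even to the continuous value.
    """
    if not (0 < p <= 0.74):
        raise ValueError("packing fraction must be in (0, 0.74]")
    if monomer_d <= 0:
        raise ValueError("monomer diameter must be positive")
    d = np.asarray(d_h, dtype=float)
    if np.any(d < 0):
        raise ValueError("hydrodynamic diameter must be non-negative")
    n = p * (d / monomer_d) ** 3
    if rounded:
        n = np.round(n)
    return float(n) if np.isscalar(d_h) else n


def cluster_histogram(dist: SizeDistribution, monomer_d: float, p: float) -> ClusterSizeHistogram:
    """Map a d_H distribution to a cluster-occupancy histogram, carrying
    the frequency weights over unchanged."""
    keep = dist.d_h > 0
    n = cluster_size_from_dh(dist.d_h[keep], monomer_d, p)
    return ClusterSizeHistogram(n=n, frequencies=dist.weights[keep], packing_fraction=p, monomer_diameter=monomer_d)


def histogram_dh(d_h_values: np.ndarray, bin_width: float = 0.1) -> SizeDistribution:
    """Frequency histogram of observed d_H values on half-open bins
    [d, d + bin_width); conserves total count."""
    d = np.asarray(d_h_values, dtype=float)
    if d.size == 0:
        raise ValueError("no d_H values to histogram")
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.floor(d.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    centers = edges[:-1] + bin_width / 2.0
    return SizeDistribution(centers, counts.astype(float), weighting="number", bin_width=bin_width)
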