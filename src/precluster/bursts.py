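"""Single-molecule burst analysis: threshold burst selection on binned
intensity traces, per-burst fluorescence-lifetime estimation, and the
static/dynamic FRET reference lines in efficiency-vs-lifetime space.

Burst selection follows the intensity-threshold convention: the mean and
standard deviation of the background are estimated iteratively from
below-threshold bins, bursts are contiguous runs of bins exceeding
mean + sigma_mult * sd (sigma_mult = 2 by default), and bursts outside a
[10, 3000]-photon window are discarded.

The FRET lines map a donor fluorescence-weighted lifetime tau (ns) to a
FRET efficiency E. Their polynomial/rational coefficients are treated as
opaque dataset-specific calibration constants, configurable via
:class:`FretLineCoefficients`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .containers import IntensityTrace

__all__ = [
    "Burst",
    "BurstTable",
    "select_bursts",
    "burst_lifetime",
    "FretLineCoefficients",
    "fret_lines",
    "efficiency_lifetime_histogram",
]


@dataclass
class Burst:
    start_s: float
    stop_s: float
    photons: float
    mean_rate_khz: float
    lifetime_ns: float | None = None


@dataclass
class BurstTable:
    bursts: list[Burst]
    background_mean: float  # counts per bin
    background_sd: float
    threshold: float

    def __len__(self) -> int:
        return len(self.bursts)

    @property
    def photon_counts(self) -> np.ndarray:
        return np.array([b.photons for b in self.bursts])


def select_bursts(
    trace: IntensityTrace,
    sigma_mult: float = 2.0,
    min_photons: int = 10,
    max_photons: int = 3000,
) -> BurstTable:
    """Select bursts as contiguous runs of bins above an iteratively
    estimated background threshold.

    Background mean/sd come from two passes: first over all bins, then
    restricted to bins below the first-pass threshold. Bursts with fewer
    than ``min_photons`` or more than ``max_photons`` photons are dropped.
    """
    counts = trace.counts
    if counts.size < 100:
        raise ValueError("need at least 100 bins to estimate background")
    mean, sd = counts.mean(), counts.std()
    below = counts <= mean + sigma_mult * sd
    if not np.any(below):
        raise ValueError("all bins above threshold: background not estimable")
    mean, sd = counts[below].mean(), counts[below].std()
    threshold = mean + sigma_mult * sd

    above = counts > threshold
    bursts: list[Burst] = []
    bin_s = trace.bin_width * 1e-3
    i = 0
    while i < counts.size:
        if above[i]:
            j = i
            while j + 1 < counts.size and above[j + 1]:
                j += 1
            photons = float(counts[i : j + 1].sum())
            if min_photons <= photons <= max_photons:
                start = trace.bin_times[i]
                stop = trace.bin_times[j] + bin_s
                duration_ms = (j - i + 1) * trace.bin_width
                bursts.append(
                    Burst(start_s=start, stop_s=stop, photons=photons, mean_rate_khz=photons / duration_ms)
                )
            i = j + 1
        else:
            i += 1
    return BurstTable(bursts=bursts, background_mean=mean, background_sd=sd, threshold=threshold)


def burst_lifetime(
    delays_ns: np.ndarray,
    background_fraction: float = 0.0,
    period_ns: float = 25.0,
    min_photons: int = 10,
) -> float:
    """Maximum-likelihood mono-exponential lifetime (ns) of a photon-delay
    sample, mixed with a flat background of the stated fraction over the
    excitation period.

    With zero background the estimator reduces exactly to the sample mean
    of the delays (the exponential MLE identity).
    """
    t = np.asarray(delays_ns, dtype=float)
    if t.size < min_photons:
        raise ValueError(f"need at least {min_photons} photons for a lifetime estimate")
    if not (0.0 <= background_fraction <= 1.0):
        raise ValueError("background fraction must lie in [0, 1]")
    if background_fraction >= 1.0:
        raise ValueError("background fraction 1.0: no fluorescence signal to fit")
    if background_fraction == 0.0:
        return float(t.mean())

    beta = background_fraction

    def nll(tau: float) -> float:
        sig = (1.0 - beta) / tau * np.exp(-t / tau)
        return -np.sum(np.log(sig + beta / period_ns))

    res = minimize_scalar(nll, bounds=(1e-3, 10.0 * max(t.mean(), 1e-3)), method="bounded")
    return float(res.x)


@dataclass
class FretLineCoefficients:
    """Dataset-specific calibration constants of the FRET lines.

    ``static_poly`` are the quartic coefficients (tau^4 ... tau^0) of the
    static-line numerator; ``divisor`` the donor-only normalization;
    the dynamic line is E = 1 - (tau1*tau2)/(divisor*(tau1 + tau2 -
    (slope*tau - intercept))).
    """

    static_poly: tuple[float, ...] = (0.0065, -0.0927, 0.4244, 0.3738, -0.0215)
    divisor: float = 3.9000
    tau1: float = 1.7000
    tau2: float = 3.7000
    dynamic_slope: float = 1.3337
    dynamic_intercept: float = 1.2360


def fret_lines(
    tau_ns: float | np.ndarray,
    which: str = "static",
    coeffs: FretLineCoefficients | None = None,
) -> float | np.ndarray:
    """FRET efficiency on the static or dynamic reference line at donor
    lifetime tau (ns).

    Raises ``ZeroDivisionError`` where the dynamic line's denominator
    vanishes (its vertical asymptote).
    """
    c = coeffs or FretLineCoefficients()
    tau = np.asarray(tau_ns, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lifetimes must be non-negative")
    if which == "static":
        e = 1.0 - np.polyval(c.static_poly, tau) / c.divisor
    elif which == "dynamic":
        denom = c.divisor * (c.tau1 + c.tau2 - (c.dynamic_slope * tau - c.dynamic_intercept))
        if np.any(denom == 0):
            raise ZeroDivisionError("dynamic FRET line evaluated at its vertical asymptote")
        e = 1.0 - (c.tau1 * c.tau2) / denom
    else:
        raise ValueError("which must be 'static' or 'dynamic'")
    return float(e) if np.isscalar(tau_ns) else e


def efficiency_lifetime_histogram(
    efficiencies: np.ndarray,
    lifetimes_ns: np.ndarray,
    e_bins: np.ndarray | int = 50,
    tau_bins: np.ndarray | int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D burst histogram in (E, tau) space; its marginals equal the 1-D
    histograms on the same bin edges (count conservation)."""
    e = np.asarray(efficiencies, dtype=float)
    tau = np.asarray(lifetimes_ns, dtype=float)
    if e.shape != tau.shape:
        raise ValueError("need one lifetime per efficiency")
    hist, e_edges, tau_edges = np.histogram2d(e, tau, bins=[e_bins, tau_bins])
    return hist, e_edges, tau_edges
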