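"""Synthetic-data generators with known ground truth for every pipeline
stage: FCS curves, DLS correlation curves, particle coordinate frames,
binned burst traces and photon delays, microfluidic scans, and melting
curves.

All generators are bitwise-reproducible under a fixed seed, and their
noiseless output equals the corresponding closed-form model to floating-
point round-off, so every downstream estimator can be tested against the
truth the generator records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .containers import CorrelationCurve, Frame, IntensityTrace, MeltingCurve, SizeDistribution, TrajectoryFrameSet
from .dls import DLSInstrument, scattering_vector, stokes_einstein
from .fcs import FcsModelParams, eval_fcs_model
from .mcs import AVOGADRO, MCSGeometry

__all__ = [
    "FcsSimSpec",
    "ParticleFrameSpec",
    "MeltSimSpec",
    "gen_fcs_curve",
    "eval_dls_model",
    "gen_dls_curve",
    "gen_particle_frames",
    "gen_burst_trace",
    "gen_photon_delays",
    "gen_mcs_scan",
    "gen_melting_curve",
]

NoiseSpec = float | Callable[[np.ndarray], np.ndarray]


def _noise_sd_array(noise_sd: NoiseSpec, lags: np.ndarray) -> np.ndarray:
    if callable(noise_sd):
        return np.broadcast_to(np.asarray(noise_sd(lags), dtype=float), lags.shape).copy()
    return np.full_like(lags, float(noise_sd))


# ---------------------------------------------------------------- FCS


@dataclass
class FcsSimSpec:
    """Ground-truth parameters of a simulated FCS curve.

    components: (fraction, diffusion_time_ms) pairs, fractions summing to 1.
    noise_sd: constant or a function of the lag grid.
    """

    components: Sequence[tuple[float, float]]
    n_particles: float = 1.0
    aspect_ratio: float = 5.0
    bunching_amplitude: float = 0.0
    bunching_time_ms: float = 1e-3
    offset: float = 0.0
    noise_sd: NoiseSpec = 0.0
    lag_grid_ms: np.ndarray = field(default_factory=lambda: np.logspace(-4, 2, 160))
    seed: int = 0

    def __post_init__(self) -> None:
        self.lag_grid_ms = np.asarray(self.lag_grid_ms, dtype=float)
        fr = np.array([f for f, _ in self.components], dtype=float)
        td = np.array([t for _, t in self.components], dtype=float)
        if abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError("component fractions must sum to 1")
        if np.any(td <= 0) or self.bunching_time_ms <= 0:
            raise ValueError("all times must be positive")
        if np.any(np.diff(self.lag_grid_ms) <= 0) or np.any(self.lag_grid_ms <= 0):
            raise ValueError("lag grid must be positive and strictly increasing")

    def model_params(self) -> FcsModelParams:
        return FcsModelParams(
            fractions=tuple(f for f, _ in self.components),
            diffusion_times=tuple(t for _, t in self.components),
            n_particles=self.n_particles,
            aspect_ratio=self.aspect_ratio,
            bunching_amplitude=self.bunching_amplitude,
            bunching_time=self.bunching_time_ms,
            offset=self.offset,
        )


def gen_fcs_curve(spec: FcsSimSpec) -> CorrelationCurve:
    """Simulate an FCS autocorrelation curve: the multi-component
    3D-Gaussian model plus Gaussian noise of the stated per-point SD,
    which is also stored as the error column."""
    clean = eval_fcs_model(spec.lag_grid_ms, spec.model_params())
    sd = _noise_sd_array(spec.noise_sd, spec.lag_grid_ms)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, 1.0, spec.lag_grid_ms.size) * sd
    return CorrelationCurve(spec.lag_grid_ms, clean.values + noise, sd, kind="fluorescence")


# ---------------------------------------------------------------- DLS


def eval_dls_model(
    tau_ms: np.ndarray, size_dist: SizeDistribution, instrument: DLSInstrument, b: float
) -> np.ndarray:
    """Closed-form polydisperse intensity correlation
    G(tau) = 1 + b * g1(tau)^2, g1 = sum_i w_i exp(-D_i q^2 tau) with
    intensity weights w_i derived from the number weights by the d^6
    dipole rule. Accepts tau = 0."""
    if size_dist.weighting != "number":
        raise ValueError("generator requires a number-weighted distribution")
    if b <= 0:
        raise ValueError("coherence factor b must be positive")
    tau = np.asarray(tau_ms, dtype=float)
    w_int = size_dist.weights * size_dist.d_h**6
    total = w_int.sum()
    if total == 0:
        raise ValueError("distribution has zero total intensity")
    w_int = w_int / total
    q = scattering_vector(instrument) * 1e9  # 1/m
    d = stokes_einstein(instrument, size_dist.d_h)  # m^2/s
    decay = np.exp(-np.outer(tau * 1e-3, d * q**2))  # (n_tau, n_sizes)
    g1 = decay @ w_int
    return 1.0 + b * g1**2


def gen_dls_curve(
    size_dist: SizeDistribution,
    instrument: DLSInstrument,
    b: float = 0.9,
    noise_sd: NoiseSpec = 0.0,
    seed: int = 0,
    lag_grid_ms: np.ndarray | None = None,
) -> CorrelationCurve:
    """Simulate a DLS intensity correlation curve for a polydisperse,
    number-weighted size distribution."""
    if lag_grid_ms is None:
        lag_grid_ms = np.logspace(-4, 3, 200)
    lag_grid_ms = np.asarray(lag_grid_ms, dtype=float)
    clean = eval_dls_model(lag_grid_ms, size_dist, instrument, b)
    sd = _noise_sd_array(noise_sd, lag_grid_ms)
    rng = np.random.default_rng(seed)
    values = clean + rng.normal(0.0, 1.0, lag_grid_ms.size) * sd
    return CorrelationCurve(lag_grid_ms, values, sd, kind="intensity")


# ---------------------------------------------------------------- frames


@dataclass
class ParticleFrameSpec:
    """Specification of synthetic solvation frames around a central
    peptide.

    ``density_profile`` maps a species ("anion", "cation", "water") to a
    list of non-overlapping radial shells (r_lo_nm, r_hi_nm, multiplier):
    the local density inside each shell is the bulk density times the
    multiplier (accumulation > 1, depletion < 1). Shell radii must stay
    within half the box edge so expectations have closed form.
    """

    box_edge_nm: float = 7.0
    n_anion: int = 60
    n_cation: int = 60
    n_water: int = 2000
    density_profile: dict[str, list[tuple[float, float, float]]] = field(default_factory=dict)
    peptide_offsets_nm: np.ndarray = field(default_factory=lambda: np.zeros((1, 3)))
    peptide_masses: np.ndarray = field(default_factory=lambda: np.array([100.0]))
    net_charge: float = 0.0
    n_frames: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.peptide_offsets_nm = np.asarray(self.peptide_offsets_nm, dtype=float).reshape(-1, 3)
        self.peptide_masses = np.asarray(self.peptide_masses, dtype=float)
        if self.box_edge_nm <= 0:
            raise ValueError("box edge must be positive")
        half = self.box_edge_nm / 2.0
        for species, shells in self.density_profile.items():
            shells_sorted = sorted(shells)
            for (lo, hi, mult) in shells_sorted:
                if not (0 <= lo < hi):
                    raise ValueError("shell radii must satisfy 0 <= r_lo < r_hi")
                if hi > half + 1e-12:
                    raise ValueError("shell radii must stay within half the box edge")
                if mult < 0:
                    raise ValueError("shell multipliers must be non-negative")
            for (_, hi1, _), (lo2, _, _) in zip(shells_sorted, shells_sorted[1:]):
                if lo2 < hi1 - 1e-12:
                    raise ValueError(f"overlapping shells for species {species!r}")

    # -- closed-form expectations ------------------------------------

    def _shells(self, species: str) -> list[tuple[float, float, float]]:
        return sorted(self.density_profile.get(species, []))

    def _norm_volume(self, species: str) -> float:
        """Integral of the density multiplier over the box (nm^3)."""
        v = self.box_edge_nm**3
        for lo, hi, mult in self._shells(species):
            v += (mult - 1.0) * 4.0 / 3.0 * np.pi * (hi**3 - lo**3)
        return v

    def expected_cumulative(self, species: str, r_nm: np.ndarray) -> np.ndarray:
        """Expected number of ``species`` particles within distance r of
        the box center."""
        r = np.asarray(r_nm, dtype=float)
        n_total = {"anion": self.n_anion, "cation": self.n_cation, "water": self.n_water}[species]
        vol = 4.0 / 3.0 * np.pi * np.minimum(r, self.box_edge_nm / 2.0) ** 3
        for lo, hi, mult in self._shells(species):
            inner = np.clip(np.minimum(r, hi), lo, None) ** 3 - lo**3
            vol = vol + (mult - 1.0) * 4.0 / 3.0 * np.pi * np.maximum(inner, 0.0)
        return n_total * vol / self._norm_volume(species)

    def expected_gamma(
        self, species: str, r_nm: np.ndarray, bulk_shell_nm: tuple[float, float] = (2.5, 3.38)
    ) -> np.ndarray:
        """Analytic preferential-interaction profile implied by the shell
        multipliers (ground truth for the estimator)."""
        lo, hi = bulk_shell_nm
        bulk_ion = self.expected_cumulative(species, np.array([hi]))[0] - self.expected_cumulative(
            species, np.array([lo])
        )[0]
        bulk_wat = self.expected_cumulative("water", np.array([hi]))[0] - self.expected_cumulative(
            "water", np.array([lo])
        )[0]
        ratio = bulk_ion / bulk_wat
        return self.expected_cumulative(species, r_nm) - self.expected_cumulative("water", r_nm) * ratio


def _sample_species(
    rng: np.random.Generator, n: int, box: float, shells: list[tuple[float, float, float]]
) -> np.ndarray:
    """Rejection-sample ``n`` positions with radial density multipliers
    about the box center, wrapped into [0, box)."""
    if not shells:
        return rng.uniform(0.0, box, size=(n, 3))
    m_max = max(1.0, max(m for _, _, m in shells))
    center = np.full(3, box / 2.0)
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        batch = max(4 * (n - filled), 64)
        pts = rng.uniform(0.0, box, size=(batch, 3))
        r = np.linalg.norm(pts - center, axis=1)
        mult = np.ones(batch)
        for lo, hi, m in shells:
            mult[(r >= lo) & (r < hi)] = m
        keep = rng.uniform(0.0, m_max, batch) < mult
        pts = pts[keep]
        take = min(pts.shape[0], n - filled)
        out[filled : filled + take] = pts[:take]
        filled += take
    return out


def gen_particle_frames(spec: ParticleFrameSpec) -> TrajectoryFrameSet:
    """Generate frames of anion/cation/water positions around a central
    peptide, with local densities modulated by the spec's radial shell
    multipliers. The analytic expected Gamma(r) is attached as ground
    truth (``result.ground_truth``)."""
    rng = np.random.default_rng(spec.seed)
    box = np.full(3, spec.box_edge_nm)
    center = box / 2.0
    frames = []
    for _ in range(spec.n_frames):
        frames.append(
            Frame(
                peptide_xyz=center + spec.peptide_offsets_nm,
                peptide_masses=spec.peptide_masses,
                anion_xyz=_sample_species(rng, spec.n_anion, spec.box_edge_nm, spec._shells("anion")),
                cation_xyz=_sample_species(rng, spec.n_cation, spec.box_edge_nm, spec._shells("cation")),
                water_xyz=_sample_species(rng, spec.n_water, spec.box_edge_nm, spec._shells("water")),
                box=box.copy(),
            )
        )
    truth = {
        "spec": spec,
        "expected_cumulative": spec.expected_cumulative,
        "expected_gamma": spec.expected_gamma,
    }
    return TrajectoryFrameSet({"rep0": frames}, net_charge=spec.net_charge, ground_truth=truth)


# ---------------------------------------------------------------- bursts


def gen_burst_trace(
    background_rate_khz: float,
    burst_events: list[tuple[float, float, float]],
    bin_width_ms: float = 1.0,
    total_time_s: float = 10.0,
    seed: int = 0,
    lifetime_ns: float | None = None,
) -> tuple[IntensityTrace, list[tuple[float, float, float]]]:
    """Simulate a binned photon-count trace: Poisson background at
    ``background_rate_khz`` plus burst events given as (start_s,
    duration_s, rate_khz). Overlapping events are merged with summed
    rates; the merged event list is returned as ground truth. If
    ``lifetime_ns`` is given, per-photon delay times drawn from a
    mono-exponential of that lifetime are attached to the trace."""
    if background_rate_khz < 0 or any(r < 0 for _, _, r in burst_events):
        raise ValueError("rates must be non-negative")
    for start, dur, _ in burst_events:
        if start < 0 or start + dur > total_time_s:
            raise ValueError("events must lie within the trace")
    n_bins = int(round(total_time_s / (bin_width_ms * 1e-3)))
    edges = np.arange(n_bins + 1) * bin_width_ms * 1e-3
    rate_per_bin = np.full(n_bins, background_rate_khz)  # kHz == counts/ms
    for start, dur, rate in burst_events:
        overlap = np.clip(np.minimum(edges[1:], start + dur) - np.maximum(edges[:-1], start), 0.0, None)
        rate_per_bin += rate * overlap / (bin_width_ms * 1e-3)

    # merge overlapping truth events, summing rates on overlap segments
    merged: list[tuple[float, float, float]] = []
    for start, dur, rate in sorted(burst_events):
        if merged and start < merged[-1][1]:
            s0, e0, r0 = merged[-1]
            merged[-1] = (s0, max(e0, start + dur), r0 + rate)
        else:
            merged.append((start, start + dur, rate))

    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate_per_bin * bin_width_ms).astype(float)
    delays = None
    if lifetime_ns is not None:
        delays = rng.exponential(lifetime_ns, size=int(counts.sum()))
    trace = IntensityTrace(edges[:-1], counts, bin_width_ms, photon_delays=delays)
    return trace, merged


def gen_photon_delays(
    n: int, lifetime_ns: float, background_fraction: float = 0.0, period_ns: float = 25.0, seed: int = 0
) -> np.ndarray:
    """Draw photon delay times: a mono-exponential of the stated lifetime
    mixed with a flat background over the excitation period."""
    rng = np.random.default_rng(seed)
    is_bg = rng.uniform(size=n) < background_fraction
    delays = rng.exponential(lifetime_ns, size=n)
    delays[is_bg] = rng.uniform(0.0, period_ns, size=int(is_bg.sum()))
    return delays


# ---------------------------------------------------------------- MCS


def gen_mcs_scan(
    cluster_concentration_M: float,
    geometry: MCSGeometry | None = None,
    n_positions: int | None = None,
    seed: int = 0,
    background_mean: float = 50.0,
    peak_amplitude: float = 200.0,
    peak_width_bins: int = 3,
    bin_width_ms: float = 1.0,
) -> tuple[list[IntensityTrace], int, float]:
    """Simulate one confocal scan: ``n_positions`` traces of Poisson
    background with cluster-transit peaks injected at a Poisson rate that
    inverts the flux/concentration equations.

    The expected peak count per trace is
    lambda = c * N_A * Q_sample * t / (4 h d_step / (pi z w)), i.e. a scan
    generated at concentration c and analysed with
    :func:`precluster.mcs.detect_peaks` + ``flux_and_concentration``
    recovers c in expectation. Returns (traces, total injected peaks,
    lambda per trace)."""
    if cluster_concentration_M < 0:
        raise ValueError("concentration must be non-negative")
    geometry = geometry or MCSGeometry()
    n_positions = n_positions or geometry.n_positions
    q_l_s = geometry.q_sample_ul_h * 1e-6 / 3600.0
    lam = cluster_concentration_M * AVOGADRO * q_l_s * geometry.dwell_s / geometry.geometric_factor
    n_bins = int(round(geometry.dwell_s / (bin_width_ms * 1e-3)))
    rng = np.random.default_rng(seed)
    traces = []
    total_true = 0
    for _ in range(n_positions):
        counts = rng.poisson(background_mean, n_bins).astype(float)
        n_peaks = rng.poisson(lam)
        total_true += int(n_peaks)
        if n_peaks:
            starts = rng.integers(0, n_bins - peak_width_bins, size=n_peaks)
            for s in starts:
                counts[s : s + peak_width_bins] += peak_amplitude
        traces.append(IntensityTrace(np.arange(n_bins) * bin_width_ms * 1e-3, counts, bin_width_ms))
    return traces, total_true, lam


# ---------------------------------------------------------------- melting


@dataclass
class MeltSimSpec:
    """Logistic melting-curve specification: ratio ramps between the two
    baselines with midpoint (deg C) and steepness (1/deg C)."""

    temp_grid_C: np.ndarray = field(default_factory=lambda: np.arange(20.0, 95.0, 0.5))
    midpoint_C: float = 57.0
    # two-state van 't Hoff transition with dH ~ 400 kJ/mol at Tm ~ 330 K:
    # d(theta)/dT|Tm = dH/(4 R Tm^2) ~ 0.11 /K, logistic k = 4x that
    steepness: float = 0.44
    baseline_low: float = 0.80
    baseline_high: float = 0.95
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.temp_grid_C = np.asarray(self.temp_grid_C, dtype=float)
        if self.temp_grid_C.size < 5:
            raise ValueError("need at least 5 temperature points")
        if np.any(np.diff(self.temp_grid_C) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if self.baseline_high == self.baseline_low:
            raise ValueError("baselines must differ")


def gen_melting_curve(spec: MeltSimSpec, replicate: str = "") -> MeltingCurve:
    """Simulate a 350/330 fluorescence-ratio melting curve: a logistic
    sigmoid between the baselines, inflection at the midpoint, plus
    Gaussian noise."""
    t = spec.temp_grid_C
    sigmoid = 1.0 / (1.0 + np.exp(-spec.steepness * (t - spec.midpoint_C)))
    ratio = spec.baseline_low + (spec.baseline_high - spec.baseline_low) * sigmoid
    rng = np.random.default_rng(spec.seed)
    ratio = ratio + rng.normal(0.0, spec.noise_sd, t.size) if spec.noise_sd > 0 else ratio
    return MeltingCurve(t, ratio, replicate)
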