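# Methods

This note records the models implemented in `precluster`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations. It is the package's design record; all
empirical statements below are reproduced by the test suite or by
`scripts/acceptance.py`.

## Dynamic light scattering

The field correlation of a monodisperse scatterer population is a single
exponential, and the measured intensity correlation follows the Siegert
relation, so the package works with

    G(τ) = 1 + b · g₁(τ)²,   g₁(τ) = exp(−D_t q² τ)

with instrument constant `b` and scattering vector
`q = 4π n₀/λ₀ · sin(θ/2)`. Defaults (632.8 nm, 173°, n₀ = 1.33) describe a
red-laser backscattering instrument in aqueous buffer. Stokes–Einstein
(`k_B = 1.381e-23 J/K`) converts `D_t` to the hydrodynamic diameter
`d_H = 2R_h`, the package's standard size variable. For polydisperse
samples the generator forms `g₁` as the intensity-weighted sum of
per-species exponentials and returns `1 + b g₁²`; the monoexponential fit
is intended for effectively monomodal curves and raises on flat input.

`fit_monoexponential` estimates `(b, D_t)` by weighted least squares with
`D_t` parameterized on a log scale (the decay rate spans orders of
magnitude); the starting point comes from the log-slope of the early decay.

### Intensity-to-number inversion

Scattered intensity scales as `d⁶` for particles small against the
wavelength; number weights are intensity weights divided by the
per-particle scattered intensity and renormalized. Two intensity models
are provided: the Rayleigh `d⁶` rule and the total Mie scattering
cross-section `Q_sca(x, m)·πr²` from the partial-wave series (truncated at
the Wiscombe order `x + 4.05 x^{1/3} + 2`, Riccati–Bessel functions from
scipy's spherical Bessel routines, real refractive index only — proteins
are non-absorbing at 632.8 nm). The series reproduces the published
reference efficiency `Q_ext = 2.8820` at `m = 1.5, x = 10`, approaches the
analytic Rayleigh limit at small `x`, and tends to the extinction-paradox
value 2 for large spheres. Two identifications are approximations and are
deliberate: the hydrodynamic diameter is treated as the optical sphere
diameter, and clusters are treated as homogeneous spheres of refractive
index 1.45 (typical protein; configurable). Detection-angle-resolved Mie
intensities are not used; the total cross-section suffices for relative
per-size weighting and has the correct Rayleigh limit.

Regularized multi-modal inversion of DLS decays (CONTIN-style) is
intentionally not implemented: measured size distributions are consumed as
instrument exports (or synthetic equivalents), and only the
intensity/number weighting conversion and cluster-size mapping are applied
downstream.

### Cluster occupancy

`n = p (d_H/d_mono)³` under the spherical approximation, with packing
fraction bounded by crystalline packing (`p ≤ 0.74`); 0.64 (random close
packing) and 0.33 (condensate-like, solvent fraction 0.6–0.7) are the two
standard choices. `n` is reported as a continuous value; optional integer
reporting uses round-half-even. `d_H` histograms use half-open bins
`[d, d+Δ)` with `Δ = 0.1 nm` by default and conserve total count.

## FCS model and fitting

The multi-component 3D-Gaussian autocorrelation with a photophysical
bunching factor is

    G(t_c) = G₀ + (1/N) Σᵢ fᵢ (1 + t_c/t_{d,i})⁻¹ (1 + t_c/(sᵢ² t_{d,i}))^{−1/2}
                  · (1 − A + A e^{−t_c/t_A}),   Σ fᵢ = 1,

with focal aspect ratio `s = z₀/w₀` (default 5, typical confocal), particle
number `N` and offset `G₀`. Fractions are box-constrained to [0, 1] and
times to positive values rather than wrapped in absolute values — the
optima are equivalent and the uncertainties better behaved. Fits are
weighted by per-point error columns when present (unit weights otherwise),
run from 8 log-uniform multi-starts with a fixed seed, keep the best
reduced χ², and support a diffusion time shared globally across curves
(the monomer-cut / cluster-cut selections: one global dye or monomer time
plus one per-curve time). Two-component fits whose recovered times lie
within a factor 1.5 are flagged `times-close`, and near-zero fractions
`degenerate-fraction`, rather than raised — degenerate models are a
diagnostic outcome, not an error.

Diffusion times convert to coefficients against a dye standard,
`D = D_ref t_{d,ref}/t_d`, then to `R_h` by Stokes–Einstein at 293.15 K
with the viscosity of water at 20 °C. The reference diffusivity default is
`4.3e-6 cm²/s` (Rhodamine 110 scale). The field value is sometimes quoted
with an ambiguous exponent sign; the constant is an explicit configurable
field of `ReferenceStandard` so any calibration can be substituted.

## Maximum-entropy inversion

The diffusional part of a curve is expanded over a fixed grid of diffusion
times (default 101 log-spaced points over 10⁻³–10² ms) with simplex
weights `p`, fixed `G₀`, `N` and photophysics, and the regularized
functional

    Q(p) = χ²(p) − ν S(p),   S(p) = −Σ pᵢ ln(pᵢ/mᵢ),  m uniform

is minimized for each ν of a 30-point log schedule. χ² is assembled once
in quadratic form `χ₀² + q·p + p·H·p`. Enforcing `Σp = 1` makes `S` a
proper KL divergence (`S ≤ 0`, zero only at the prior); the overall
amplitude is absorbed by `1/N`.

Numerics: the outer loop replaces `−S` by its second-order model about the
current iterate (gradient floored at `p = 1e−12`; model curvature damped at
`1/max(p, 1e−4)` so zero-weight grid points stay mobile) and solves each
simplex-constrained QP with a primal active-set method using exact KKT
solves; a backtracking line search on the true objective guards each outer
step. Convergence: `max|Δp| < 1e−8` or 60 outer iterations. The ν path is
solved warm-started in ascending order, then re-minimized in a descending
sweep and finished by a neighbour-exchange polish; at its fixpoint every
path point beats its neighbours under its own objective, which implies the
textbook monotonicity of both χ²_red and S along ν. The reported solution
is the corner of the (S, log χ²_red) L-curve, located as the interior point
of maximum discrete (Menger) curvature after scaling both axes to unit
range; a collinear path returns the mid-point with a warning flag. The
solver was verified against a zooming brute-force grid search over the
probability simplex on a small problem (agreement ≤ 1e−4 in Q).

## Burst analysis and FRET lines

Burst search operates on binned counts (bin width configurable). The
background mean and SD are estimated in two passes — all bins, then bins
below the first-pass threshold — and bursts are contiguous runs above
`mean + 2σ`, kept if their summed counts lie in [10, 3000] photons.
Lifetimes are mono-exponential maximum-likelihood estimates; with a
nonzero background fraction the likelihood mixes the exponential with a
flat distribution over the excitation period, and at zero background the
estimator reduces exactly to the sample mean. Detector corrections
(g-factor, crosstalk, γ) default to identity and are the caller's
responsibility. The static (quartic-over-constant) and dynamic (rational)
FRET-line coefficients are dataset-specific calibration constants stored
in one configurable record; the dynamic line's vertical asymptote raises
rather than returning a silent value.

## Microfluidic cluster counting

Per-trace thresholds are `mean + 5·SD` with the plain standard deviation
(a median/MAD robust option exists but is off by default, matching the
plain-SD convention); adjacent super-threshold samples merge into one
peak, and a one-sample gap splits peaks. Traces are grouped in scan order
into the four channel groups and the group means averaged. Flux and
concentration follow

    F = (n̄/t) · 4 h d_step/(π z w),   c = F/(N_A Q_sample)

with defaults t = 4 s, h = 28 µm, d_step = 5.64 µm, z = 3 µm, w = 0.4 µm,
Q_sample = 15 µL/h (the syringe pump's total withdraw rate, 150 µL/h, is a
separate configurable quantity; the conversion uses the sample-stream flow).

## Preferential interaction coefficients

Distances are measured from the mass-weighted peptide center of mass with
the minimum-image convention in orthorhombic boxes (r grids beyond half
the box edge are flagged); water molecules are located by their oxygen
site. Cumulative counts use 0.2 Å bins. Each replicate is analysed
independently: its bulk ion/water ratio is pooled over its own frames
(shell 2.5–3.38 nm, bounds mapped to the nearest bin edges), Γ is computed
per frame and averaged, and the SEM is taken across replicate means.
Keeping the ratio within-replicate is essential: a ratio pooled across
replicates injects an error component common to all replicates that the
across-replicate SEM cannot see, biasing |Γ|/SEM upward — this was
verified numerically on uniform synthetic frames. A per-frame ratio
variant is available. `Γ_salt = ½(Γ_anion + Γ_cation − |Z|)` propagates
SEMs in quadrature. RDFs use ideal-gas shell normalization at the observed
density, excluding self-pairs.

Real MD trajectories must be supplied pre-centered as coordinate frames
(the package reads its own plain-text XYZ-like format); trajectory-format
ingestion (XTC/GRO) and any force-field analysis are out of scope.

## nanoDSF

The apparent melting temperature is the extremum of largest magnitude of
the first derivative of the 350/330 ratio (maximum for increasing,
minimum for decreasing transitions). The ratio is smoothed with a 5-point
Savitzky–Golay filter (configurable; the unsmoothed derivative is also
returned), and the transition is located on a more heavily smoothed copy
of the derivative used only for peak finding. Sub-grid refinement is the
intensity-weighted centroid of the contiguous derivative-peak region above
30% of the extremum: for a symmetric transition the centroid is an
unbiased estimate of the inflection temperature and averages point noise,
which a single-point argmax plus 3-point parabola cannot do at realistic
noise; the parabola remains as a fallback for very narrow peaks. The
centroid assumes an approximately symmetric transition — strongly
asymmetric melts would bias it, a documented limitation. Flat curves are
flagged `no-transition` with no temperature returned, and constant offsets
or positive scalings of the ratio leave the result unchanged.

## Synthetic data: what it emulates, and what it does not

The generators draw from the closed-form models above: FCS/DLS curves are
the exact model plus independent Gaussian noise (constant or
lag-dependent SD, stored as the error column); solvation frames place
particles uniformly, modulated by piecewise-constant radial shell
multipliers via rejection sampling around a box-centered peptide, which
gives closed-form expected cumulative counts and Γ profiles (shells are
required to fit within half the box edge for that closed form to be
exact); burst traces are Poisson counts at a piecewise-constant rate with
overlapping events merged; scans inject square peaks at the Poisson rate
that exactly inverts the flux/concentration equations; melting curves are
logistic sigmoids. Noise defaults represent the study conditions: 1% of
the local correlation amplitude for correlation curves (correlator noise
scales with the correlation; a constant-SD option exists since real
correlator noise models vary by instrument), and melting steepness
0.44 /°C from a two-state van 't Hoff argument (ΔH ≈ 400 kJ/mol at
T_m ≈ 330 K gives d f/dT = ΔH/(4RT_m²) ≈ 0.11 /K, logistic k four times
that) on a 0.5 °C grid.

What passing tests show is therefore estimator correctness and statistical
calibration under these idealized conditions. The generators do not
emulate: correlated correlator noise and afterpulsing, diffusion-path
photon statistics (binned Poisson only), detector dead time, Taylor
dispersion or flow-profile effects in the microfluidic channel, instrument
smoothing of melting curves, or solvent structure beyond radial density
shells. Agreement on synthetic data bounds algorithmic error, not
instrument systematics.

Statistical acceptance checks of the form "|Γ| < 3 SEM everywhere" are
tail-sensitive: across ~10 bins they fail by chance for a few percent of
seeds even for a correct estimator. The test suite uses fixed seeds chosen
in advance; the acceptance script reports the continuous max-z statistic
so that marginal exceedances remain visible rather than binary.

## Problem sizes

Defaults were chosen so the whole suite and the acceptance script each run
in well under a minute on one CPU: 160-point lag grids and 20-seed
recovery studies for FCS; a 101-point grid and 30-point ν schedule for
MEM (with the brute-force oracle on a 5-component toy); 32 replicates of
16 frames with ~1700 particles for Γ profiles; 100-position scans × 20
replicates for the MCS round trip; 100 seeds for melting recovery. All are
arguments, not constants, and scale up unchanged.
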