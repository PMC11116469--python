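# precluster

Quantitative analysis of **pre-percolation protein clusters** — the rare,
finite multi-molecule assemblies that phase-separating proteins such as FUS
form in sub-saturated solution, below the saturation concentration at which
macroscopic condensates appear. Detecting and sizing these clusters requires
stitching together several biophysical measurements, each with its own
inversion problem. This package implements that analysis chain as a tested
Python library for biophysicists working with light scattering, fluorescence
correlation, single-molecule fluorescence, microfluidic particle counting,
MD solvation frames and thermal-stability ramps.

## What it computes

**Dynamic light scattering (`precluster.dls`, `precluster.mie`).**
The intensity autocorrelation of a monodisperse scatterer decays as
`G(τ) = 1 + b·exp(−2 D_t q² τ)` with scattering vector
`q = 4π n₀/λ₀ · sin(θ/2)`; Stokes–Einstein,
`D_t = k_B T / (6π η R_h)`, converts decay rates into hydrodynamic
diameters `d_H = 2R_h`. Because scattered intensity grows as `d⁶` (Rayleigh)
— or, for larger spheres, as the full Mie cross-section computed from the
partial-wave series — intensity-weighted size distributions are inverted to
number weights before interpretation. Cluster occupancies follow the
spherical packing model `n = p·(d_H/d_mono)³` with packing fraction
`p ∈ (0, 0.74]` (0.64 random close packing, 0.33 condensate-like).

**FCS fitting and maximum-entropy inversion (`precluster.fcs`,
`precluster.mem`).** Autocorrelation curves are fit with the 3D-Gaussian
multi-component model

    G(t_c) = G₀ + (1/N) · Σᵢ fᵢ (1 + t_c/t_{d,i})⁻¹ (1 + t_c/(s² t_{d,i}))^(−1/2)
                   · (1 − A + A e^(−t_c/t_A))

including a photophysical bunching term, with optional diffusion times
shared globally across curves. Beyond the two-species assumption, the
maximum-entropy method solves for a full diffusion-time distribution *p* on
a 101-point log grid by minimizing `Q(p) = χ²(p) − ν S(p)` over the
probability simplex, where `S(p) = −Σ pᵢ ln(pᵢ/mᵢ)` is the Kullback–Leibler
entropy against a uniform prior. Each subproblem is a convex quadratic
program solved exactly by an active-set method; ν is chosen at the corner of
the (S, log χ²_red) L-curve. Fitted times convert to sizes against a dye
reference: `D = D_ref · t_{d,ref}/t_d`, then Stokes–Einstein.

**Single-molecule bursts and FRET lines (`precluster.bursts`).** Bursts are
selected from binned photon traces by the 2σ-above-background rule with a
10-photon minimum and 3000-photon maximum; per-burst lifetimes come from a
mono-exponential maximum-likelihood fit with a flat background mixture. The
static and dynamic FRET reference lines map donor lifetime to FRET
efficiency for E-vs-τ burst histograms.

**Microfluidic confocal counting (`precluster.mcs`).** Peaks exceeding
5 SD above the per-trace mean count cluster transits; the mean count per
trace converts to a flux `F = (n̄/t)·4 h d_step/(π z w)` and a molar
concentration `c = F/(N_A Q_sample)` — femtomolar sensitivity.

**Preferential interaction coefficients (`precluster.interaction`).** From
particle coordinate frames, `Γ_ion(r) = N_ion(r) − N_H₂O(r)·(N_ion/N_H₂O)_bulk`
quantifies accumulation (Γ>0) or exclusion (Γ<0) of ions around a peptide,
with the bulk ratio taken from a 2.5–3.38 nm shell, SEM over replicates, and
`Γ_salt = ½(Γ_anion + Γ_cation − |Z|)`. Radial distribution functions use
minimum-image distances in orthorhombic boxes.

**nanoDSF melting analysis (`precluster.melting`).** Apparent melting
temperatures are the first-derivative extremum of the 350/330 nm
fluorescence ratio, with Savitzky–Golay smoothing and sub-grid peak
refinement.

**Synthetic data (`precluster.synthetic`).** Every input the pipeline
consumes can be generated with known ground truth — multi-component FCS
curves, polydisperse DLS correlations, solvation frames with prescribed
accumulation/depletion shells (and closed-form expected Γ), Poisson burst
traces, cluster-transit scans and sigmoidal melting curves — all
bitwise-reproducible under a fixed seed.

## Worked example

```bash
python examples/fcs_two_component_fit.py
```

```
true diffusion times : 0.200 ms / 2.000 ms, fast fraction 0.70
fitted diffusion times: 0.197 ms / 1.994 ms
fitted fast fraction  : 0.698
fitted particle number: 1.998 (true 2.0)
reduced chi-square    : 0.752
```

A monomer/cluster mixture (70% at 0.2 ms, 30% at 2.0 ms, noise 1% of the
local correlation amplitude) is recovered to within 2% in both diffusion
times; χ²_red ≈ 1 confirms the noise model. The companion script
`examples/mem_diffusion_spectrum.py` inverts the same curve without assuming
two species and finds a bimodal distribution peaked at 0.178 and 2.239 ms —
each within one grid step of the truth:

```
regularization nu at L-curve corner: 85.32 (chi2_red 0.889)
distribution peaks at: 0.178 ms, 2.239 ms
```

`examples/dls_cluster_sizes.py` completes the chain from correlation decay
to cluster occupancy: a 9.2 nm assembly of 4.6 nm monomers at random close
packing contains `n = 0.64·(9.2/4.6)³ = 5.12` molecules, and a 46 nm cluster
at condensate-like packing contains 330. One script per capability lives in
`examples/`.

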