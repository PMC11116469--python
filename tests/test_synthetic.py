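"""Generator contracts: seeded determinism, noiseless output equal to the
closed-form models, and the statistical properties the downstream
estimators rely on."""

import numpy as np
import pytest

from precluster import DLSInstrument, SizeDistribution
from precluster.dls import scattering_vector, stokes_einstein
from precluster.mcs import MCSGeometry, AVOGADRO
from precluster.synthetic import (
    FcsSimSpec,
    MeltSimSpec,
    ParticleFrameSpec,
    eval_dls_model,
    gen_burst_trace,
    gen_dls_curve,
    gen_fcs_curve,
    gen_mcs_scan,
    gen_melting_curve,
    gen_particle_frames,
)


class TestGenFcsCurve:
    def test_lag_to_zero_limit_is_g0_plus_inv_n(self):
        spec = FcsSimSpec(
            components=[(1.0, 0.5)], n_particles=4.0, offset=0.3,
            lag_grid_ms=np.array([1e-9, 1.0]),
        )
        curve = gen_fcs_curve(spec)
        assert curve.values[0] == pytest.approx(0.3 + 0.25, rel=1e-6)

    def test_lag_to_infinity_limit_is_g0(self):
        spec = FcsSimSpec(
            components=[(1.0, 0.5)], n_particles=4.0, offset=0.3,
            lag_grid_ms=np.array([1.0, 1e9]),
        )
        curve = gen_fcs_curve(spec)
        assert curve.values[-1] == pytest.approx(0.3, abs=1e-6)

    def test_seeded_determinism(self):
        spec = lambda: FcsSimSpec(
            components=[(0.5, 0.2), (0.5, 2.0)], noise_sd=0.01, seed=7
        )
        c1, c2 = gen_fcs_curve(spec()), gen_fcs_curve(spec())
        np.testing.assert_array_equal(c1.values, c2.values)

    def test_error_column_equals_noise_sd(self):
        spec = FcsSimSpec(components=[(1.0, 0.5)], noise_sd=0.02, seed=1)
        assert np.all(gen_fcs_curve(spec).errors == 0.02)

    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FcsSimSpec(components=[(0.5, 0.2), (0.4, 2.0)])

    def test_non_increasing_lag_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            FcsSimSpec(components=[(1.0, 0.5)], lag_grid_ms=np.array([1.0, 1.0]))


class TestGenDlsCurve:
    def test_value_at_zero_lag_is_one_plus_b(self, instrument):
        delta = SizeDistribution([10.0], [1.0], weighting="number")
        val = eval_dls_model(np.array([0.0]), delta, instrument, b=1.0)
        assert val[0] == pytest.approx(2.0, rel=1e-14)

    def test_monodisperse_decay_rate_is_2dq2(self, instrument):
        # log-slope of G-1 must equal -2 D q^2 exactly for a single size
        delta = SizeDistribution([10.0], [1.0], weighting="number")
        tau = np.array([0.05, 0.1])  # ms
        g = eval_dls_model(tau, delta, instrument, b=0.8)
        slope = (np.log(g[1] - 1.0) - np.log(g[0] - 1.0)) / ((tau[1] - tau[0]) * 1e-3)
        q = scattering_vector(instrument) * 1e9
        d = stokes_einstein(instrument, 10.0)
        assert slope == pytest.approx(-2.0 * d * q**2, rel=1e-12)

    def test_bimodal_matches_brute_force_sum(self, instrument):
        dist = SizeDistribution([8.0, 40.0], [0.9, 0.1], weighting="number")
        tau = np.logspace(-3, 2, 40)
        g = eval_dls_model(tau, dist, instrument, b=0.7)
        # brute force: per-size intensity weights d^6, field sum of exponentials
        w = dist.weights * dist.d_h**6
        w = w / w.sum()
        q = scattering_vector(instrument) * 1e9
        g1 = np.zeros_like(tau)
        for wi, di in zip(w, dist.d_h):
            g1 += wi * np.exp(-stokes_einstein(instrument, di) * q**2 * tau * 1e-3)
        np.testing.assert_allclose(g, 1.0 + 0.7 * g1**2, rtol=1e-12)

    def test_seeded_determinism_and_kind(self, instrument):
        dist = SizeDistribution([10.0], [1.0], weighting="number")
        c1 = gen_dls_curve(dist, instrument, noise_sd=0.01, seed=3)
        c2 = gen_dls_curve(dist, instrument, noise_sd=0.01, seed=3)
        np.testing.assert_array_equal(c1.values, c2.values)
        assert c1.kind == "intensity"

    def test_intensity_weighted_input_rejected(self, instrument):
        dist = SizeDistribution([10.0], [1.0], weighting="intensity")
        with pytest.raises(ValueError, match="number-weighted"):
            gen_dls_curve(dist, instrument)

    def test_non_positive_b_rejected(self, instrument):
        dist = SizeDistribution([10.0], [1.0], weighting="number")
        with pytest.raises(ValueError, match="b must be positive"):
            gen_dls_curve(dist, instrument, b=0.0)


class TestGenParticleFrames:
    def test_counts_match_spec_and_determinism(self):
        spec = ParticleFrameSpec(n_anion=20, n_cation=25, n_water=100, n_frames=3, seed=9)
        fs1, fs2 = gen_particle_frames(spec), gen_particle_frames(spec)
        for f in fs1.replicates["rep0"]:
            assert f.anion_xyz.shape == (20, 3)
            assert f.cation_xyz.shape == (25, 3)
            assert f.water_xyz.shape == (100, 3)
        np.testing.assert_array_equal(
            fs1.replicates["rep0"][0].water_xyz, fs2.replicates["rep0"][0].water_xyz
        )

    def test_uniform_profile_gives_zero_analytic_gamma(self):
        spec = ParticleFrameSpec(n_frames=1)
        r = np.linspace(0.1, 3.4, 50)
        np.testing.assert_allclose(spec.expected_gamma("anion", r), 0.0, atol=1e-10)

    def test_depleted_shell_analytic_gamma(self):
        # anion-free shell 0-1 nm: Gamma(1 nm) = -(expected waters in 1 nm) * bulk ratio
        spec = ParticleFrameSpec(
            n_anion=60, n_water=2000, density_profile={"anion": [(0.0, 1.0, 0.0)]}
        )
        gamma_1nm = spec.expected_gamma("anion", np.array([1.0]))[0]
        waters_1nm = spec.expected_cumulative("water", np.array([1.0]))[0]
        lo, hi = 2.5, 3.38
        ratio = (
            spec.expected_cumulative("anion", np.array([hi]))[0]
            - spec.expected_cumulative("anion", np.array([lo]))[0]
        ) / (
            spec.expected_cumulative("water", np.array([hi]))[0]
            - spec.expected_cumulative("water", np.array([lo]))[0]
        )
        assert gamma_1nm < 0
        assert gamma_1nm == pytest.approx(-waters_1nm * ratio, rel=1e-12)

    def test_overlapping_shells_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            ParticleFrameSpec(density_profile={"anion": [(0.0, 1.0, 0.0), (0.5, 2.0, 2.0)]})

    def test_shell_density_converges_to_multiplier(self):
        # empirical density in an enriched shell approaches bulk x multiplier
        mult = 3.0
        errors = []
        for n_frames in (10, 100, 1000):
            spec = ParticleFrameSpec(
                n_anion=50, n_cation=1, n_water=1,
                density_profile={"anion": [(1.0, 2.0, mult)]},
                n_frames=n_frames, seed=21,
            )
            fs = gen_particle_frames(spec)
            expected = spec.expected_cumulative("anion", np.array([1.0, 2.0]))
            got = []
            for f in fs.replicates["rep0"]:
                d = np.linalg.norm(f.anion_xyz - f.box / 2, axis=1)
                got.append(np.sum((d >= 1.0) & (d < 2.0)))
            errors.append(abs(np.mean(got) - (expected[1] - expected[0])))
        assert errors[2] < errors[0] + 1e-9
        assert errors[2] < 0.5  # converged near the analytic expectation


class TestGenBurstTrace:
    def test_background_poisson_mean(self):
        trace, _ = gen_burst_trace(2.0, [], bin_width_ms=1.0, total_time_s=20.0, seed=4)
        n = len(trace)
        assert n >= 10_000
        se = np.sqrt(2.0 / n)
        assert abs(trace.counts.mean() - 2.0) < 3 * se

    def test_event_exceeds_background_threshold(self):
        trace, truth = gen_burst_trace(
            2.0, [(0.5, 0.005, 50.0)], bin_width_ms=1.0, total_time_s=2.0, seed=8
        )
        inside = (trace.bin_times >= 0.5) & (trace.bin_times < 0.505)
        assert trace.counts[inside].max() > 2.0 + 2 * np.sqrt(2.0)
        assert truth == [(0.5, 0.505, 50.0)]

    def test_overlapping_events_merged(self):
        _, truth = gen_burst_trace(
            1.0, [(0.1, 0.05, 10.0), (0.12, 0.05, 20.0)], total_time_s=1.0, seed=0
        )
        assert len(truth) == 1
        assert truth[0] == (0.1, pytest.approx(0.17), 30.0)

    def test_seeded_determinism(self):
        t1, _ = gen_burst_trace(2.0, [(0.2, 0.01, 30.0)], total_time_s=1.0, seed=11)
        t2, _ = gen_burst_trace(2.0, [(0.2, 0.01, 30.0)], total_time_s=1.0, seed=11)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_event_outside_trace_rejected(self):
        with pytest.raises(ValueError, match="within the trace"):
            gen_burst_trace(1.0, [(0.9, 0.5, 10.0)], total_time_s=1.0)


class TestGenMcsScan:
    def test_zero_concentration_zero_peaks(self):
        traces, n_true, lam = gen_mcs_scan(0.0, MCSGeometry(), n_positions=5, seed=2)
        assert n_true == 0 and lam == 0.0

    def test_rate_inverts_flux_equations(self):
        geom = MCSGeometry()
        c = 2e-14
        _, _, lam = gen_mcs_scan(c, geom, n_positions=1, seed=0)
        q_l_s = geom.q_sample_ul_h * 1e-6 / 3600.0
        assert lam == pytest.approx(c * AVOGADRO * q_l_s * geom.dwell_s / geom.geometric_factor)

    def test_doubling_concentration_doubles_rate(self):
        _, _, lam1 = gen_mcs_scan(1e-14, n_positions=1, seed=0)
        _, _, lam2 = gen_mcs_scan(2e-14, n_positions=1, seed=0)
        assert lam2 == pytest.approx(2 * lam1)


class TestGenMeltingCurve:
    def test_noiseless_inflection_at_midpoint(self):
        spec = MeltSimSpec(
            temp_grid_C=np.arange(30.0, 90.0, 0.1), midpoint_C=60.0, noise_sd=0.0
        )
        curve = gen_melting_curve(spec)
        deriv = np.gradient(curve.ratio, curve.temperature)
        assert curve.temperature[np.argmax(deriv)] == pytest.approx(60.0, abs=0.1)

    def test_swapped_baselines_decreasing(self):
        spec = MeltSimSpec(baseline_low=0.95, baseline_high=0.80, noise_sd=0.0)
        curve = gen_melting_curve(spec)
        assert curve.ratio[0] > curve.ratio[-1]

    def test_seeded_determinism(self):
        c1 = gen_melting_curve(MeltSimSpec(noise_sd=0.01, seed=5))
        c2 = gen_melting_curve(MeltSimSpec(noise_sd=0.01, seed=5))
        np.testing.assert_array_equal(c1.ratio, c2.ratio)

    def test_equal_baselines_rejected(self):
        with pytest.raises(ValueError, match="baselines"):
            MeltSimSpec(baseline_low=0.9, baseline_high=0.9)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError, match="5"):
            MeltSimSpec(temp_grid_C=np.array([20.0, 30.0, 40.0, 50.0]))
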