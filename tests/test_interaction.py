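"""Preferential interaction coefficients and radial distribution
functions, checked against closed forms and brute-force loops."""

import numpy as np
import pytest

from precluster.containers import Frame, TrajectoryFrameSet
from precluster.interaction import (
    GammaProfile,
    gamma_ion_profile,
    gamma_salt,
    minimum_image_distances,
    radial_counts,
    rdf,
)
from precluster.synthetic import ParticleFrameSpec, gen_particle_frames


def _frame_with(anions, waters, box_edge=6.0, cations=None):
    box = np.full(3, box_edge)
    center = box / 2
    return Frame(
        peptide_xyz=center.reshape(1, 3),
        peptide_masses=np.array([100.0]),
        anion_xyz=np.asarray(anions, float).reshape(-1, 3),
        cation_xyz=np.asarray(cations if cations is not None else np.empty((0, 3)), float).reshape(-1, 3),
        water_xyz=np.asarray(waters, float).reshape(-1, 3),
        box=box,
    )


class TestRadialCounts:
    def test_single_ion_step_at_its_distance(self):
        # one anion 0.5 nm (5 A) from the center
        f = _frame_with([[3.5, 3.0, 3.0]], [[3.0, 3.0, 4.0]])
        fs = TrajectoryFrameSet({"r": [f]})
        r, counts = radial_counts(fs, "anion", bin_A=0.2)
        # half-open bins [lo, hi): 5.0 A lands in the bin with outer edge 5.2
        assert counts[0, r < 5.2 - 1e-9].max() == 0
        assert np.all(counts[0, r >= 5.2 - 1e-9] == 1)

    def test_periodic_image_counted_at_true_distance(self):
        # particle at 0.1 nm across the boundary: image distance 2 A + 1 A
        f = _frame_with([[5.9, 3.0, 3.0]], [[3.0, 3.0, 4.0]], box_edge=6.0)
        f.peptide_xyz = np.array([[0.1, 3.0, 3.0]])  # 0.2 nm min-image gap
        fs = TrajectoryFrameSet({"r": [f]})
        r, counts = radial_counts(fs, "anion", bin_A=0.2)
        first_nonzero = r[np.argmax(counts[0] > 0)]
        assert first_nonzero == pytest.approx(2.0, abs=0.2 + 1e-9)

    def test_uniform_gas_matches_volume_fraction(self):
        spec = ParticleFrameSpec(n_anion=200, n_cation=1, n_water=1, n_frames=200, seed=13)
        fs = gen_particle_frames(spec)
        r, counts = radial_counts(fs, "anion", bin_A=1.0)
        r_nm = r / 10.0
        expected = spec.expected_cumulative("anion", r_nm)
        mean = counts.mean(axis=0)
        se = counts.std(axis=0, ddof=1) / np.sqrt(counts.shape[0])
        inside = r_nm <= spec.box_edge_nm / 2
        # Poisson-based floor on the SE for bins too rare to populate
        se_floor = np.sqrt(expected / counts.shape[0])
        z = np.abs(mean[inside] - expected[inside]) / np.maximum(se[inside], se_floor[inside])
        # cumulative counts are correlated across r: allow one 3-SE outlier
        assert np.mean(z <= 3.0) >= 1.0 - 1.5 / z.size
        assert z.max() <= 4.5

    def test_r_beyond_half_box_warns(self):
        f = _frame_with([[3.5, 3.0, 3.0]], [[3.0, 3.0, 4.0]])
        with pytest.warns(UserWarning, match="half the box"):
            radial_counts(TrajectoryFrameSet({"r": [f]}), "anion", r_max_A=40.0)


class TestGammaProfiles:
    def test_direct_formula_arithmetic(self):
        # N_ion = 10, N_H2O = 1000, bulk ratio 0.02 -> Gamma = 10 - 20 = -10
        assert 10 - 1000 * 0.02 == -10  # the formula the estimator applies

    def test_uniform_frames_gamma_within_noise(self):
        reps = {}
        for k in range(8):
            spec = ParticleFrameSpec(n_anion=80, n_cation=80, n_water=1500, n_frames=10, seed=170 + k)
            reps[f"rep{k}"] = gen_particle_frames(spec).replicates["rep0"]
        prof = gamma_ion_profile(TrajectoryFrameSet(reps), "anion", bin_A=2.5)
        z = np.abs(prof.gamma) / np.maximum(prof.sem, 1e-9)
        assert np.mean(z <= 3.0) >= 0.85
        assert z.max() <= 4.5

    def test_depletion_shell_matches_analytic_truth(self):
        spec = ParticleFrameSpec(
            n_anion=80, n_cation=80, n_water=1500,
            density_profile={"anion": [(0.0, 1.2, 0.0)]},
            n_frames=48, seed=23,
        )
        frames = gen_particle_frames(spec).replicates["rep0"]
        fs = TrajectoryFrameSet({f"rep{k}": frames[12 * k : 12 * (k + 1)] for k in range(4)})
        prof = gamma_ion_profile(fs, "anion", bin_A=1.0)
        truth = spec.expected_gamma("anion", prof.r_A / 10.0)
        inside = prof.r_A <= spec.box_edge_nm / 2 * 10
        miss = np.abs(prof.gamma - truth)[inside] > 3 * np.maximum(prof.sem[inside], 0.3)
        assert miss.mean() < 0.05
        # depletion shows as clearly negative Gamma at the shell edge
        k = np.searchsorted(prof.r_A, 12.0)
        assert prof.gamma[k] < 0

    def test_matches_brute_force_per_frame(self):
        spec = ParticleFrameSpec(n_anion=15, n_cation=15, n_water=60, n_frames=4, seed=31)
        fs = gen_particle_frames(spec)
        prof = gamma_ion_profile(fs, "anion", bin_A=0.2)
        # explicit per-particle loop, same bulk-shell pooled ratio
        frames = fs.replicates["rep0"]
        edges = np.arange(prof.r_A.size + 1) * 0.2  # same construction as the grid
        lo_edge = edges[int(round(25.0 / 0.2))]
        hi_edge = edges[int(round(33.8 / 0.2))]
        shell_ion = shell_wat = 0.0
        dist = {}
        for i, f in enumerate(frames):
            com = f.center_of_mass()
            d_ion = np.array(
                [np.linalg.norm((p - com) - f.box * np.round((p - com) / f.box)) * 10 for p in f.anion_xyz]
            )
            d_wat = np.array(
                [np.linalg.norm((p - com) - f.box * np.round((p - com) / f.box)) * 10 for p in f.water_xyz]
            )
            dist[i] = (d_ion, d_wat)
            shell_ion += np.sum((d_ion >= lo_edge) & (d_ion < hi_edge))
            shell_wat += np.sum((d_wat >= lo_edge) & (d_wat < hi_edge))
        ratio = shell_ion / shell_wat
        gammas = []
        for i in range(len(frames)):
            d_ion, d_wat = dist[i]
            g = [np.sum(d_ion < r) - np.sum(d_wat < r) * ratio for r in edges[1:]]
            gammas.append(g)
        brute = np.mean(gammas, axis=0)
        assert prof.bulk_ratio == pytest.approx(ratio, rel=1e-12)
        np.testing.assert_allclose(prof.gamma, brute, atol=1e-9)

    def test_sem_scales_with_replicates(self):
        # 48 iid replicates, compared as 12 groups of 4 vs 3 groups of 16:
        # the mean SEM ratio approaches sqrt(16/4) = 2 (1.86 after the
        # small-sample bias of the standard deviation); a band excluding 1
        # distinguishes 1/sqrt(n) scaling from no scaling
        all_reps = []
        for k in range(48):
            spec = ParticleFrameSpec(n_anion=40, n_cation=40, n_water=400, n_frames=5, seed=700 + k)
            all_reps.append(gen_particle_frames(spec).replicates["rep0"])

        def mean_sem(group_size):
            sems = []
            for g in range(48 // group_size):
                reps = {
                    f"r{j}": all_reps[g * group_size + j] for j in range(group_size)
                }
                prof = gamma_ion_profile(TrajectoryFrameSet(reps), "anion", bin_A=2.0)
                sems.append(prof.sem[5:])
            return np.mean(sems)

        ratio = mean_sem(4) / mean_sem(16)
        assert 1.3 < ratio < 2.7

    def test_empty_bulk_shell_rejected(self):
        f = _frame_with([[3.5, 3.0, 3.0]], [[3.0, 3.0, 3.2]])
        with pytest.raises(ValueError, match="no water"):
            gamma_ion_profile(TrajectoryFrameSet({"r": [f]}), "anion")


class TestGammaSalt:
    def _profile(self, gamma, sem=None):
        r = np.arange(1.0, 4.0)
        g = np.full(3, float(gamma))
        s = np.full(3, 0.0 if sem is None else sem)
        return GammaProfile(r_A=r, gamma=g, sem=s, bulk_ratio=0.02, species="anion")

    def test_substitution(self):
        out = gamma_salt(self._profile(-3.0), self._profile(1.0), net_charge=2.0)
        np.testing.assert_allclose(out.gamma, -2.0)

    def test_zero_case(self):
        out = gamma_salt(self._profile(0.0), self._profile(0.0), net_charge=0.0)
        np.testing.assert_allclose(out.gamma, 0.0)

    def test_label_swap_symmetry(self):
        a, c = self._profile(-3.0), self._profile(1.0)
        np.testing.assert_allclose(
            gamma_salt(a, c, 2.0).gamma, gamma_salt(c, a, -2.0).gamma
        )

    def test_sem_quadrature(self):
        out = gamma_salt(self._profile(0.0, 0.3), self._profile(0.0, 0.4), 0.0)
        np.testing.assert_allclose(out.sem, 0.5 * 0.5)

    def test_grid_mismatch_rejected(self):
        a = self._profile(0.0)
        b = GammaProfile(r_A=np.arange(2.0, 5.0), gamma=np.zeros(3), sem=np.zeros(3),
                         bulk_ratio=0.02, species="cation")
        with pytest.raises(ValueError, match="grid"):
            gamma_salt(a, b, 0.0)


class TestRdf:
    def test_uniform_gas_near_unity(self):
        spec = ParticleFrameSpec(n_anion=120, n_cation=120, n_water=1, n_frames=30, seed=41)
        fs = gen_particle_frames(spec)
        r, g = rdf(fs, "anion", "cation", bin_A=2.0)
        inner = (r > 5.0) & (r < 28.0)
        assert abs(np.mean(g[inner]) - 1.0) < 0.05
        assert np.all(np.abs(g[inner] - 1.0) < 0.5)

    def test_self_pairs_excluded_same_species(self):
        spec = ParticleFrameSpec(n_anion=100, n_cation=1, n_water=1, n_frames=30, seed=43)
        fs = gen_particle_frames(spec)
        r, g = rdf(fs, "anion", "anion", bin_A=2.0)
        inner = (r > 5.0) & (r < 28.0)
        assert abs(np.mean(g[inner]) - 1.0) < 0.06

    def test_exclusion_zone_zero(self):
        # waters kept away from the central anion by construction
        rng = np.random.default_rng(7)
        waters = []
        while len(waters) < 200:
            p = rng.uniform(0, 6.0, 3)
            if np.linalg.norm(p - 3.0) > 1.0:
                waters.append(p)
        f = _frame_with([[3.0, 3.0, 3.0]], waters)
        r, g = rdf(TrajectoryFrameSet({"r": [f]}), "anion", "water", bin_A=1.0)
        assert np.all(g[r < 9.5] == 0)

    def test_matches_brute_force_double_loop(self):
        spec = ParticleFrameSpec(n_anion=25, n_cation=25, n_water=1, n_frames=2, seed=47)
        fs = gen_particle_frames(spec)
        r, g = rdf(fs, "anion", "cation", bin_A=1.0)
        edges = np.arange(r.size + 1) * 1.0
        counts = np.zeros(r.size)
        norm = 0.0
        for f in fs.all_frames:
            for a in f.anion_xyz:
                for c in f.cation_xyz:
                    d = a - c
                    d -= f.box * np.round(d / f.box)
                    dd = np.linalg.norm(d) * 10
                    k = int(dd // 1.0)
                    if k < counts.size:
                        counts[k] += 1
            norm += 25 * 25 / (np.prod(f.box) * 1e3)
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        brute = np.where(shell * norm > 0, counts / (shell * norm), 0.0)
        np.testing.assert_allclose(g, brute, rtol=1e-9)

    def test_empty_selection_rejected(self):
        f = _frame_with([[3.0, 3.0, 3.0]], np.empty((0, 3)))
        with pytest.raises(ValueError, match="empty"):
            rdf(TrajectoryFrameSet({"r": [f]}), "anion", "water")


def test_minimum_image_distance_wraps():
    box = np.full(3, 10.0)
    d = minimum_image_distances(np.array([[9.5, 0.0, 0.0]]), np.array([0.5, 0.0, 0.0]), box)
    assert d[0] == pytest.approx(1.0)
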