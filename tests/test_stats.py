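"""Two-sample GLM, smoothness estimation, FWE thresholds, cluster reporting."""

import numpy as np
import pytest
from scipy import integrate, ndimage
from scipy import stats as sps

from ratpet.phantom import PhantomSpec, make_cohort, make_ground_truth
from ratpet.stats import (
    DesignMatrix,
    SmoothnessEstimate,
    StatResult,
    cluster_table,
    estimate_smoothness,
    expected_euler_characteristic,
    fit_two_sample_t,
    fwe_threshold,
    permutation_max_t,
    proportional_scaling,
    t_to_z,
    two_sample_analysis,
)
from ratpet.volume import Volume


def _vols(arrays, vs=(1, 1, 1)):
    return [Volume(np.asarray(a, float), vs) for a in arrays]


def _ones_mask(shape, vs=(1, 1, 1)):
    return Volume(np.ones(shape), vs)


class TestDesignMatrix:
    def test_two_group_construction(self):
        d = DesignMatrix.two_group(3, 2)
        assert d.matrix.shape == (5, 2)
        assert d.matrix[:, 0].sum() == 3

    def test_contrast_must_sum_to_zero(self):
        with pytest.raises(ValueError):
            DesignMatrix(np.eye(2), contrast=(1.0, 1.0))

    def test_single_group_membership(self):
        bad = np.ones((3, 2))
        with pytest.raises(ValueError):
            DesignMatrix(bad)


class TestProportionalScaling:
    def test_already_at_grand_mean(self):
        v = _vols([np.full((3, 3, 3), 50.0)])
        out = proportional_scaling(v, _ones_mask((3, 3, 3)))
        np.testing.assert_array_equal(out[0].data, 50.0)

    def test_halving(self):
        v = _vols([np.full((3, 3, 3), 100.0)])
        out = proportional_scaling(v, _ones_mask((3, 3, 3)), grand_mean=50.0)
        np.testing.assert_array_equal(out[0].data, 50.0)

    def test_random_global_factors_removed(self, rng):
        base = rng.random((4, 4, 4)) + 1.0
        scans = _vols([base * f for f in (0.3, 1.7, 9.2)])
        mask = _ones_mask((4, 4, 4))
        out = proportional_scaling(scans, mask, grand_mean=50.0)
        means = [v.data.mean() for v in out]
        np.testing.assert_allclose(means, 50.0, atol=1e-9)

    def test_zero_mean_scan_rejected(self):
        scans = _vols([np.zeros((2, 2, 2))])
        with pytest.raises(ValueError, match="scan 0"):
            proportional_scaling(scans, _ones_mask((2, 2, 2)))


class TestTwoSampleT:
    def test_identical_groups_give_zero(self, rng):
        a = _vols([rng.random((4, 4, 4)) for _ in range(3)])
        b = [v.copy() for v in a]
        res = fit_two_sample_t(a, b, _ones_mask((4, 4, 4)))
        np.testing.assert_allclose(res.tmap.data[res.valid_mask], 0.0, atol=1e-10)

    def test_hand_computed_toy_voxel(self):
        """A={1,2,3}, B={4,5,6} at one voxel: pooled t = -3.674, df = 4."""
        shape = (1, 1, 1)
        a = _vols([np.full(shape, v) for v in (1.0, 2.0, 3.0)])
        b = _vols([np.full(shape, v) for v in (4.0, 5.0, 6.0)])
        res = fit_two_sample_t(a, b, _ones_mask(shape))
        assert res.df == 4
        # oracle: t = (1-2=-3) / sqrt(s_p^2 (1/3+1/3)), s_p^2 = 1
        assert res.tmap.data[0, 0, 0] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-9)
        assert res.tmap.data[0, 0, 0] == pytest.approx(-3.674, abs=1e-3)

    def test_zero_variance_voxels_excluded(self):
        shape = (2, 1, 1)
        a = _vols([np.array([[[1.0]], [[5.0]]]) for _ in range(2)])
        b = _vols([np.array([[[1.0]], [[6.0]]]) for _ in range(2)])
        res = fit_two_sample_t(a, b, _ones_mask(shape))
        assert not res.valid_mask[0, 0, 0]  # constant voxel
        assert res.valid_mask[1, 0, 0] is not None

    def test_sign_flips_with_group_swap(self, rng):
        a = _vols([rng.random((3, 3, 3)) for _ in range(3)])
        b = _vols([rng.random((3, 3, 3)) for _ in range(3)])
        mask = _ones_mask((3, 3, 3))
        ab = fit_two_sample_t(a, b, mask)
        ba = fit_two_sample_t(b, a, mask)
        np.testing.assert_allclose(ab.tmap.data, -ba.tmap.data, atol=1e-12)

    def test_minimum_group_size(self, rng):
        a = _vols([rng.random((2, 2, 2))])
        b = _vols([rng.random((2, 2, 2)) for _ in range(2)])
        with pytest.raises(ValueError):
            fit_two_sample_t(a, b, _ones_mask((2, 2, 2)))

    def test_peak_inside_injected_deficit(self):
        """Seeded 9v8 cohort with a 20% left-territory deficit: peak |t| in territory."""
        spec = PhantomSpec(dims=(40, 32, 26), effect_fraction=0.0).normalized()
        ga, gb, gt = make_cohort(spec, 9, 8, effect_in_a=-0.2, seed=77)
        res = two_sample_analysis(
            [s.volume for s in ga], [s.volume for s in gb], gt.brain_mask,
            contrast="A<B", extent=0,
        )
        # A<B contrast: t = B - A is largest where A is depressed
        idx = np.unravel_index(
            np.argmax(np.where(res.valid_mask, res.tmap.data, -np.inf)), res.tmap.shape
        )
        territory = ndimage.binary_dilation(gt.territory.data > 0, iterations=2)
        assert territory[idx]


class TestTToZ:
    def test_zero_maps_to_zero(self):
        for df in (1, 5, 50):
            assert t_to_z(0.0, df) == pytest.approx(0.0, abs=1e-12)

    def test_normal_limit(self):
        assert t_to_z(1.96, 10_000) == pytest.approx(1.96, abs=0.01)

    def test_matches_quadrature_oracle(self):
        """z such that Phi(z) = F_t(3; 10), with F_t integrated numerically."""
        t, df = 3.0, 10
        dens = lambda x: sps.t.pdf(x, df)
        tail, _ = integrate.quad(dens, t, np.inf)
        z_expected = sps.norm.isf(tail)
        assert t_to_z(t, df) == pytest.approx(z_expected, abs=1e-6)

    def test_extreme_t_does_not_saturate(self):
        z = t_to_z(150.0, 15)
        assert np.isfinite(z)
        assert 10 < z <= 38
        assert t_to_z(-150.0, 15) == -z

    def test_monotone_in_t(self):
        zs = [t_to_z(t, 8) for t in np.linspace(-5, 5, 21)]
        assert np.all(np.diff(zs) > 0)


class TestSmoothness:
    def test_white_noise_close_to_voxel_size(self, rng):
        shape = (24, 24, 24)
        R = rng.standard_normal((12,) + shape)
        sm = estimate_smoothness(R, np.ones(shape, bool))
        # white noise: derivative variance 2 => FWHM = sqrt(2 ln 2) ~ 1.18 voxels
        for f in sm.fwhm_mm:
            assert f == pytest.approx(1.0, rel=0.25)

    def test_known_smoothing_recovered(self, rng):
        shape = (32, 32, 32)
        sig = 2.0 / np.sqrt(8 * np.log(2))  # 2-voxel FWHM
        R = np.stack(
            [ndimage.gaussian_filter(rng.standard_normal(shape), sig, mode="wrap") for _ in range(12)]
        )
        sm = estimate_smoothness(R, np.ones(shape, bool))
        for f in sm.fwhm_mm:
            assert f == pytest.approx(np.hypot(2.0, 1.0), rel=0.2)

    def test_smoothing_more_increases_fwhm(self, rng):
        shape = (24, 24, 24)
        noise = rng.standard_normal((10,) + shape)
        mask = np.ones(shape, bool)
        f1 = estimate_smoothness(
            np.stack([ndimage.gaussian_filter(n, 1.0) for n in noise]), mask
        ).fwhm_mm
        f2 = estimate_smoothness(
            np.stack([ndimage.gaussian_filter(n, 2.0) for n in noise]), mask
        ).fwhm_mm
        assert all(b > a for a, b in zip(f1, f2))

    def test_constant_residuals_rejected(self):
        R = np.ones((4, 3, 3, 3))
        with pytest.raises(ValueError):
            estimate_smoothness(R, np.ones((3, 3, 3), bool))

    def test_cuboid_resel_counts(self):
        """Lattice resel formulae reduce to the closed cuboid values."""
        from ratpet.stats import _lattice_resels

        m = np.ones((11, 6, 9), bool)
        f = (2.0, 2.0, 2.0)
        r0, r1, r2, r3 = _lattice_resels(m, f)
        a, b, c = 10 / 2, 5 / 2, 8 / 2  # side lengths in FWHM units
        assert r0 == pytest.approx(1.0)
        assert r1 == pytest.approx(a + b + c)
        assert r2 == pytest.approx(a * b + a * c + b * c)
        assert r3 == pytest.approx(a * b * c)


class TestFweThreshold:
    def _sm(self, resels, n=1000):
        return SmoothnessEstimate((3.0, 3.0, 3.0), resels, n)

    def test_small_volume_limit_is_uncorrected(self):
        sm = self._sm((1.0, 0.0, 0.0, 0.0))
        thr = fwe_threshold(sm, 20, alpha=0.05)
        assert thr == pytest.approx(sps.t.isf(0.05, 20), abs=1e-6)

    def test_rft_below_bonferroni_for_smooth_fields(self, rng):
        shape = (24, 24, 24)
        sig = 3.0 / np.sqrt(8 * np.log(2))
        R = np.stack(
            [ndimage.gaussian_filter(rng.standard_normal(shape), sig, mode="wrap") for _ in range(14)]
        )
        mask = np.ones(shape, bool)
        sm = estimate_smoothness(R, mask)
        t_rft = fwe_threshold(sm, 12, 0.05, "rft")
        t_bonf = fwe_threshold(sm, 12, 0.05, "bonferroni")
        assert t_rft <= t_bonf

    def test_threshold_monotone_in_alpha(self):
        sm = self._sm((1.0, 5.0, 20.0, 30.0))
        assert fwe_threshold(sm, 15, 0.01) > fwe_threshold(sm, 15, 0.05)

    def test_permutation_threshold_is_quantile(self):
        samples = np.arange(100, dtype=float)
        sm = self._sm((1.0, 0, 0, 0))
        thr = fwe_threshold(sm, 15, 0.05, "permutation", permutation_samples=samples)
        assert thr == pytest.approx(np.quantile(samples, 0.95))

    def test_expected_ec_decreasing_in_t(self):
        sm = self._sm((1.0, 5.0, 20.0, 30.0))
        ts = np.linspace(3, 10, 15)
        ecs = [expected_euler_characteristic(t, sm, 15) for t in ts]
        assert np.all(np.diff(ecs) < 0)

    def test_rft_type_one_error_is_conservative_not_inflated(self):
        """RFT on null cohorts never exceeds the nominal level (<= alpha band top).

        At df=15 with ~3-voxel smoothness the EC bound makes RFT strictly
        conservative; this guards the important direction (no false-positive
        inflation).
        """
        spec = PhantomSpec(dims=(36, 28, 22)).normalized()
        gt = make_ground_truth(spec)
        hits = 0
        n = 40
        for rep in range(n):
            a, b, _ = make_cohort(spec, 9, 8, 0.0, seed=5_000 + rep)
            res = two_sample_analysis(
                [s.volume for s in a], [s.volume for s in b], gt.brain_mask, extent=0
            )
            hits += bool(((res.tmap.data > res.threshold) & res.valid_mask).any())
        assert hits / n <= 0.09


class TestPermutation:
    def test_exhaustive_when_few_relabelings(self, rng):
        a = _vols([rng.random((3, 3, 3)) for _ in range(3)])
        b = _vols([rng.random((3, 3, 3)) for _ in range(3)])
        samples = permutation_max_t(a, b, _ones_mask((3, 3, 3)), n_permutations=500)
        from math import comb

        assert len(samples) == comb(6, 3)

    def test_observed_labelling_included(self, rng):
        a = _vols([rng.random((3, 3, 3)) + 1.0 for _ in range(3)])
        b = _vols([rng.random((3, 3, 3)) for _ in range(3)])
        mask = _ones_mask((3, 3, 3))
        res = fit_two_sample_t(a, b, mask)
        obs_max = res.tmap.data[res.valid_mask].max()
        samples = permutation_max_t(a, b, mask, n_permutations=500)
        assert np.any(np.isclose(samples, obs_max, atol=1e-10))


class TestClusterTable:
    def _result(self, t, vs=(1, 1, 1), origin=None):
        t = np.asarray(t, float)
        origin = origin or tuple((n - 1) / 2 for n in t.shape)
        vol = Volume(t, vs, origin=origin, space="template")
        return StatResult(tmap=vol, df=15, valid_mask=np.ones(t.shape, bool))

    def test_empty_map_gives_empty_table(self):
        res = self._result(np.zeros((6, 6, 6)))
        df = cluster_table(res, threshold=3.0)
        assert len(df) == 0

    def test_extent_filter_counts_components(self):
        t = np.zeros((20, 12, 12))
        t[1:6, 1:5, 1:4] = 5.0  # 60-voxel blob
        t[10:15, 6:10, 6:8] = 5.0  # 40-voxel blob
        t[3, 2, 2] = 6.0
        res = self._result(t)
        df = cluster_table(res, threshold=4.0, extent=50)
        assert df["cluster"].nunique() == 1
        assert int(df.iloc[0].K_E) == 60

    def test_peak_coordinates_match_argmax(self):
        t = np.zeros((9, 9, 9))
        t[2, 3, 4] = 7.0
        t[2, 3, 5] = 6.0
        t[2, 4, 4] = 5.5
        res = self._result(t, vs=(1, 1, 1.8), origin=(4, 4, 4))
        df = cluster_table(res, threshold=5.0, extent=1)
        row = df.iloc[0]
        assert (row.x, row.y, row.z) == (-2.0, -1.0, 0.0)
        assert row.Max_T == pytest.approx(7.0)
        assert row.Max_Z == pytest.approx(t_to_z(7.0, 15))

    def test_secondary_peaks_are_distant(self):
        t = np.zeros((30, 8, 8))
        t[2:26, 2:6, 2:6] = 4.5
        t[4, 4, 4] = 8.0
        t[20, 4, 4] = 7.0  # 16 mm away: reported as a sub-row
        t[6, 4, 4] = 7.5  # 2 mm away: suppressed
        res = self._result(t)
        df = cluster_table(res, threshold=4.0, extent=10, min_peak_distance_mm=8.0)
        assert df["cluster"].nunique() == 1
        assert len(df) <= 3  # at most three maxima reported per cluster
        assert {8.0, 7.0} <= set(df.Max_T)  # distant secondary peak reported
        assert 7.5 not in set(df.Max_T)  # near-peak within 8 mm suppressed

    def test_clusters_sorted_by_extent(self):
        t = np.zeros((24, 10, 10))
        t[1:4, 1:4, 1:4] = 6.0  # 27 voxels
        t[10:16, 1:7, 1:6] = 5.0  # 180 voxels
        res = self._result(t)
        df = cluster_table(res, threshold=4.0, extent=5)
        firsts = df.groupby("cluster").K_E.first()
        assert firsts.loc[1] >= firsts.loc[2]


class TestFullPipeline:
    def test_power_and_localization(self):
        """20% left-cortex deficit is detected and localized in seeded cohorts."""
        spec = PhantomSpec(dims=(40, 32, 26)).normalized()
        gt = make_ground_truth(spec)
        detected = 0
        n = 6
        for rep in range(n):
            ga, gb, _ = make_cohort(spec, 9, 8, effect_in_a=-0.2, seed=9_000 + rep)
            res = two_sample_analysis(
                [s.volume for s in ga], [s.volume for s in gb], gt.brain_mask,
                contrast="A<B", extent=20,
            )
            if len(res.clusters) == 0:
                continue
            supra = (res.tmap.data > res.threshold) & res.valid_mask
            labels, _ = ndimage.label(supra, ndimage.generate_binary_structure(3, 2))
            territory = gt.territory.data > 0
            if np.any(supra & territory):
                detected += 1
        assert detected >= 0.9 * n

    def test_cluster_table_sign_invariance(self):
        spec = PhantomSpec(dims=(36, 28, 22)).normalized()
        ga, gb, gt = make_cohort(spec, 9, 8, effect_in_a=-0.15, seed=123)
        va = [s.volume for s in ga]
        vb = [s.volume for s in gb]
        r1 = two_sample_analysis(va, vb, gt.brain_mask, contrast="A<B", extent=10)
        r2 = two_sample_analysis(vb, va, gt.brain_mask, contrast="B<A", extent=10)
        np.testing.assert_allclose(r1.tmap.data, r2.tmap.data, atol=1e-10)
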