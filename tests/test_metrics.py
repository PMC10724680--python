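"""Evaluation metrics against closed forms and independent oracles."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from cycleharm import (DegenerateInputError, HistogramSummary,
                       TissueSegmentation, UndefinedMetricError, Volume,
                       age_error_stats, cjv, efc, first_order_radiomics,
                       fwhm_estimate, heterogeneity_index, histogram_distance,
                       pca_project, radiomic_profile, rpve, segment_three_class,
                       snr_tissue, ssim3d, tissue_volume_fractions, wm2max)
from cycleharm.metrics import FIRST_ORDER_FEATURES


def cube(values, mask=None):
    data = np.asarray(values, dtype=float)
    return Volume(data, np.ones(data.shape, bool) if mask is None else mask)


class TestTissueVolumeFractions:
    def test_hard_label_counts(self):
        gm = np.zeros((4, 5, 5)); wm = np.zeros((4, 5, 5)); csf = np.zeros((4, 5, 5))
        gm[0] = 1; wm[1:3] = 1; csf[3] = 1
        seg = TissueSegmentation(gm, wm, csf)
        assert tissue_volume_fractions(seg) == pytest.approx((0.25, 0.5, 0.25))

    def test_fractions_sum_to_one(self, phantom40):
        assert sum(tissue_volume_fractions(phantom40.segmentation)) == pytest.approx(1.0)

    def test_phantom_bookkeeping_recovered(self, phantom40):
        fr = tissue_volume_fractions(phantom40.segmentation)
        direct = (phantom40.segmentation.gm.sum() / phantom40.segmentation.total().sum())
        assert fr[0] == pytest.approx(direct, rel=1e-12)

    def test_all_zero_rejected(self):
        z = np.zeros((3, 3, 3))
        with pytest.raises(DegenerateInputError):
            tissue_volume_fractions(TissueSegmentation(z, z, z))


class TestCJV:
    def test_constructed_value(self, block_volume):
        vol, seg = block_volume
        g = vol.data[:5]; w = vol.data[5:]
        expected = (g.std() + w.std()) / abs(w.mean() - g.mean())
        assert cjv(vol, seg) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariant(self, block_volume):
        vol, seg = block_volume
        scaled = vol.copy_with(vol.data * 3.7)
        assert cjv(scaled, seg) == pytest.approx(cjv(vol, seg), rel=1e-12)

    def test_noiseless_tissues_give_zero(self):
        data = np.zeros((4, 4, 4)); data[:2] = 300.0; data[2:] = 600.0
        gm = np.zeros_like(data); wm = np.zeros_like(data)
        gm[:2] = 1; wm[2:] = 1
        vol = Volume(data, np.ones(data.shape, bool))
        assert cjv(vol, TissueSegmentation(gm, wm, np.zeros_like(gm))) == 0.0

    def test_equal_means_undefined(self):
        data = np.full((4, 4, 4), 5.0)
        gm = np.zeros_like(data); wm = np.zeros_like(data)
        gm[:2] = 1; wm[2:] = 1
        with pytest.raises(UndefinedMetricError):
            cjv(Volume(data, np.ones(data.shape, bool)),
                TissueSegmentation(gm, wm, np.zeros_like(gm)))


class TestEFC:
    def test_constant_image_maximal(self):
        assert efc(cube(np.full((8, 8, 8), 5.0))) == pytest.approx(1.0)

    def test_single_voxel_zero(self):
        data = np.zeros((8, 8, 8)); data[3, 3, 3] = 7.0
        assert efc(cube(data)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation(self, rng):
        data = rng.uniform(0, 100, size=(10, 10, 10))
        n = data.size
        xmax = np.sqrt((data ** 2).sum())
        direct = -np.sum((data / xmax) * np.log(data / xmax)) / (np.sqrt(n) * np.log(np.sqrt(n)))
        assert efc(cube(data)) == pytest.approx(direct, abs=1e-9)


class TestSNR:
    def test_closed_form_limit(self, rng):
        data = rng.normal(500.0, 50.0, size=(20, 20, 20))
        seg = TissueSegmentation(np.ones(data.shape), np.zeros(data.shape),
                                 np.zeros(data.shape))
        vol = Volume(data, np.ones(data.shape, bool))
        assert snr_tissue(vol, seg, "gm") == pytest.approx(
            data.mean() / data.std(ddof=1), rel=1e-9)
        assert snr_tissue(vol, seg, "gm") == pytest.approx(10.0, rel=0.05)

    def test_scale_invariant(self, rng):
        data = rng.normal(500.0, 50.0, size=(10, 10, 10))
        seg = TissueSegmentation(np.ones(data.shape), np.zeros(data.shape),
                                 np.zeros(data.shape))
        a = snr_tissue(Volume(data, np.ones(data.shape, bool)), seg, "gm")
        b = snr_tissue(Volume(3 * data, np.ones(data.shape, bool)), seg, "gm")
        assert a == pytest.approx(b, rel=1e-9)

    def test_doubling_noise_halves_snr(self, rng):
        mu = 500.0
        n1 = rng.normal(0, 40.0, size=(25, 25, 25))
        seg = TissueSegmentation(np.ones(n1.shape), np.zeros(n1.shape), np.zeros(n1.shape))
        s1 = snr_tissue(Volume(mu + n1, np.ones(n1.shape, bool)), seg, "gm")
        s2 = snr_tissue(Volume(mu + 2 * n1, np.ones(n1.shape, bool)), seg, "gm")
        assert s1 / s2 == pytest.approx(2.0, rel=0.02)

    def test_zero_variance_undefined(self):
        data = np.full((4, 4, 4), 9.0)
        seg = TissueSegmentation(np.ones(data.shape), np.zeros(data.shape),
                                 np.zeros(data.shape))
        with pytest.raises(UndefinedMetricError):
            snr_tissue(Volume(data, np.ones(data.shape, bool)), seg, "gm")


class TestWM2Max:
    def test_direct_ratio(self):
        data = np.zeros((10, 10, 10))
        data[:5] = 400.0          # non-WM brain
        data[5:] = 600.0          # WM
        wm = np.zeros_like(data); wm[5:] = 1
        seg = TissueSegmentation(np.zeros_like(wm), wm, np.zeros_like(wm))
        vol = Volume(data, np.ones(data.shape, bool))
        p95 = np.percentile(data, 95)
        assert wm2max(vol, seg) == pytest.approx(600.0 / p95, rel=1e-9)

    def test_uniform_brain_is_one(self):
        data = np.full((6, 6, 6), 500.0)
        seg = TissueSegmentation(np.zeros(data.shape), np.ones(data.shape),
                                 np.zeros(data.shape))
        assert wm2max(Volume(data, np.ones(data.shape, bool)), seg) == pytest.approx(1.0)

    def test_rescale_invariant(self, phantom40):
        v = phantom40.volume
        s = phantom40.segmentation
        assert wm2max(v.copy_with(v.data * 2.5), s) == pytest.approx(
            wm2max(v, s), rel=1e-9)


class TestRPVE:
    def test_binary_map_zero(self):
        m = np.zeros((5, 5, 5)); m[:2] = 1.0
        seg = TissueSegmentation(m, np.zeros_like(m), np.zeros_like(m))
        assert rpve(seg, "gm") == 0.0

    def test_hand_sum(self):
        m = np.zeros((5, 5, 5)).ravel()
        m[:80] = 1.0
        m[80:120] = 0.5
        seg = TissueSegmentation(m.reshape(5, 5, 5), np.zeros((5, 5, 5)),
                                 np.zeros((5, 5, 5)))
        # f-sum = 40 * 0.5 = 20; p-sum = 100 -> 20%
        assert rpve(seg, "gm") == pytest.approx(20.0)

    def test_bounded_on_phantom(self, phantom40):
        for t in ("gm", "wm", "csf"):
            assert 0.0 <= rpve(phantom40.segmentation, t) <= 100.0


class TestFWHM:
    def test_recovers_known_smoothing(self, rng):
        from scipy import ndimage
        target = 3.0
        sm = ndimage.gaussian_filter(rng.normal(size=(64, 64, 64)), target / 2.3548)
        est = fwhm_estimate(Volume(sm, np.ones(sm.shape, bool)))
        assert est == pytest.approx(target, rel=0.10)

    def test_barely_smoothed_noise_below_voxel_and_a_half(self, rng):
        # near-white noise: a sigma-0.5 kernel has true FWHM ~1.18 voxels;
        # the first-difference estimator must stay below 1.5 voxel widths
        # (pure white noise makes the estimator's log argument fluctuate
        # around zero, where the per-axis estimate is undefined by design)
        from scipy import ndimage
        noise = ndimage.gaussian_filter(rng.normal(size=(48, 48, 48)), 0.5)
        est = fwhm_estimate(Volume(noise, np.ones(noise.shape, bool)))
        assert est < 1.5

    def test_scales_with_voxel_spacing(self, rng):
        from scipy import ndimage
        sm = ndimage.gaussian_filter(rng.normal(size=(48, 48, 48)), 1.5)
        v1 = Volume(sm, np.ones(sm.shape, bool), spacing=(1, 1, 1))
        v2 = Volume(sm, np.ones(sm.shape, bool), spacing=(2, 2, 2))
        assert fwhm_estimate(v2) == pytest.approx(2 * fwhm_estimate(v1), rel=1e-9)


class TestRadiomics:
    def test_profile_has_36_values(self, phantom40):
        prof = radiomic_profile(phantom40.volume, phantom40.segmentation)
        assert prof.shape == (36,)
        assert np.isfinite(prof).all()

    def test_constant_region(self):
        data = np.full((4, 4, 4), 7.0)
        f = first_order_radiomics(cube(data), np.ones(data.shape, bool))
        assert f["variance"] == 0.0
        assert f["entropy"] == 0.0
        assert f["uniformity"] == 1.0

    def test_enumerated_region_hand_oracle(self):
        data = np.zeros((4, 1, 1)); data[:, 0, 0] = [1.0, 2.0, 2.0, 3.0]
        f = first_order_radiomics(cube(data), np.ones(data.shape, bool), bin_width=1.0)
        x = np.array([1.0, 2.0, 2.0, 3.0])
        assert f["mean"] == 2.0
        assert f["median"] == 2.0
        assert f["range"] == 2.0
        assert f["minimum"] == 1.0 and f["maximum"] == 3.0
        assert f["energy"] == pytest.approx((x ** 2).sum())
        assert f["rms"] == pytest.approx(np.sqrt((x ** 2).mean()))
        assert f["variance"] == pytest.approx(x.var())
        assert f["mad"] == pytest.approx(np.abs(x - 2.0).mean())
        p = np.array([0.25, 0.5, 0.25])
        assert f["uniformity"] == pytest.approx((p ** 2).sum())
        assert f["entropy"] == pytest.approx(-(p * np.log2(p)).sum())

    def test_feature_list_is_pinned(self):
        assert len(FIRST_ORDER_FEATURES) == 18
        assert len(set(FIRST_ORDER_FEATURES)) == 18


class TestPCA:
    def test_rank_one_data(self, rng):
        base = rng.normal(size=10)
        X = np.outer(base, rng.normal(size=5)) + 0.0
        coords, ve = pca_project(X)
        assert ve[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_explained_ordering(self, rng):
        X = rng.normal(size=(30, 8))
        _, ve = pca_project(X)
        assert ve[0] >= ve[1] >= 0.0
        assert ve[0] + ve[1] <= 1.0 + 1e-12

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(25, 6))
        Xs = (X - X.mean(0)) / X.std(0)
        cov = np.cov(Xs, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        proj = Xs @ evecs[:, order[:2]]
        coords, _ = pca_project(X)
        for k in range(2):
            dot = np.dot(coords[:, k], proj[:, k])
            np.testing.assert_allclose(coords[:, k], np.sign(dot) * proj[:, k],
                                       atol=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_project(np.zeros((2, 5)))


class TestSSIM3D:
    def test_identical_volumes(self, rng):
        a = rng.uniform(1, 900, size=(16, 16, 16))
        assert ssim3d(a, a.copy()) == pytest.approx(1.0)

    def test_constant_pair_closed_form(self):
        a = np.zeros((10, 10, 10))
        b = np.full((10, 10, 10), 1000.0)
        c1 = (0.01 * 1000.0) ** 2
        assert ssim3d(a, b) == pytest.approx(c1 / (1000.0 ** 2 + c1), rel=1e-9)

    def test_matches_reference_implementation(self, rng):
        a = rng.uniform(1, 900, size=(24, 24, 24))
        b = a + rng.normal(0, 50, size=a.shape)
        ref = structural_similarity(a, b, data_range=1000.0, win_size=7,
                                    gaussian_weights=False)
        assert ssim3d(a, b) == pytest.approx(ref, abs=1e-6)

    def test_background_slices_removed(self, rng):
        core_a = rng.uniform(100, 900, size=(12, 12, 12))
        core_b = core_a + rng.normal(0, 30, size=core_a.shape)
        a = np.zeros((30, 30, 30)); b = np.zeros((30, 30, 30))
        a[4:16, 4:16, 4:16] = core_a
        b[4:16, 4:16, 4:16] = core_b
        assert ssim3d(a, b) == pytest.approx(ssim3d(core_a, core_b), rel=1e-9)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim3d(np.zeros((8, 8, 8)), np.zeros((9, 9, 9)))


class TestHistogramStatistics:
    edges = np.linspace(0.0, 900.0, 101)

    def _h(self, counts):
        c = np.zeros(100); c[:len(counts)] = counts
        return HistogramSummary(c, self.edges)

    def test_identical_distance_zero(self):
        h = self._h([5, 3, 1])
        assert histogram_distance(h, h) == 0.0

    def test_unit_displacement(self):
        assert histogram_distance(self._h([1]), self._h([0, 1])) == pytest.approx(np.sqrt(2))

    def test_metric_properties_on_random_triples(self, rng):
        hs = [self._h(rng.integers(0, 50, size=100)) for _ in range(3)]
        d01 = histogram_distance(hs[0], hs[1])
        d10 = histogram_distance(hs[1], hs[0])
        assert d01 == d10
        assert histogram_distance(hs[0], hs[2]) <= d01 + histogram_distance(hs[1], hs[2])

    def test_heterogeneity_identical_sites_zero(self):
        h = self._h([5, 3])
        assert heterogeneity_index([h, h, h]) == 0.0

    def test_heterogeneity_two_point_sd(self):
        h1 = self._h([0, 0, 0, 0, 0, 10])
        h2 = self._h([0, 0, 0, 0, 0, 20])
        assert heterogeneity_index([h1, h2]) == pytest.approx(10 / np.sqrt(2))

    def test_heterogeneity_order_invariant(self, rng):
        hs = [self._h(rng.integers(0, 30, size=100)) for _ in range(4)]
        assert heterogeneity_index(hs) == pytest.approx(
            heterogeneity_index(hs[::-1]))

    def test_heterogeneity_vanishes_at_grand_mean(self, rng):
        hs = [self._h(rng.integers(0, 30, size=100)) for _ in range(4)]
        grand = np.mean([h.counts for h in hs], axis=0)
        uniform = [HistogramSummary(grand.copy(), self.edges) for _ in hs]
        assert heterogeneity_index(hs) > 0
        assert heterogeneity_index(uniform) == 0.0


class TestAgeErrorStats:
    def test_worked_example(self):
        s = age_error_stats([30.0, 40.0], [35.0, 35.0], train_mean=50.0,
                            test_mean=40.0)
        assert s.mae == 5.0
        assert s.mpad == 0.0
        assert s.tmd == 10.0

    def test_mae_dominates_mpad(self, rng):
        for _ in range(20):
            p = rng.normal(50, 10, size=30)
            t = rng.normal(50, 10, size=30)
            s = age_error_stats(p, t, 50.0, 50.0)
            assert s.mae >= abs(s.mpad)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            age_error_stats([1.0], [1.0, 2.0], 0.0, 0.0)


class TestFallbackSegmentation:
    def test_recovers_phantom_fractions(self, phantom40):
        est = segment_three_class(phantom40.volume)
        true_fr = tissue_volume_fractions(phantom40.segmentation)
        est_fr = tissue_volume_fractions(est)
        np.testing.assert_allclose(est_fr, true_fr, atol=0.03)


class TestIQMSetInvariance:
    def test_rescale_invariance_of_ratio_metrics(self, phantom40):
        from cycleharm import iqm_set
        v, s = phantom40.volume, phantom40.segmentation
        a = iqm_set(v, s)
        b = iqm_set(v.copy_with(v.data * 4.2), s)
        for name in ("cjv", "snr_gm", "snr_wm", "snr_csf", "wm2max", "fwhm"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-6)
        assert (a.icv_gm, a.icv_wm, a.icv_csf) == (b.icv_gm, b.icv_wm, b.icv_csf)
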