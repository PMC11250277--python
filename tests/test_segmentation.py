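"""Ellipsoidal segmentation: masking, seeding, EM, the fitness criterion and
the composed workflow against generator ground truth."""

import numpy as np
import pytest

from msidyn.segmentation import (
    BinarizeConfig,
    EllipseComponent,
    SegmentConfig,
    assign_pixels,
    binarize,
    detect_seeds,
    em_fit,
    fitness_degree,
    segment,
    select_components,
)
from msidyn.synth.images import rasterize_ellipse

from conftest import match_centers


def disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def axis_aligned_component(cy, cx, var_r, var_c, quantile=0.95):
    return EllipseComponent(mean=np.array([cy, cx], dtype=float),
                            covariance=np.diag([var_r, var_c]).astype(float),
                            weight=1.0, boundary_quantile=quantile)


class TestBinarize:
    def test_constant_image_gives_empty_mask(self):
        img = np.full((80, 80), 55.0)
        assert not binarize(img, BinarizeConfig(offset_frac=0.02)).any()

    def test_disk_on_gradient_recovered(self):
        shape = (300, 300)
        img = 10.0 + 50.0 * np.linspace(0, 1, shape[1])[None, :] * np.ones(shape)
        truth = disk_mask(shape, 150, 140, 22)
        img[truth] = 200.0
        mask = binarize(img)
        inter = (mask & truth).sum()
        union = (mask | truth).sum()
        assert inter / union >= 0.95

    def test_small_blob_removed(self):
        img = np.full((100, 100), 10.0)
        img[50:52, 50:52] = 200.0  # 4-pixel blob, below the 30 px minimum
        assert not binarize(img).any()

    def test_nonfinite_rejected(self):
        img = np.full((50, 50), 10.0)
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            binarize(img)


class TestDetectSeeds:
    def test_single_disk_yields_center_seed(self):
        mask = disk_mask((80, 80), 40, 37, 14)
        seeds = detect_seeds(mask)
        assert len(seeds) == 1
        r, c, _ = seeds[0]
        assert np.hypot(r - 40, c - 37) <= 1.0

    def test_two_disjoint_disks_yield_two_seeds(self):
        mask = disk_mask((100, 100), 30, 30, 10) | disk_mask((100, 100), 70, 70, 10)
        assert len(detect_seeds(mask)) == 2

    def test_close_maxima_merged(self):
        # two overlapping disks with centers 3 px apart: two local maxima
        # within the merge distance collapse to one seed
        mask = disk_mask((60, 60), 30, 29, 8) | disk_mask((60, 60), 30, 32, 8)
        assert len(detect_seeds(mask, merge_dist_px=5.0)) == 1

    def test_empty_mask(self):
        assert detect_seeds(np.zeros((10, 10), dtype=bool)) == []


class TestEmFit:
    def test_single_component_recovers_gaussian_mle(self):
        mask = rasterize_ellipse((80, 80), 40, 38, 12, 7, 0.4)
        fit = em_fit(mask, [(38, 40, 5.0)])
        pts = np.argwhere(mask).astype(float)
        np.testing.assert_allclose(fit.components[0].mean, pts.mean(axis=0),
                                   atol=1e-6)
        mle_cov = np.cov(pts.T, bias=True)
        np.testing.assert_allclose(fit.components[0].covariance, mle_cov,
                                   atol=1e-6)

    def test_mirror_symmetric_blobs_give_mirror_means(self):
        mask = disk_mask((60, 120), 30, 30, 10) | disk_mask((60, 120), 30, 90, 10)
        fit = em_fit(mask, [(30, 30, 9.0), (30, 90, 9.0)])
        m0, m1 = (c.mean for c in fit.components)
        assert m0[0] == pytest.approx(m1[0], abs=1e-6)
        assert m0[1] + m1[1] == pytest.approx(120.0, abs=1e-6)

    def test_loglik_trace_non_decreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            shape = (50, 50)
            mask = np.zeros(shape, dtype=bool)
            n_blobs = rng.integers(1, 4)
            seeds = []
            for _ in range(n_blobs):
                cy, cx = rng.integers(10, 40, size=2)
                r = rng.integers(4, 9)
                mask |= disk_mask(shape, cy, cx, r)
                seeds.append((int(cy), int(cx), float(r)))
            fit = em_fit(mask, seeds)
            diffs = np.diff(fit.loglik_trace)
            assert (diffs >= -1e-6 * np.abs(fit.loglik_trace[:-1])).all()

    def test_agrees_with_reference_gmm_on_separated_blobs(self):
        pytest.importorskip("sklearn")
        from sklearn.mixture import GaussianMixture

        mask = disk_mask((80, 160), 40, 40, 12) | disk_mask((80, 160), 40, 120, 9)
        fit = em_fit(mask, [(40, 40, 11.0), (40, 120, 8.0)], tol=1e-8)
        pts = np.argwhere(mask).astype(float)
        ref = GaussianMixture(n_components=2, covariance_type="full",
                              means_init=[[40, 40], [40, 120]], tol=1e-8,
                              random_state=0).fit(pts)
        ours = sorted([tuple(c.mean) for c in fit.components], key=lambda t: t[1])
        theirs = sorted([tuple(m) for m in ref.means_], key=lambda t: t[1])
        np.testing.assert_allclose(ours, theirs, atol=0.5)


class TestFitnessDegree:
    def _perfect_setup(self):
        shape = (200, 200)
        comps = [
            axis_aligned_component(50, 50, 40, 20),
            axis_aligned_component(60, 150, 25, 25),
            axis_aligned_component(150, 100, 30, 55),
        ]
        cover = np.zeros(shape, dtype=int)
        for comp in comps:
            yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
            pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
            cover += comp.contains(pts).reshape(shape)
        mask = cover > 0
        assert cover.max() == 1  # disjoint by construction
        return mask, comps

    def test_perfect_fit_scores_exactly_one(self):
        mask, comps = self._perfect_setup()
        intensity = np.where(mask, 180.0, 20.0)
        fb = fitness_degree(mask, comps, intensity)
        assert fb.score == 1.0
        assert fb.A_B == 0 and fb.A_T == 0 and fb.W_I == 0

    def test_all_background_scores_minus_one(self):
        shape = (100, 100)
        mask = np.zeros(shape, dtype=bool)
        mask[:10, :10] = True  # foreground far from the ellipse
        comp = axis_aligned_component(70, 70, 30, 30)
        fb = fitness_degree(mask, [comp], np.full(shape, 50.0))
        assert fb.score == -1.0

    def test_duplicate_component_scores_half(self):
        mask, comps = self._perfect_setup()
        one = [comps[1], comps[1]]  # coincident duplicate on covered fg
        sub_mask = np.zeros_like(mask)
        shape = mask.shape
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
        sub_mask |= comps[1].contains(pts).reshape(shape)
        fb = fitness_degree(sub_mask, one, np.where(sub_mask, 180.0, 20.0))
        assert fb.score == pytest.approx(0.5)

    def test_covered_pixel_conservation_and_bound(self, benchmark_image):
        spec, channels, truth = benchmark_image
        mask = binarize(channels["dapi"])
        seeds = detect_seeds(mask)
        fit = em_fit(mask, seeds)
        fb = fitness_degree(mask, fit.components, channels["dapi"])
        assert fb.A_F + fb.A_B == fb.E
        assert fb.score <= 1.0
        assert min(fb.A_F, fb.A_B, fb.A_T, fb.W_I) >= 0

    def test_empty_coverage_is_an_error(self):
        mask = np.ones((20, 20), dtype=bool)
        comp = axis_aligned_component(500, 500, 4, 4)  # off-image
        with pytest.raises(ValueError):
            fitness_degree(mask, [comp])


class TestSelectComponents:
    def test_spurious_seed_rejected(self):
        shape = (60, 60)
        mask = disk_mask(shape, 20, 20, 9) | disk_mask(shape, 40, 42, 9)
        seeds = [(20, 20, 9.0), (40, 42, 9.0), (30, 31, 2.0)]  # third is noise
        fit, fb = select_components(mask, seeds)
        assert len(fit.components) == 2
        full_fit = em_fit(mask, seeds)
        fb_full = fitness_degree(mask, full_fit.components)
        assert fb.score >= fb_full.score

    def test_single_seed_unchanged(self):
        mask = disk_mask((40, 40), 20, 20, 10)
        fit, _ = select_components(mask, [(20, 20, 10.0)])
        assert len(fit.components) == 1


class TestAssignPixels:
    def test_partition_of_foreground(self):
        mask = disk_mask((60, 60), 20, 20, 8) | disk_mask((60, 60), 40, 40, 8)
        fit = em_fit(mask, [(20, 20, 8.0), (40, 40, 8.0)])
        labels = assign_pixels(mask, fit.components)
        np.testing.assert_array_equal(labels > 0, mask)
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_exact_tie_breaks_to_lower_index(self):
        mask = np.ones((20, 20), dtype=bool)
        comp = axis_aligned_component(10, 10, 9, 9)
        twin = axis_aligned_component(10, 10, 9, 9)
        labels = assign_pixels(mask, [comp, twin])
        assert (labels[mask] == 1).all()


class TestSegmentWorkflow:
    def test_blank_image_yields_no_cells(self):
        channels = {"dapi": np.full((100, 100), 12.0)}
        cells, labels = segment(channels)
        assert cells == []
        assert not labels.any()

    def test_benchmark_recovery(self, benchmark_image):
        spec, channels, truth = benchmark_image
        cells, _ = segment(channels, um_per_px=spec.um_per_px)
        n_true = len(truth.ellipses)
        assert abs(len(cells) - n_true) <= 0.05 * n_true
        rate, rmse = match_centers(truth, cells)
        assert rate >= 0.95
        assert rmse < 2.0

    def test_deterministic(self, clean_image):
        spec, channels, _ = clean_image
        cells1, labels1 = segment(channels, um_per_px=spec.um_per_px)
        cells2, labels2 = segment(channels, um_per_px=spec.um_per_px)
        np.testing.assert_array_equal(labels1, labels2)
        assert [c.center_rc for c in cells1] == [c.center_rc for c in cells2]

    def test_missing_nuclear_channel(self):
        with pytest.raises(KeyError):
            segment({"cd8": np.zeros((10, 10))})
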