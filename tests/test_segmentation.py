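"""Normalization, CSF threshold, skull strip and fuzzy c-means."""

import numpy as np
import pytest
from scipy import ndimage

from cortexratio import phantom, segmentation
from cortexratio.segmentation import (
    DegenerateInput,
    dice,
    estimate_csf_threshold,
    fuzzy_segment,
    local_intensity_normalize,
    segment_t1,
    skull_strip,
)
from cortexratio.volume import BinaryMask, ScalarVolume


class TestNormalize:
    def test_constant_image_maps_to_one(self):
        vol = ScalarVolume(np.full((24, 24, 24), 3.7))
        norm, flagged = local_intensity_normalize(vol)
        np.testing.assert_allclose(norm.data[~flagged], 1.0, atol=1e-6)

    def test_single_bright_voxel_not_amplified(self):
        data = np.zeros((24, 24, 24))
        data[12, 12, 12] = 5.0
        norm, _ = local_intensity_normalize(ScalarVolume(data))
        assert norm.data[12, 12, 12] <= 1.0 + 1e-9

    def test_smooth_bias_is_divided_out(self, small_phantom):
        t1, _, truth = small_phantom
        ax = [np.linspace(-1, 1, n) for n in t1.shape]
        U, V, W = np.meshgrid(*ax, indexing="ij")
        bias = np.exp(0.3 * U + 0.2 * V - 0.25 * W)
        biased = t1.like(t1.data * bias)
        norm, _ = local_intensity_normalize(biased)
        wm = truth.wm_mask()

        def cov(x):
            return x.std() / x.mean()

        assert cov(norm.data[wm]) < cov(biased.data[wm]) / 2

    def test_all_zero_image_rejected(self):
        with pytest.raises(DegenerateInput):
            local_intensity_normalize(ScalarVolume(np.zeros((8, 8, 8))))

    def test_even_window_rejected(self, small_phantom):
        t1, _, _ = small_phantom
        with pytest.raises(ValueError):
            local_intensity_normalize(t1, window=4)


class TestCSFThreshold:
    def test_threshold_lies_between_two_modes(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0.2, 0.01, 5000),
                            rng.normal(0.7, 0.01, 5000)])
        res = estimate_csf_threshold(x)
        assert 0.2 < res.value < 0.7
        assert not res.fallback

    def test_unimodal_falls_back_to_otsu(self):
        rng = np.random.default_rng(1)
        res = estimate_csf_threshold(rng.normal(0.5, 0.05, 5000))
        assert res.fallback and res.method == "otsu"

    def test_too_few_voxels_rejected(self):
        with pytest.raises(DegenerateInput):
            estimate_csf_threshold(np.ones(10))

    def test_noiseless_phantom_threshold_reproduces_tissue_mask(self, small_phantom):
        t1, _, truth = small_phantom
        norm, flagged = local_intensity_normalize(t1)
        head = (t1.data > 0) & ~flagged
        res = estimate_csf_threshold(norm.data[head])
        mask = head & (norm.data > res.value)
        brain = truth.gm_mask() | truth.wm_mask()
        # CSF gone, tissue kept (dura removal is morphology's job)
        assert not np.any(mask & truth.csf_mask)
        assert np.all(mask[brain])


class TestSkullStrip:
    def test_dura_free_mask_covering_brain(self, small_phantom):
        t1, _, truth = small_phantom
        norm, flagged = local_intensity_normalize(t1)
        head = BinaryMask((t1.data > 0) & ~flagged, t1.spacing, "head")
        mask, _ = skull_strip(norm, head)
        dura = truth.tissue_labels == phantom.DURA
        brain = truth.gm_mask() | truth.wm_mask()
        assert (mask.data & dura).sum() == 0
        assert (mask.data & brain).sum() >= 0.99 * brain.sum()

    def test_opening_is_identity_on_large_convex_mask(self):
        ball = np.zeros((32, 32, 32), dtype=bool)
        ax = [np.arange(32) - 15.5] * 3
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        ball[(X**2 + Y**2 + Z**2) < 100] = True
        elem = ndimage.generate_binary_structure(3, 1)
        opened = ndimage.binary_dilation(ndimage.binary_erosion(ball, elem), elem)
        assert np.array_equal(opened, ball)

    def test_upsample_downsample_volume_change_small(self, small_phantom):
        _, _, truth = small_phantom
        mask = (truth.gm_mask() | truth.wm_mask()).astype(float)
        up = ndimage.zoom(mask, 2.0, order=1, grid_mode=True, mode="nearest")
        down = ndimage.zoom(up, 0.5, order=1, grid_mode=True, mode="nearest")
        v0 = mask.sum()
        v1 = (down > 0.5).sum()
        assert abs(v1 - v0) / v0 < 0.01


class TestFuzzySegment:
    def test_two_valued_image_is_exact_fixed_point(self):
        data = np.zeros((12, 12, 12))
        data[:6] = 0.4
        data[6:] = 0.9
        vol = ScalarVolume(data)
        mask = np.ones(data.shape, dtype=bool)
        memb = fuzzy_segment(vol, mask, spatial_beta=0.0)
        np.testing.assert_allclose(memb.centroids, [0.4, 0.9], atol=1e-6)
        u = memb.memberships
        assert np.all((u[0][mask] > 0.999) | (u[1][mask] > 0.999))

    def test_memberships_sum_to_one_in_mask(self, small_phantom):
        t1, _, truth = small_phantom
        mask = truth.gm_mask() | truth.wm_mask()
        memb = fuzzy_segment(t1, mask)
        s = memb.memberships.sum(axis=0)[mask]
        np.testing.assert_allclose(s, 1.0, atol=1e-9)

    def test_objective_non_increasing(self, small_phantom):
        # strict descent is a theorem for the alternating minimization at
        # beta=0; the spatially regularized update (neighbours held fixed)
        # must still improve the objective overall
        t1, _, truth = small_phantom
        rng = np.random.default_rng(5)
        noisy = t1.like(t1.data + rng.normal(0, 0.015, t1.shape))
        mask = truth.gm_mask() | truth.wm_mask()
        plain = fuzzy_segment(noisy, mask, spatial_beta=0.0)
        h = plain.objective_history
        assert all(b <= a + 1e-9 * abs(a) for a, b in zip(h, h[1:]))
        reg = fuzzy_segment(noisy, mask, spatial_beta=0.3)
        hr = reg.objective_history
        assert hr[-1] <= hr[0]

    def test_spatial_penalty_improves_noisy_dice(self, small_phantom):
        t1, _, truth = small_phantom
        rng = np.random.default_rng(6)
        sigma = 0.12 * t1.data[truth.gm_mask()].mean()
        noisy = t1.like(t1.data + rng.normal(0, sigma, t1.shape))
        mask = truth.gm_mask() | truth.wm_mask()
        plain = fuzzy_segment(noisy, mask, spatial_beta=0.0)
        reg = fuzzy_segment(noisy, mask, spatial_beta=0.5)
        d_plain = dice(plain.hard_labels == 2, truth.wm_mask())
        d_reg = dice(reg.hard_labels == 2, truth.wm_mask())
        assert d_reg > d_plain

    def test_matches_bruteforce_two_means_on_small_instance(self):
        # beta=0, m=2 FCM hard labels on separable data = 2-means partition
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(0.3, 0.02, 200),
                               rng.normal(0.8, 0.02, 200)])
        data = vals.reshape((8, 10, 5))
        vol = ScalarVolume(data)
        mask = np.ones(data.shape, dtype=bool)
        memb = fuzzy_segment(vol, mask, spatial_beta=0.0, tol=1e-10,
                             max_iter=500)
        # brute force 2-means: try every threshold between sorted values
        xs = np.sort(vals)
        best = None
        for cut in range(1, len(xs)):
            lo, hi = xs[:cut], xs[cut:]
            sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if best is None or sse < best[0]:
                best = (sse, 0.5 * (xs[cut - 1] + xs[cut]))
        labels_bf = (data > best[1]).astype(int) + 1
        agree = (memb.hard_labels == labels_bf).mean()
        assert agree == 1.0

    def test_degenerate_constant_mask_rejected(self):
        vol = ScalarVolume(np.ones((8, 8, 8)))
        with pytest.raises(DegenerateInput):
            fuzzy_segment(vol, np.ones((8, 8, 8), dtype=bool))


class TestFullChain:
    def test_noiseless_standard_phantom_exact_recovery(self, standard_phantom):
        t1, _, truth = standard_phantom
        seg = segment_t1(t1)
        assert dice(seg["gm_mask"].data, truth.gm_mask()) == 1.0
        assert dice(seg["wm_mask"].data, truth.wm_mask()) == 1.0

    def test_three_percent_noise_recovery(self, standard_phantom):
        t1, t2, truth = standard_phantom
        t1n, _ = phantom.apply_bias_and_noise(t1, t2, truth, seed=13,
                                              noise_sigma_frac=0.03)
        seg = segment_t1(t1n)
        assert dice(seg["gm_mask"].data, truth.gm_mask()) >= 0.95
        assert dice(seg["wm_mask"].data, truth.wm_mask()) >= 0.95

    def test_ratio_analysis_consumes_original_intensities(self, standard_phantom):
        """Scaling T1w rescales the ratio: normalization never leaks into it."""
        from cortexratio import pipeline
        t1, t2, truth = standard_phantom
        config = pipeline.PipelineConfig(register=False)
        geom = pipeline.build_geometry(truth.gm_mask(), truth.wm_mask(),
                                       truth.roi_labels, truth.spacing, config)
        out1 = pipeline.process_subject("a", t1, t2, geom, config)
        out2 = pipeline.process_subject("b", t1.like(2.0 * t1.data), t2,
                                        geom, config)
        ok = np.isfinite(out1.shell_values)
        np.testing.assert_allclose(out2.shell_values[ok],
                                   2.0 * out1.shell_values[ok], rtol=1e-10)
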