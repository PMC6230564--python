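"""Phantom generator: geometry, effects, bias/noise, determinism."""

import numpy as np
import pytest
from scipy import ndimage

from cortexratio import phantom
from cortexratio.registration import RigidTransform


class TestGeometry:
    def test_every_gm_voxel_has_one_roi_label(self, small_phantom):
        _, _, truth = small_phantom
        gm = truth.gm_mask()
        assert truth.n_rois == 8
        assert np.all(truth.roi_labels[gm] >= 1)
        assert np.all(truth.roi_labels[gm] <= 8)
        assert np.all(truth.roi_labels[~gm] == 0)

    def test_clean_ratio_ordering_follows_tissue_means(self, small_phantom):
        t1, t2, truth = small_phantom
        ratio = np.divide(t1.data, t2.data, out=np.zeros_like(t1.data),
                          where=t2.data > 0)
        wm = ratio[truth.wm_mask()].mean()
        gm = ratio[truth.gm_mask()].mean()
        csf = ratio[truth.csf_mask].mean()
        assert wm > gm > csf

    def test_same_arguments_give_bit_identical_phantoms(self):
        a = phantom.make_brain_phantom((32, 32, 32), n_rois=4)
        b = phantom.make_brain_phantom((32, 32, 32), n_rois=4)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)
        assert np.array_equal(a[2].tissue_labels, b[2].tissue_labels)

    def test_labels_are_topologically_nested(self, small_phantom):
        # no GM voxel touches (26-adjacency) background without CSF/dura between
        _, _, truth = small_phantom
        bg = (truth.tissue_labels == phantom.BACKGROUND) & ~truth.csf_mask
        near_bg = ndimage.binary_dilation(
            bg, ndimage.generate_binary_structure(3, 3))
        assert not np.any(near_bg & truth.gm_mask())
        # every WM voxel is strictly interior to the GM shell: WM dilated
        # once never reaches CSF/background
        wm_d = ndimage.binary_dilation(truth.wm_mask())
        assert not np.any(wm_d & (truth.tissue_labels == 0))

    def test_degenerate_geometry_raises(self):
        with pytest.raises(phantom.InvalidGeometry):
            phantom.make_brain_phantom(
                (16, 16, 16),
                geometry=phantom.PhantomGeometry(wm_radii=(1.0, 1.0, 1.0),
                                                 ribbon_thickness=1.0),
            )

    @pytest.mark.parametrize("n_rois", [1, 7, 82])
    def test_sector_partition_counts(self, n_rois):
        rng = np.random.default_rng(0)
        theta = np.arccos(rng.uniform(-1, 1, 20000))
        phi = rng.uniform(-np.pi, np.pi, 20000)
        labels = phantom.sector_partition(theta, phi, n_rois)
        assert set(np.unique(labels)) == set(range(1, n_rois + 1))


class TestGroupEffect:
    def test_zero_effect_is_identity(self, small_phantom):
        _, t2, truth = small_phantom
        out = phantom.apply_group_effect(t2, truth, {})
        assert np.array_equal(out.data, t2.data)

    def test_effect_scales_clean_ratio_exactly_and_locally(self, small_phantom):
        t1, t2, truth = small_phantom
        out = phantom.apply_group_effect(t2, truth, {3: 0.05})
        in_roi = truth.roi_labels == 3
        ratio_before = t1.data[in_roi] / t2.data[in_roi]
        ratio_after = t1.data[in_roi] / out.data[in_roi]
        np.testing.assert_allclose(ratio_after, 1.05 * ratio_before, rtol=1e-12)
        other = truth.gm_mask() & ~in_roi
        assert np.array_equal(out.data[other], t2.data[other])

    def test_effect_below_minus_one_rejected(self, small_phantom):
        _, t2, truth = small_phantom
        with pytest.raises(phantom.InvalidEffect):
            phantom.apply_group_effect(t2, truth, {1: -1.0})


class TestBiasAndNoise:
    def test_unit_fields_zero_noise_is_identity(self, small_phantom):
        t1, t2, truth = small_phantom
        t1o, t2o = phantom.apply_bias_and_noise(t1, t2, truth, seed=0,
                                                noise_sigma_frac=0.0)
        assert np.array_equal(t1o.data, t1.data)
        assert np.array_equal(t2o.data, t2.data)

    def test_receive_bias_cancels_in_voxelwise_ratio(self, small_phantom):
        t1, t2, truth = small_phantom
        rng = np.random.default_rng(1)
        truth.receive_field = phantom.polynomial_bias_field(
            t1.shape, t1.spacing, 0.4, rng)
        t1o, t2o = phantom.apply_bias_and_noise(t1, t2, truth, seed=0,
                                                noise_sigma_frac=0.0)
        brain = truth.gm_mask() | truth.wm_mask()
        obs = t1o.data[brain] / t2o.data[brain]
        clean = t1.data[brain] / t2.data[brain]
        np.testing.assert_allclose(obs, clean, rtol=1e-10)
        truth.receive_field = None

    def test_fixed_seed_reproduces_noise(self, small_phantom):
        t1, t2, truth = small_phantom
        a = phantom.apply_bias_and_noise(t1, t2, truth, seed=42,
                                         noise_sigma_frac=0.03)
        b = phantom.apply_bias_and_noise(t1, t2, truth, seed=42,
                                         noise_sigma_frac=0.03)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)

    def test_rician_noise_keeps_signal_nonnegative(self, small_phantom):
        t1, t2, truth = small_phantom
        t1o, _ = phantom.apply_bias_and_noise(t1, t2, truth, seed=3,
                                              noise_sigma_frac=0.05,
                                              noise_model="rician")
        assert np.all(t1o.data >= 0)

    def test_nonpositive_field_rejected(self, small_phantom):
        t1, t2, truth = small_phantom
        bad = t1.like(np.zeros(t1.shape))
        with pytest.raises(phantom.InvalidField):
            phantom.PhantomTruth(truth.tissue_labels, truth.roi_labels,
                                 truth.csf_mask, truth.spacing,
                                 receive_field=bad)


class TestMisalignment:
    def test_integer_translation_is_exact_shift(self, small_phantom):
        _, t2, _ = small_phantom
        rigid = RigidTransform((0, 0, 0), (2.0, 0.0, 0.0))
        out = phantom.apply_misalignment(t2, rigid)
        np.testing.assert_allclose(out.data[:-2], t2.data[2:], atol=1e-12)

    def test_round_trip_within_interpolation_tolerance(self, small_phantom):
        # on a smooth volume (piecewise-constant edges would dominate the
        # interpolation error), forward-then-inverse returns the original
        _, t2, _ = small_phantom
        sm = t2.like(ndimage.gaussian_filter(t2.data, 3.0))
        c = tuple((n - 1) / 2.0 for n in sm.shape)
        rigid = RigidTransform((3.0, -2.0, 1.0), (1.5, -0.5, 1.0), c)
        from cortexratio.registration import resample
        fwd = phantom.apply_misalignment(sm, rigid)
        back, valid = resample(fwd, rigid.inverse(), sm, "linear")
        interior = ndimage.binary_erosion(valid.data, iterations=3)
        dyn = np.ptp(sm.data)
        assert np.max(np.abs(back.data[interior] - sm.data[interior])) < 0.02 * dyn

    def test_excessive_transform_rejected(self, small_phantom):
        _, t2, _ = small_phantom
        with pytest.raises(ValueError):
            phantom.apply_misalignment(t2, RigidTransform((20, 0, 0), (0, 0, 0)))

    def test_out_of_fov_detected(self, standard_phantom):
        # the standard phantom fills the FOV: a 10 mm shift clips cortex
        _, t2, truth = standard_phantom
        rigid = RigidTransform((0, 0, 0), (0, 10.0, 0))
        with pytest.raises(phantom.OutOfFOV):
            phantom.apply_misalignment(t2, rigid, brain_mask=truth.gm_mask())


class TestCohortSimulation:
    def test_cohort_counts_and_determinism(self, tmp_path):
        spec = phantom.CohortSpec(
            shape=(24, 24, 24),
            geometry=phantom.PhantomGeometry(wm_radii=(6.0, 7.0, 6.5),
                                             perturb_amp=0.0),
            n_rois=4, n_per_group_per_site=1,
            groups=("Control", "HD2"), sites=("site1", "site2"),
        )
        m1 = phantom.simulate_cohort(spec, tmp_path / "a", seed=5)
        assert len(m1) == 4  # 2 groups x 2 sites x 1
        assert sorted(m1["group"].unique()) == ["Control", "HD2"]
        phantom.simulate_cohort(spec, tmp_path / "b", seed=5)
        assert phantom.manifest_checksum(tmp_path / "a") == \
            phantom.manifest_checksum(tmp_path / "b")

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = phantom.CohortSpec(effect_map={"HD2": {3: 0.05}})
        path = tmp_path / "spec.yaml"
        spec.to_yaml(str(path))
        back = phantom.CohortSpec.from_yaml(str(path))
        assert back.effect_map == {"HD2": {3: 0.05}}
        assert back.shape == spec.shape
        assert back.geometry == spec.geometry

    def test_control_group_required(self):
        spec = phantom.CohortSpec(groups=("HD1", "HD2"))
        with pytest.raises(ValueError):
            spec.validate()
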