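from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from cectkit import diffusion_pipeline as dp
from cectkit import phantom as ph
from cectkit.volume_io import AttenuationVolume


class TestSurfaceTilt:
    def test_untilted_phantom_reads_zero(self, small_spec, uptake_default):
        vol, _ = ph.generate_plug_volume(small_spec, uptake_default, 0.0)
        tx, ty = dp.estimate_surface_tilt(vol, -450.0)
        assert abs(tx) < 0.1 and abs(ty) < 0.1

    def test_known_tilt_recovered(self, uptake_default):
        spec = ph.PhantomSpec(voxel_size_um=80.0, surface_tilt_deg=(3.0, -2.0))
        vol, _ = ph.generate_plug_volume(spec, uptake_default, 0.0)
        tx, ty = dp.estimate_surface_tilt(vol, -450.0)
        assert tx == pytest.approx(3.0, abs=0.2)
        assert ty == pytest.approx(-2.0, abs=0.2)

    def test_pure_noise_has_no_surface(self, rng):
        vol = AttenuationVolume(rng.normal(0.0, 10.0, (20, 20, 20)), voxel_size_um=40.0)
        with pytest.raises(ValueError, match="no surface"):
            dp.estimate_surface_tilt(vol, -450.0)


class TestAlignment:
    def test_zero_rotation_is_identity(self, small_spec, uptake_default):
        vol, _ = ph.generate_plug_volume(small_spec, uptake_default, 24.0)
        out = dp.align_surface(vol, 0.0, 0.0)
        assert np.array_equal(out.values, vol.values)

    def test_align_then_reestimate_leaves_small_residual(self, uptake_default):
        spec = ph.PhantomSpec(voxel_size_um=80.0, surface_tilt_deg=(3.0, -2.0))
        vol, _ = ph.generate_plug_volume(spec, uptake_default, 0.0)
        aligned = dp.align_surface(vol, *dp.estimate_surface_tilt(vol, -450.0))
        rx, ry = dp.estimate_surface_tilt(aligned, -450.0)
        assert abs(rx) <= 0.2 and abs(ry) <= 0.2

    def test_rotation_inverse_composition(self, uptake_default):
        """Rotating by theta then -theta returns the interior of the volume to
        within interpolation tolerance (sharp interfaces excluded)."""
        spec = ph.PhantomSpec(voxel_size_um=80.0, noise_sd_hu=10.0, seed=1)
        vol, truth = ph.generate_plug_volume(spec, uptake_default, 24.0)
        back = dp.align_surface(dp.align_surface(vol, 3.0, -2.0), -3.0, 2.0)
        interior = ndimage.binary_erosion(truth["labels"] == 1, iterations=3)
        diff = np.abs(back.values - vol.values)[interior]
        assert diff.mean() <= 2.0 * spec.noise_sd_hu

    def test_excessive_angles_rejected(self, small_spec, uptake_default):
        vol, _ = ph.generate_plug_volume(small_spec, uptake_default, 0.0)
        with pytest.raises(ValueError):
            dp.align_surface(vol, 50.0, 0.0)


class TestSegmentation:
    def test_mask_matches_generator_truth(self, uptake_default):
        spec = ph.PhantomSpec(
            voxel_size_um=80.0, noise_sd_hu=10.0, seed=2, surface_tilt_deg=(2.0, -1.0)
        )
        vol, truth = ph.generate_plug_volume(spec, uptake_default, 24.0)
        mask = dp.segment(vol, (-500.0, 1000.0))
        assert (mask.labels == truth["labels"]).mean() >= 0.99

    def test_reversed_thresholds_rejected(self, small_spec, uptake_default):
        vol, _ = ph.generate_plug_volume(small_spec, uptake_default, 0.0)
        with pytest.raises(ValueError, match="ordered"):
            dp.segment(vol, (1000.0, -500.0))

    def test_lesion_voxels_labelled_background(self, uptake_default):
        """A fluid-filled scalpel track is excluded from the cartilage label."""
        spec = ph.PhantomSpec(voxel_size_um=40.0)
        lesion = ph.LesionSpec(kind="sharp_cut", width_at_surface_mm=0.1)
        vol, truth = ph.generate_plug_volume(spec, uptake_default, 24.0, lesions=[lesion])
        mask = dp.segment(vol, (50.0, 1000.0))
        assert (mask.labels[truth["lesion_mask"]] == 0).mean() == 1.0

    def test_no_cartilage_rejected(self, rng):
        vol = AttenuationVolume(np.full((10, 8, 8), -1000.0), voxel_size_um=40.0)
        with pytest.raises(ValueError, match="no cartilage"):
            dp.segment(vol, (-500.0, 1000.0))


class TestROIProfile:
    def test_uniform_cartilage_gives_constant_profile(self, small_spec, uptake_default):
        vol, _ = ph.generate_plug_volume(small_spec, uptake_default, 0.0)
        mask = dp.segment(vol, (-500.0, 1000.0))
        means, depths = dp.extract_roi_profile(vol, mask)
        assert np.allclose(means, small_spec.hu_cartilage, atol=1e-3)
        assert np.all(np.diff(depths) > 0)

    def test_roi_disk_is_30_voxels_wide_at_40um(self):
        """1.2 mm ROI at 40 um voxels spans 30 voxels across."""
        labels = np.zeros((5, 64, 64), dtype=np.uint8)
        labels[2] = 1
        mask = dp.SegmentationMask(labels, (-500.0, 1000.0), labels.sum(axis=0))
        disk = dp._roi_disk(mask, 1.2, 0.04)
        assert disk.sum(axis=1).max() == 30

    def test_depth_weighted_uptake_recovered_per_slice(self, small_spec):
        """Per-slice ROI means match the generator's analytic values."""
        uptake = ph.UptakeTruth(depth_weight=lambda d: d)
        vol, _ = ph.generate_plug_volume(small_spec, uptake, 72.0)
        mask = dp.segment(vol, (-500.0, 1000.0))
        means, depths = dp.extract_roi_profile(vol, mask)
        expected = small_spec.hu_cartilage + uptake.bath_hu_gain * uptake.partition(
            depths / 100.0, 72.0
        )
        assert np.max(np.abs(means - expected)) <= 0.5

    def test_roi_outside_cartilage_rejected(self, small_spec, uptake_default):
        vol, truth = ph.generate_plug_volume(small_spec, uptake_default, 0.0)
        mask = dp.segment(vol, (-500.0, 1000.0))
        empty = dp.SegmentationMask(
            np.zeros_like(mask.labels), mask.thresholds, np.zeros_like(mask.thickness_vox)
        )
        with pytest.raises(ValueError):
            dp.extract_roi_profile(vol, empty)


class TestStandardize:
    def test_constant_input_gives_constant_100_points(self):
        prof = dp.standardize_profile(np.full(7, 3.5), np.linspace(5, 95, 7))
        assert prof.values.shape == (100,)
        assert np.allclose(prof.values, 3.5)

    def test_input_on_grid_is_identity(self, rng):
        vals = rng.normal(size=100)
        prof = dp.standardize_profile(vals, dp.DEPTH_GRID_PCT)
        assert np.allclose(prof.values, vals)

    def test_linear_ramp_interpolates_exactly(self):
        native = np.array([0.5, 40.0, 99.5])
        prof = dp.standardize_profile(2.0 * native, native)
        assert np.allclose(prof.values, 2.0 * dp.DEPTH_GRID_PCT)

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError):
            dp.standardize_profile(np.array([1.0, 2.0]), np.array([10.0, 90.0]))

    @given(
        n=st.integers(3, 40),
        lo=st.floats(-30.0, 10.0),
        span=st.floats(50.0, 160.0),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_profile_always_has_100_points(self, n, lo, span, seed):
        r = np.random.default_rng(seed)
        native = np.sort(r.uniform(lo, lo + span, n))
        native += np.arange(n) * 1e-6  # enforce strict monotonicity
        prof = dp.standardize_profile(r.normal(size=n), native)
        assert prof.values.shape == (100,)


class TestPartitionAlgebra:
    def test_identical_profiles_subtract_to_zero(self, rng):
        p = dp.DepthProfile(rng.normal(size=100), units="HU")
        assert np.allclose(dp.subtract_baseline(p, p).values, 0.0)

    def test_unit_mismatch_rejected(self):
        a = dp.DepthProfile(np.zeros(100), units="HU")
        b = dp.DepthProfile(np.zeros(100), units="percent")
        with pytest.raises(ValueError, match="unit"):
            dp.subtract_baseline(a, b)

    def test_baseline_subtraction_recovers_forward_model(self, small_spec, uptake_default):
        """Noiseless t=72 minus t=0 equals bath_gain * P(z, 72) pointwise."""
        vols, truths = ph.generate_diffusion_series(
            small_spec, uptake_default, times_h=(0.0, 72.0)
        )
        profs = []
        for vol in vols:
            mask = dp.segment(vol, (-500.0, 1000.0))
            means, depths = dp.extract_roi_profile(vol, mask)
            profs.append(dp.standardize_profile(means, depths))
        contrast = dp.subtract_baseline(profs[1], profs[0])
        expected = uptake_default.bath_hu_gain * truths[1]["partition_profile_pct"]
        assert np.max(np.abs(contrast.values - expected)) <= 0.5

    def test_profile_equal_to_bath_is_100_percent(self):
        prof = dp.DepthProfile(np.full(100, 1200.0), units="HU")
        assert np.allclose(dp.to_partition(prof, 1200.0).values, 100.0)

    def test_zero_profile_is_zero_percent_and_negative_preserved(self):
        zero = dp.to_partition(dp.DepthProfile(np.zeros(100), "HU"), 800.0)
        assert np.allclose(zero.values, 0.0)
        neg = dp.to_partition(dp.DepthProfile(np.full(100, -43.8), "HU"), 1200.0)
        assert np.allclose(neg.values, -3.65)

    @given(c=st.floats(0.01, 100.0), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_partition_scale_invariance(self, c, seed):
        vals = np.random.default_rng(seed).normal(50.0, 30.0, 100)
        base = dp.to_partition(dp.DepthProfile(vals, "HU"), 1200.0)
        scaled = dp.to_partition(dp.DepthProfile(c * vals, "HU"), c * 1200.0)
        assert np.allclose(base.values, scaled.values, rtol=1e-9, atol=1e-9)

    def test_nonpositive_bath_rejected(self):
        with pytest.raises(ValueError):
            dp.to_partition(dp.DepthProfile(np.zeros(100), "HU"), 0.0)

    def test_bulk_partition_reductions(self):
        assert dp.bulk_partition(dp.DepthProfile(np.full(100, 40.0), "percent")) == 40.0
        ramp = np.linspace(0.0, 100.0, 100)
        assert dp.bulk_partition(dp.DepthProfile(ramp, "percent")) == pytest.approx(50.0)


class TestAttenuationContrast:
    def test_uniform_volume_has_zero_contrast(self, small_spec, uptake_default):
        vol, truth = ph.generate_plug_volume(small_spec, uptake_default, 0.0, medium="fluid")
        mask = dp.SegmentationMask(
            truth["labels"], (-500.0, 1000.0), (truth["labels"] == 1).sum(axis=0)
        )
        flat = AttenuationVolume(np.full(vol.shape, 50.0), vol.voxel_size_um)
        assert dp.attenuation_contrast(flat, mask) == pytest.approx(0.0)

    def test_pbs_palette_reads_printed_difference(self):
        spec = ph.PhantomSpec(voxel_size_um=80.0, hu_fluid=0.0, hu_cartilage=77.0)
        vol, truth = ph.generate_plug_volume(
            spec, ph.UptakeTruth(p_max_pct=0.0), 0.0, medium="fluid"
        )
        mask = dp.segment(vol, (38.0, 1000.0))
        assert dp.attenuation_contrast(vol, mask) == pytest.approx(77.0, abs=0.5)

    def test_no_fluid_rejected(self, small_spec, uptake_default):
        vol, truth = ph.generate_plug_volume(small_spec, uptake_default, 0.0)
        labels = truth["labels"].copy()
        labels[labels == 0] = 2  # pretend everything non-cartilage is bone
        mask = dp.SegmentationMask(labels, (-500.0, 1000.0), (labels == 1).sum(axis=0))
        with pytest.raises(ValueError, match="fluid"):
            dp.attenuation_contrast(vol, mask)


class TestEndToEnd:
    def test_noiseless_pipeline_matches_kinetics_truth(self, uptake_default):
        """Zero tilt, constant depth weight: bulk partition within 0.5 %
        absolute of the saturation formula at every time point."""
        spec = ph.PhantomSpec(voxel_size_um=80.0)
        vols, truths = ph.generate_diffusion_series(spec, uptake_default)
        series = dp.analyze_series(
            vols, [t["time_h"] for t in truths], bath_hu=uptake_default.bath_hu
        )
        truth_bulk = np.array([t["bulk_partition_pct"] for t in truths])
        assert np.max(np.abs(series.bulk_pct - truth_bulk)) <= 0.5
        assert series.bulk_pct[0] == 0.0

    def test_partition_invariant_to_global_hu_offset(self, small_spec, uptake_default):
        vols, truths = ph.generate_diffusion_series(
            small_spec, uptake_default, times_h=(0.0, 24.0, 72.0)
        )
        times = [t["time_h"] for t in truths]
        base = dp.analyze_series(vols, times, bath_hu=uptake_default.bath_hu, align=False)
        shifted = [
            AttenuationVolume(v.values + 50.0, v.voxel_size_um, dict(v.meta)) for v in vols
        ]
        moved = dp.analyze_series(shifted, times, bath_hu=uptake_default.bath_hu, align=False)
        assert np.allclose(base.profiles_pct, moved.profiles_pct, atol=1e-4)

    def test_small_tilt_does_not_change_bulk_partition(self, uptake_default):
        times = (0.0, 24.0, 72.0)
        flat = ph.PhantomSpec(voxel_size_um=40.0)
        tilted = replace(flat, surface_tilt_deg=(4.0, 3.0))
        v0, _ = ph.generate_diffusion_series(flat, uptake_default, times)
        v5, _ = ph.generate_diffusion_series(tilted, uptake_default, times)
        s0 = dp.analyze_series(v0, times, bath_hu=uptake_default.bath_hu, align=False)
        s5 = dp.analyze_series(v5, times, bath_hu=uptake_default.bath_hu)
        assert np.max(np.abs(s5.bulk_pct - s0.bulk_pct)) <= 1.0
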