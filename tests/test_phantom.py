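import math
import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import spearmanr

from cectkit import phantom as ph


class TestPlugVolume:
    def test_baseline_cartilage_is_native_attenuation(self, small_spec, uptake_default):
        vol, truth = ph.generate_plug_volume(small_spec, uptake_default, 0.0)
        cart = truth["labels"] == 1
        assert np.allclose(vol.values[cart], small_spec.hu_cartilage)
        assert truth["bulk_partition_pct"] == 0.0

    def test_partition_matches_scalar_formula_at_72h(self, small_spec, uptake_default):
        """Constant depth weight: every depth carries Pmax(1-exp(-72/tau))."""
        vol, truth = ph.generate_plug_volume(small_spec, uptake_default, 72.0)
        expected = 56.49 * (1.0 - math.exp(-72.0 / 62.85))
        assert np.allclose(truth["partition_profile_pct"], expected, atol=1e-12)
        cart = truth["labels"] == 1
        hu_expected = small_spec.hu_cartilage + uptake_default.bath_hu_gain * expected
        assert np.allclose(vol.values[cart], hu_expected, atol=1e-3)

    def test_sharp_cut_voxel_count_matches_slab_geometry(self, uptake_default):
        spec = ph.PhantomSpec(voxel_size_um=40.0)
        lesion = ph.LesionSpec(kind="sharp_cut", width_at_surface_mm=0.1)
        _, truth = ph.generate_plug_volume(spec, uptake_default, 0.0, lesions=[lesion])
        vox = spec.voxel_size_mm
        radius = spec.plug_diameter_mm / 2.0 / vox
        half = lesion.width_at_surface_mm / 2.0 / vox
        depth = lesion.depth_fraction * spec.cartilage_thickness_mm / vox
        strip_area = 2.0 * (
            half * math.sqrt(radius**2 - half**2) + radius**2 * math.asin(half / radius)
        )
        analytic = strip_area * depth
        one_layer = 2.0 * math.sqrt(radius**2 - half**2) * depth
        assert abs(int(truth["lesion_mask"].sum()) - analytic) <= one_layer

    def test_lesion_wider_than_plug_rejected(self, small_spec, uptake_default):
        lesion = ph.LesionSpec(width_at_surface_mm=5.0)
        with pytest.raises(ValueError, match="wider"):
            ph.generate_plug_volume(small_spec, uptake_default, 0.0, lesions=[lesion])

    def test_too_thin_cartilage_rejected(self, uptake_default):
        spec = ph.PhantomSpec(cartilage_thickness_mm=0.2, voxel_size_um=100.0)
        with pytest.raises(ValueError, match="thinner"):
            ph.generate_plug_volume(spec, uptake_default, 0.0)

    def test_cartilage_voxel_count_conserved_under_tilt(self, uptake_default):
        flat = ph.PhantomSpec(voxel_size_um=80.0)
        tilted = replace(flat, surface_tilt_deg=(4.0, -3.0))
        _, t0 = ph.generate_plug_volume(flat, uptake_default, 0.0)
        _, t1 = ph.generate_plug_volume(tilted, uptake_default, 0.0)
        n0 = int((t0["labels"] == 1).sum())
        n1 = int((t1["labels"] == 1).sum())
        one_slice = math.pi * (flat.plug_diameter_mm / 2.0 / flat.voxel_size_mm) ** 2
        assert abs(n0 - n1) <= one_slice


class TestDiffusionSeries:
    def test_schedule_produces_one_volume_per_time_point(self, small_spec, uptake_default):
        vols, truths = ph.generate_diffusion_series(small_spec, uptake_default)
        assert len(vols) == 8
        sat = 1.0 - np.exp(-np.asarray(ph.DEFAULT_TIMES_H) / 62.85)
        expected = 56.49 * sat
        got = np.array([t["bulk_partition_pct"] for t in truths])
        assert np.allclose(got, expected, atol=1e-12)

    def test_bulk_truth_monotone_and_concave(self, small_spec, uptake_default):
        _, truths = ph.generate_diffusion_series(small_spec, uptake_default)
        bulk = np.array([t["bulk_partition_pct"] for t in truths])
        times = np.array([t["time_h"] for t in truths])
        assert np.all(np.diff(bulk) > 0)
        rates = np.diff(bulk) / np.diff(times)
        assert np.all(np.diff(rates) < 0)

    def test_invalid_schedules_rejected(self, small_spec, uptake_default):
        with pytest.raises(ValueError):
            ph.generate_diffusion_series(small_spec, uptake_default, times_h=(0.0, 3.0, 1.0))
        with pytest.raises(ValueError):
            ph.generate_diffusion_series(small_spec, uptake_default, times_h=(1.0, 3.0))

    def test_noise_fresh_per_time_point(self, uptake_default):
        spec = ph.PhantomSpec(
            voxel_size_um=100.0, cartilage_thickness_mm=1.2, plug_diameter_mm=3.0, noise_sd_hu=10.0
        )
        vols, truths = ph.generate_diffusion_series(spec, uptake_default, times_h=(0.0, 1.0))
        assert truths[0]["seed"] != truths[1]["seed"]
        bg0 = vols[0].values[0]
        bg1 = vols[1].values[0]
        assert not np.allclose(bg0, bg1)


class TestIndentationGenerators:
    def test_beta_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            ph.ViscoTruth(beta=1.2)
        with pytest.raises(ValueError, match="beta"):
            ph.ViscoTruth(beta=0.0)

    def test_hold_force_decays_to_hayes_equilibrium(self, geometry):
        truth = ph.ViscoTruth(alpha_s=20.0, beta=1.0)
        record, summary = ph.generate_stress_relaxation(truth, geometry)
        prestress = geometry.prestress_kpa * math.pi * geometry.indenter_radius_mm**2
        for k, (_, hold_start, end) in enumerate(record.steps):
            f_end = record.force_mn[end - 1] - prestress
            # 600 s hold is 30 relaxation times: fully relaxed
            assert f_end == pytest.approx(summary["f_eq_mn"][k], rel=1e-9)

    def test_sinusoid_phase_is_loss_angle(self, geometry):
        _, truth0 = ph.generate_sinusoid(ph.ViscoTruth(eta_over_k_s=0.0), geometry)
        assert truth0["phase_shift_deg"] == 0.0
        _, truth45 = ph.generate_sinusoid(
            ph.ViscoTruth(eta_over_k_s=1.0 / (2.0 * math.pi)), geometry
        )
        assert truth45["phase_shift_deg"] == pytest.approx(45.0, abs=1e-12)

    def test_sinusoid_protocol_preconditions(self):
        with pytest.raises(ValueError):
            ph.SinusoidProtocol(n_cycles=1)
        with pytest.raises(ValueError):
            ph.SinusoidProtocol(fs_hz=20.0)


class TestCohort:
    def test_zero_noise_couplings_give_perfect_rank_correlation(self):
        spec = ph.CohortSpec(n_samples=12, noise_sd={}, seed=3)
        df = ph.generate_cohort(spec)
        assert spearmanr(df["pg_od_superficial"], df["p_max_pct"]).statistic == 1.0
        assert spearmanr(df["pg_od_superficial"], df["phase_shift_deg"]).statistic == -1.0

    def test_sign_flipped_coupling_inverts_correlation(self):
        couplings = ph._default_couplings()
        couplings["p_max_pct"] = (95.0, -32.0)
        spec = ph.CohortSpec(n_samples=12, couplings=couplings, noise_sd={}, seed=3)
        df = ph.generate_cohort(spec)
        assert spearmanr(df["latent_pg"], df["p_max_pct"]).statistic == -1.0

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            ph.CohortSpec(n_samples=2)

    def test_member_truths_reflect_row(self):
        df = ph.generate_cohort(ph.CohortSpec(n_samples=5, seed=1))
        uptake, visco = ph.cohort_member_truths(df.iloc[0])
        assert uptake.p_max_pct == df.iloc[0]["p_max_pct"]
        assert visco.e_eq_mpa == df.iloc[0]["e_eq_mpa"]
        delta = math.degrees(math.atan(2.0 * math.pi * visco.eta_over_k_s))
        assert delta == pytest.approx(df.iloc[0]["phase_shift_deg"])


class TestODSections:
    def test_flat_truth_gives_flat_noiseless_sections(self):
        sections, _, truth = ph.generate_od_section(lambda d: np.full_like(d, 1.0))
        assert np.allclose(truth["od_profile"], 1.0)
        for img in sections:
            assert np.allclose(img, img.flat[0])

    def test_out_of_range_truth_warns(self):
        with pytest.warns(UserWarning, match="calibration range"):
            ph.generate_od_section(lambda d: 2.0 + 2.0 * d)

    def test_in_range_truth_does_not_warn(self):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            ph.generate_od_section(lambda d: 0.5 + 1.0 * d)
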