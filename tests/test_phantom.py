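"""Phantom generator: template anatomy, lesion growth, forward models, cohorts."""

import numpy as np
import pytest
from scipy import ndimage

from strokemri.geometry import AcquisitionGeometry, DEFAULT_GEOMETRY
from strokemri.maps import compute_adc_map, compute_cbf_map, fit_t1_map, fit_t2_map
from strokemri.phantom import (LABELS, add_rician_noise, build_template,
                               default_group_spec, make_lesion,
                               make_tissue_field, synthesize_cohort,
                               synthesize_subject, TissueValues)
from strokemri.transforms import RigidTransform


class TestTemplate:
    def test_default_template_contains_all_six_label_classes(self, template_default):
        assert set(np.unique(template_default.labels)) == set(LABELS.values())
        for name in LABELS:
            if name != "background":
                assert template_default.label_mask(name).sum() > 0

    def test_rois_disjoint_and_in_right_hemisphere(self, template_default):
        t = template_default
        cortex, sub, vent = t.cortex_mca_mask, t.subcortex_mask, t.ventricle_mask
        assert not (cortex & sub).any()
        assert not (vent & (cortex | sub)).any()
        right = t.right_hemisphere_mask
        assert (cortex & right).sum() == cortex.sum()
        assert (sub & right).sum() == sub.sum()

    def test_hemispheres_partition_brain(self, template_small):
        t = template_small
        assert (t.left_hemisphere_mask | t.right_hemisphere_mask).sum() == t.brain_mask.sum()
        assert not (t.left_hemisphere_mask & t.right_hemisphere_mask).any()

    def test_too_small_matrix_rejected(self):
        geo = AcquisitionGeometry(matrix_size=(8, 8), fov_mm=(3.2, 3.2), n_slices=5)
        with pytest.raises(ValueError):
            build_template(geo)

    def test_bit_reproducible(self, geo_small):
        a = build_template(geo_small)
        b = build_template(geo_small)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.reference_intensity, b.reference_intensity)


class TestGeometry:
    def test_invalid_b_values_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionGeometry(b_values_s_per_mm2=(100.0, 800.0))
        with pytest.raises(ValueError):
            AcquisitionGeometry(b_values_s_per_mm2=(0.0, 0.0))

    def test_echo_train_must_cover_t2_fit(self):
        with pytest.raises(ValueError):
            AcquisitionGeometry(n_echoes=16)

    def test_echo_times_are_multiples_of_spacing(self):
        geo = DEFAULT_GEOMETRY
        assert np.allclose(geo.echo_times_ms, 4.2 * np.arange(1, 33))


class TestLesion:
    def test_zero_cortical_fraction_is_exactly_the_subcortex(self, template_small):
        les = make_lesion(template_small, cortical_fraction_2h=0.0,
                          cortical_fraction_24h=0.0)
        assert np.array_equal(les.lesion_mask_2h, template_small.subcortex_mask)

    def test_full_fractions_cover_both_rois(self, template_small):
        les = make_lesion(template_small, cortical_fraction_2h=1.0,
                          cortical_fraction_24h=1.0)
        roi = template_small.cortex_mca_mask | template_small.subcortex_mask
        assert (les.lesion_mask_24h & roi).sum() == roi.sum()

    def test_cortical_fraction_quantization(self, template_small, lesion_small):
        cortex = template_small.cortex_mca_mask
        n = cortex.sum()
        got = (lesion_small.lesion_mask_2h & cortex).sum()
        assert abs(got - 0.6 * n) <= 1.0

    @pytest.mark.parametrize("seed", range(0, 100, 1))
    def test_nestedness_over_seeds(self, template_small, seed):
        rng = np.random.default_rng(seed)
        f2, f24 = sorted(rng.uniform(0, 1, 2))
        les = make_lesion(template_small, cortical_fraction_2h=f2,
                          cortical_fraction_24h=f24,
                          subcortical_fraction_2h=rng.uniform(0, 1),
                          rng_seed=seed)
        assert not (les.lesion_mask_2h & ~les.lesion_mask_24h).any()

    def test_cortical_component_connected(self, template_small):
        les = make_lesion(template_small, cortical_fraction_2h=0.4,
                          cortical_fraction_24h=0.8, rng_seed=11)
        part = les.lesion_mask_2h & template_small.cortex_mca_mask
        _, n_cc = ndimage.label(part)
        assert n_cc == 1

    def test_lesion_confined_to_ipsilateral_hemisphere(self, template_small, lesion_small):
        assert not (lesion_small.lesion_mask_24h
                    & ~template_small.right_hemisphere_mask).any()

    def test_invalid_fraction_rejected(self, template_small):
        with pytest.raises(ValueError):
            make_lesion(template_small, cortical_fraction_2h=1.2)


class TestTissueField:
    def test_margins_enforced_around_threshold(self, template_small, lesion_small):
        with pytest.raises(ValueError):
            make_tissue_field(template_small, lesion_small.lesion_mask_24h,
                              TissueValues(t2_infarct_ms=33.5))
        with pytest.raises(ValueError):
            make_tissue_field(template_small, lesion_small.lesion_mask_24h,
                              TissueValues(t2_healthy_ms=35.0))

    def test_fields_positive_inside_brain(self, template_small, tissue_small):
        brain = template_small.brain_mask
        for name in ("t2_ms", "t1_ms", "adc_mm2_per_s", "cbf_ml_per_100g_min", "s0"):
            assert (tissue_small.field(name)[brain] > 0).all(), name


class TestSynthesizeSubject:
    def test_noise_free_round_trip_all_maps(self, template_small, lesion_small, tissue_small):
        geo = template_small.geometry
        raw = synthesize_subject(template_small, lesion_small, tissue_small,
                                 noise_sigma=0.0)
        brain = template_small.brain_mask

        t2 = fit_t2_map(raw.echo_train, geo.echo_times_ms, 20, mask=brain)
        rel = np.abs(t2.values[brain] - tissue_small.t2_ms[brain]) / tissue_small.t2_ms[brain]
        assert np.nanmax(rel) < 1e-6 and t2.validity_mask[brain].all()

        adc = compute_adc_map(raw.dwi_b0, raw.dwi_b800, geo.b_value_s_per_mm2, mask=brain)
        rel = np.abs(adc.values[brain] - tissue_small.adc_mm2_per_s[brain]) / tissue_small.adc_mm2_per_s[brain]
        assert np.nanmax(rel) < 1e-6

        t1 = fit_t1_map(raw.ir_series, np.asarray(geo.ir_inversion_times_ms), mask=brain)
        rel = np.abs(t1.values[brain] - tissue_small.t1_ms[brain]) / tissue_small.t1_ms[brain]
        assert np.nanmax(rel) < 1e-6 and t1.validity_mask[brain].all()

        cbf = compute_cbf_map(raw.casl_control, raw.casl_label, t1, mask=brain)
        rel = np.abs(cbf.values[brain] - tissue_small.cbf_ml_per_100g_min[brain]) / tissue_small.cbf_ml_per_100g_min[brain]
        assert np.nanmax(rel) < 1e-6

    def test_magnitude_images_non_negative(self, template_small, lesion_small, tissue_small):
        raw = synthesize_subject(template_small, lesion_small, tissue_small,
                                 noise_sigma=50.0, seed=3)
        for vol in (raw.echo_train, raw.dwi_b0, raw.dwi_b800,
                    raw.casl_control, raw.casl_label, raw.ir_series):
            assert (vol >= 0).all()

    def test_rician_background_mean_is_rayleigh(self):
        sigma = 10.0
        rng = np.random.default_rng(0)
        bg = add_rician_noise(np.zeros((50, 50, 20)), sigma, rng)
        assert np.isclose(bg.mean(), sigma * np.sqrt(np.pi / 2), rtol=0.01)

    def test_negative_sigma_rejected(self, template_small, lesion_small, tissue_small):
        with pytest.raises(ValueError):
            synthesize_subject(template_small, lesion_small, tissue_small,
                               noise_sigma=-1.0)

    def test_same_seed_bit_identical(self, template_small, lesion_small, tissue_small):
        a = synthesize_subject(template_small, lesion_small, tissue_small,
                               noise_sigma=20.0, seed=7)
        b = synthesize_subject(template_small, lesion_small, tissue_small,
                               noise_sigma=20.0, seed=7)
        assert np.array_equal(a.echo_train, b.echo_train)
        assert np.array_equal(a.casl_label, b.casl_label)
        c = synthesize_subject(template_small, lesion_small, tissue_small,
                               noise_sigma=20.0, seed=8)
        assert not np.array_equal(a.echo_train, c.echo_train)

    def test_misaligned_subject_moves_brain(self, template_small, lesion_small, tissue_small):
        pose = RigidTransform((0.0, 0.0, 0.0), (2.0, 0.0, 0.0),
                              template_small.geometry.center_mm)
        raw = synthesize_subject(template_small, lesion_small, tissue_small,
                                 misalignment=pose)
        assert not np.array_equal(raw.brain_mask, template_small.brain_mask)
        assert abs(int(raw.brain_mask.sum()) - int(template_small.brain_mask.sum())) < 80


class TestCohort:
    def test_degenerate_zero_variance_gives_identical_subjects(self, template_small):
        spec = default_group_spec(
            "C57Bl/6", n_subjects=3, between_subject_cv=0.0, t2_cv=0.0, t1_cv=0.0,
            snr=None, misaligned=False,
            lesion_fractions={tp: {"cortical": (0.6, 0.0), "subcortical": (1.0, 0.0)}
                              for tp in ("2h", "24h")})
        cohort = synthesize_cohort(spec, template_small, master_seed=1)
        ref = cohort[0].raw["24h"].echo_train
        for s in cohort[1:]:
            assert np.array_equal(s.raw["24h"].echo_train, ref)

    def test_same_master_seed_bit_identical(self, template_small):
        spec = default_group_spec("Sv/129", n_subjects=2, misaligned=True, snr=40.0)
        a = synthesize_cohort(spec, template_small, master_seed=42)
        b = synthesize_cohort(spec, template_small, master_seed=42)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.raw["2h"].echo_train, sb.raw["2h"].echo_train)
            assert np.array_equal(sa.lesion.lesion_mask_24h, sb.lesion.lesion_mask_24h)
            assert sa.misalignment["2h"].to_dict() == sb.misalignment["2h"].to_dict()

    def test_subjects_differ_and_pair_across_timepoints(self, template_small):
        spec = default_group_spec("C57Bl/6", n_subjects=2, snr=40.0, misaligned=False)
        cohort = synthesize_cohort(spec, template_small, master_seed=3)
        assert not np.array_equal(cohort[0].raw["24h"].echo_train,
                                  cohort[1].raw["24h"].echo_train)
        for s in cohort:
            assert set(s.raw) == {"2h", "24h"}
            assert not (s.lesion.lesion_mask_2h & ~s.lesion.lesion_mask_24h).any()

    def test_subject_tissue_parameters_longitudinally_stable(self, template_small):
        spec = default_group_spec("C57Bl/6", n_subjects=2, snr=None, misaligned=False)
        cohort = synthesize_cohort(spec, template_small, master_seed=9)
        for s in cohort:
            v2, v24 = s.tissue_values["2h"], s.tissue_values["24h"]
            assert v2.t2_healthy_ms == v24.t2_healthy_ms
            assert v2.s0_tissue == v24.s0_tissue

    def test_rejects_empty_group(self):
        with pytest.raises(ValueError):
            default_group_spec("C57Bl/6", n_subjects=0)
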