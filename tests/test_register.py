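"""Rigid transforms, resampling, brain extraction and 6-DOF registration."""

import numpy as np
import pytest

from strokemri.maps import QuantitativeMap, fit_t2_map
from strokemri.phantom import make_tissue_field, synthesize_subject
from strokemri.register import extract_brain, register_rigid, to_atlas
from strokemri.transforms import (RigidTransform, resample, resample_series,
                                  resample_validity)

SPEC_POSE = ((3.0, 2.0, -4.0), (1.2, -0.8, 0.4))


def _dice(a, b):
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


class TestRigidTransform:
    @pytest.mark.parametrize("seed", range(10))
    def test_compose_with_inverse_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        t = RigidTransform(tuple(rng.uniform(-20, 20, 3)),
                           tuple(rng.uniform(-5, 5, 3)),
                           (12.0, 12.0, 6.0))
        ident = t.compose(t.inverse())
        assert max(abs(a) for a in ident.rotations_deg) < 1e-10
        assert max(abs(v) for v in ident.translations_mm) < 1e-10

    def test_matrix_round_trip(self):
        t = RigidTransform((5.0, -3.0, 8.0), (1.0, 2.0, -0.5), (10.0, 10.0, 5.0))
        back = RigidTransform.from_matrix(t.matrix(), t.center_mm)
        assert np.allclose(back.rotations_deg, t.rotations_deg)
        assert np.allclose(back.translations_mm, t.translations_mm)

    def test_compose_order_applies_other_first(self):
        ta = RigidTransform((0, 0, 90.0), (0, 0, 0), (0, 0, 0))
        tb = RigidTransform((0, 0, 0), (1.0, 0, 0), (0, 0, 0))
        # apply tb (shift +x) then ta (rotate 90 deg about z): x -> y
        p = ta.compose(tb).apply(np.zeros((1, 3)))
        assert np.allclose(p, [[0.0, 1.0, 0.0]], atol=1e-12)

    def test_json_round_trip(self, tmp_path):
        t = RigidTransform((1.5, -2.0, 0.25), (0.1, 0.2, -0.3), (12.0, 12.0, 6.0))
        path = tmp_path / "xfm.json"
        t.to_json(path)
        assert RigidTransform.from_json(path) == t


class TestResample:
    def test_identity_nearest_bit_exact(self, template_small):
        geo = template_small.geometry
        t = RigidTransform.identity(geo.center_mm)
        out = resample(template_small.reference_intensity, t, geo, geo, "nearest")
        assert np.array_equal(out, template_small.reference_intensity)

    def test_integer_voxel_shift_round_trip(self, template_small):
        geo = template_small.geometry
        dx = geo.spacing_mm[0]
        fwd = RigidTransform((0, 0, 0), (dx, 0, 0), geo.center_mm)
        vol = template_small.reference_intensity
        shifted = resample(vol, fwd, geo, geo, "nearest")
        back = resample(shifted, fwd.inverse(), geo, geo, "nearest")
        interior = np.zeros(vol.shape, bool)
        interior[2:-2] = True
        assert np.array_equal(back[interior], vol[interior])

    def test_label_volume_guarded_against_trilinear(self, template_small):
        geo = template_small.geometry
        t = RigidTransform((1.0, 0, 0), (0, 0, 0), geo.center_mm)
        with pytest.raises(ValueError, match="label"):
            resample(template_small.labels, t, geo, geo, "trilinear")
        # explicit opt-in works
        resample(template_small.labels, t, geo, geo, "trilinear",
                 allow_label_trilinear=True)

    def test_unknown_interpolation_rejected(self, template_small):
        geo = template_small.geometry
        with pytest.raises(ValueError, match="interpolation"):
            resample(template_small.reference_intensity,
                     RigidTransform.identity(geo.center_mm), geo, geo, "cubic")

    def test_out_of_field_voxels_flagged(self, template_small):
        geo = template_small.geometry
        t = RigidTransform((0, 0, 0), (5.0, 0, 0), geo.center_mm)
        valid = resample_validity(t, geo, geo)
        assert valid.sum() < valid.size
        assert valid.any()

    def test_series_resamples_every_frame(self, template_small):
        geo = template_small.geometry
        vol4 = np.stack([template_small.reference_intensity] * 3, axis=-1)
        t = RigidTransform.identity(geo.center_mm)
        out = resample_series(vol4, t, geo, geo)
        assert out.shape == vol4.shape


class TestExtractBrain:
    def test_ground_truth_passthrough(self, template_small):
        bm = extract_brain(None, "ground_truth", template_small.brain_mask)
        assert np.array_equal(bm.mask, template_small.brain_mask)
        assert bm.source == "ground_truth"

    def test_automatic_matches_ground_truth_on_clean_phantom(self, template_small):
        bm = extract_brain(template_small.reference_intensity, "automatic")
        assert _dice(bm.mask, template_small.brain_mask) >= 0.98

    def test_all_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            extract_brain(np.zeros((16, 16, 4)), "automatic")


@pytest.fixture(scope="module")
def posed_subject(template_default, healthy_tissue_default):
    geo = template_default.geometry
    pose = RigidTransform(*SPEC_POSE, geo.center_mm)
    raw = synthesize_subject(template_default, None, healthy_tissue_default,
                             noise_sigma=0.0, misalignment=pose, seed=1)
    return pose, raw


class TestRegistration:
    def test_self_registration_is_identity(self, template_small):
        geo = template_small.geometry
        res = register_rigid(template_small.reference_intensity,
                             template_small.reference_intensity,
                             template_small.brain_mask, template_small.brain_mask,
                             geo, geo)
        assert max(abs(a) for a in res.transform.rotations_deg) < 1e-3
        assert max(abs(v) for v in res.transform.translations_mm) < 1e-3

    def test_known_displacement_recovered_noise_free(self, template_default,
                                                     posed_subject):
        geo = template_default.geometry
        pose, raw = posed_subject
        res = register_rigid(raw.echo_train[..., 0],
                             template_default.reference_intensity,
                             raw.brain_mask, template_default.brain_mask, geo, geo)
        rot_err = np.abs(np.subtract(res.transform.rotations_deg, pose.rotations_deg))
        trans_err_vox = np.abs(np.subtract(res.transform.translations_mm,
                                           pose.translations_mm)) / geo.spacing_mm
        assert rot_err.max() < 0.25
        assert trans_err_vox.max() < 0.1

    def test_known_displacement_recovered_at_snr40(self, template_default,
                                                   healthy_tissue_default):
        geo = template_default.geometry
        pose = RigidTransform(*SPEC_POSE, geo.center_mm)
        sigma = healthy_tissue_default.values.s0_tissue / 40.0
        raw = synthesize_subject(template_default, None, healthy_tissue_default,
                                 noise_sigma=sigma, misalignment=pose, seed=2)
        res = register_rigid(raw.echo_train[..., 0],
                             template_default.reference_intensity,
                             raw.brain_mask, template_default.brain_mask, geo, geo)
        rot_err = np.abs(np.subtract(res.transform.rotations_deg, pose.rotations_deg))
        trans_err_vox = np.abs(np.subtract(res.transform.translations_mm,
                                           pose.translations_mm)) / geo.spacing_mm
        assert rot_err.max() < 1.0
        assert trans_err_vox.max() < 0.5

    def test_forward_backward_consistency(self, template_default, posed_subject):
        geo = template_default.geometry
        _, raw = posed_subject
        moving = raw.echo_train[..., 0]
        fixed = template_default.reference_intensity
        fwd = register_rigid(moving, fixed, raw.brain_mask,
                             template_default.brain_mask, geo, geo).transform
        bwd = register_rigid(fixed, moving, template_default.brain_mask,
                             raw.brain_mask, geo, geo).transform
        ident = fwd.compose(bwd)
        assert max(abs(a) for a in ident.rotations_deg) < 0.5
        trans_vox = np.abs(ident.translations_mm) / geo.spacing_mm
        assert trans_vox.max() < 0.2

    def test_metric_never_degrades(self, template_default, posed_subject):
        geo = template_default.geometry
        _, raw = posed_subject
        res = register_rigid(raw.echo_train[..., 0],
                             template_default.reference_intensity,
                             raw.brain_mask, template_default.brain_mask, geo, geo)
        assert res.metric_final >= res.metric_initial - 1e-12

    def test_constant_image_rejected(self, template_small):
        geo = template_small.geometry
        flat = np.ones(geo.shape)
        with pytest.raises(ValueError):
            register_rigid(flat, template_small.reference_intensity,
                           template_small.brain_mask, template_small.brain_mask,
                           geo, geo)

    def test_empty_mask_rejected(self, template_small):
        geo = template_small.geometry
        with pytest.raises(ValueError):
            register_rigid(template_small.reference_intensity,
                           template_small.reference_intensity,
                           np.zeros(geo.shape, bool), template_small.brain_mask,
                           geo, geo)


class TestToAtlas:
    def test_identity_round_trip_and_contract(self, template_small, tissue_small):
        geo = template_small.geometry
        brain = template_small.brain_mask
        maps = {name: QuantitativeMap(tissue_small.field(f), u, brain)
                for name, f, u in (("t2", "t2_ms", "ms"),
                                   ("adc", "adc_mm2_per_s", "mm^2/s"),
                                   ("cbf", "cbf_ml_per_100g_min", "mL/100g/min"))}
        ident = RigidTransform.identity(geo.center_mm)
        out_maps, out_masks = to_atlas(maps, ident, template_small, geo,
                                       masks={"brain": brain})
        assert set(out_maps) == {"t2", "adc", "cbf"}
        for name, m in out_maps.items():
            assert m.shape == template_small.shape
            assert np.nanmax(np.abs(m.values[brain] - maps[name].values[brain])) < 1e-6
        assert np.array_equal(out_masks["brain"], brain)

    def test_misaligned_lesion_recovered_after_registration(
            self, template_default):
        from strokemri.lesion import segment_infarct_t2
        from strokemri.phantom import make_lesion

        geo = template_default.geometry
        lesion = make_lesion(template_default, 0.6, 0.95, rng_seed=4)
        tissue = make_tissue_field(template_default, lesion.lesion_mask_24h)
        pose = RigidTransform((4.0, -3.0, 2.5), (0.5, -0.6, 0.3), geo.center_mm)
        sigma = tissue.values.s0_tissue / 40.0
        raw = synthesize_subject(template_default, lesion, tissue,
                                 noise_sigma=sigma, misalignment=pose, seed=9)
        t2 = fit_t2_map(raw.echo_train, geo.echo_times_ms, 20, mask=raw.brain_mask)
        seg = segment_infarct_t2(t2, 34.0, raw.brain_mask)
        est = register_rigid(raw.echo_train[..., 0],
                             template_default.reference_intensity,
                             raw.brain_mask & ~seg.mask,
                             template_default.brain_mask, geo, geo).transform
        _, masks = to_atlas({}, est, template_default, geo,
                            masks={"lesion": seg.mask})
        assert _dice(masks["lesion"], lesion.lesion_mask_24h) >= 0.95
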