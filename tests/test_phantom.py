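"""Phantom generator: anatomy partition, intensity model, artifact injection."""
import dataclasses

import numpy as np
import pytest
from scipy import stats

from radpath import (
    PhantomSpec,
    apply_artifacts,
    make_anatomy,
    make_phantom_case,
    synthesize_histology,
    synthesize_mri,
)
from radpath.phantom import LABEL_OF, REGIONS, SliceArtifact


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(shrink_factor=1.0)
    with pytest.raises(ValueError):
        PhantomSpec(max_rotation_deg=-1)
    with pytest.raises(ValueError):
        PhantomSpec(translation_frac=0.5)
    with pytest.raises(ValueError):
        PhantomSpec(n_slices=1)
    means = dict(PhantomSpec().region_mri_means)
    means["cancer"] = means["prostate"]
    with pytest.raises(ValueError):
        PhantomSpec(region_mri_means=means)


def test_anatomy_partitions_grid():
    anatomy = make_anatomy(PhantomSpec())
    total = sum(anatomy.masks[r].astype(int) for r in REGIONS)
    assert (total == 1).all(), "region masks must tile the grid exactly once"


def test_anatomy_structure():
    anatomy = make_anatomy(PhantomSpec())
    prostate = anatomy.masks["prostate_any"]
    for i in range(anatomy.labels.shape[0]):
        assert prostate[i].any()
        urethra_area = anatomy.masks["urethra"][i].sum()
        assert 0 < urethra_area < 0.02 * prostate[i].sum()
    # apex/base taper: outer slices are smaller than the middle one
    areas = prostate.sum(axis=(1, 2))
    assert areas[0] < areas.max() and areas[-1] < areas.max()
    # substructures are inside the gland and mutually exclusive by precedence
    assert not (anatomy.masks["urethra"] & anatomy.masks["cancer"]).any()
    assert (anatomy.masks["cancer"] <= prostate).all()


def test_anatomy_two_slices_taper():
    anatomy = make_anatomy(PhantomSpec(n_slices=2))
    a0 = anatomy.masks["prostate_any"][0].sum()
    a1 = anatomy.masks["prostate_any"][1].sum()
    assert a0 > 0 and a1 > 0


def test_degenerate_spec_names_slice():
    with pytest.raises(ValueError, match="slice"):
        make_anatomy(PhantomSpec(n_slices=14))


def test_mri_zero_noise_is_piecewise_constant():
    spec = PhantomSpec(noise_sd=0.0)
    anatomy = make_anatomy(spec)
    mri = synthesize_mri(anatomy, spec)
    for region in REGIONS:
        sel = anatomy.masks[region]
        assert (mri.image[sel] == spec.region_mri_means[region]).all()


def test_mri_noise_clt():
    spec = PhantomSpec(noise_sd=10.0, seed=11)
    anatomy = make_anatomy(spec)
    mri = synthesize_mri(anatomy, spec)
    for region in REGIONS:
        sel = anatomy.masks[region]
        n = sel.sum()
        err = abs(mri.image[sel].mean() - spec.region_mri_means[region])
        assert err < 3 * 10.0 / np.sqrt(n), region


def test_mri_determinism():
    a = synthesize_mri(make_anatomy(PhantomSpec(seed=3)), PhantomSpec(seed=3))
    b = synthesize_mri(make_anatomy(PhantomSpec(seed=3)), PhantomSpec(seed=3))
    assert (a.image == b.image).all() and (a.mask == b.mask).all()


def test_histology_zero_noise_color_count():
    spec = PhantomSpec(noise_sd=0.0)
    anatomy = make_anatomy(spec)
    stack = synthesize_histology(anatomy, spec)
    for i, sl in enumerate(stack.slices):
        present = {int(v) for v in np.unique(anatomy.labels[i])}
        colors = np.unique(sl.image.reshape(-1, 3), axis=0)
        assert len(colors) == len(present)


def test_histology_mask_matches_mri_when_no_offset():
    spec = PhantomSpec(noise_sd=0.0)
    anatomy = make_anatomy(spec)
    stack = synthesize_histology(anatomy, spec)
    for i, sl in enumerate(stack.slices):
        assert (sl.mask == anatomy.masks["prostate_any"][i]).all()


def test_slice_offset_changes_masks_and_urethra():
    base = PhantomSpec(noise_sd=0.0)
    off = PhantomSpec(noise_sd=0.0, slice_offset_mm=2.0)
    anatomy = make_anatomy(base)
    s0 = synthesize_histology(anatomy, base)
    s2 = synthesize_histology(make_anatomy(off), off)
    any_mask_differs = any(
        (a.mask != b.mask).any() for a, b in zip(s0.slices, s2.slices))
    assert any_mask_differs
    # the tilted urethra moves visibly with the out-of-plane offset
    u0 = np.argwhere(s0.slices[0].labels["urethra"]).mean(axis=0)
    u2 = np.argwhere(s2.slices[0].labels["urethra"]).mean(axis=0)
    assert np.linalg.norm(u0 - u2) > 1.0


class TestApplyArtifacts:
    def _clean_stack(self, **kw):
        spec = PhantomSpec(noise_sd=0.0, **kw)
        return synthesize_histology(make_anatomy(spec), spec), spec

    def test_identity_condition_roundtrips_exactly(self):
        stack, spec = self._clean_stack()
        out, truth = apply_artifacts(stack, spec)
        for a, b, t in zip(stack.slices, out.slices, truth.per_slice):
            assert (a.image == b.image).all()
            assert (a.mask == b.mask).all()
            assert t.angle_deg == 0 and t.scale == 1.0 and t.translation == (0, 0)

    def test_rotation_only_ranges(self):
        stack, spec = self._clean_stack(max_rotation_deg=20.0, seed=5)
        _, truth = apply_artifacts(stack, spec)
        for t in truth.per_slice:
            assert -20.0 <= t.angle_deg <= 20.0
            assert t.scale == 1.0
            assert t.translation == (0.0, 0.0), "rotation-only runs stay untranslated"

    def test_shrinkage_scales_mask_area(self):
        stack, spec = self._clean_stack(shrink_factor=0.2, seed=6)
        out, truth = apply_artifacts(stack, spec)
        for a, b, t in zip(stack.slices, out.slices, truth.per_slice):
            assert t.scale == pytest.approx(0.8)
            ratio = b.mask.sum() / a.mask.sum()
            assert ratio == pytest.approx(0.64, rel=0.02)
            # translation rides along with shrinkage, bounded by 5% of width
            width_mm = a.mask.shape[1] * 0.4
            assert all(abs(v) <= 0.05 * width_mm for v in t.translation)

    def test_artifact_inversion_recovers_mask(self):
        stack, spec = self._clean_stack(max_rotation_deg=20.0, shrink_factor=0.15,
                                        seed=8)
        out, truth = apply_artifacts(stack, spec)
        import SimpleITK as sitk
        from radpath.core import to_sitk2d
        for orig, warped, art in zip(stack.slices, out.slices, truth.per_slice):
            img = to_sitk2d(warped.mask.astype(np.float32), stack.pixel_size)
            fwd = art.point_map()  # resampling with the forward map inverts the warp
            rec = sitk.GetArrayFromImage(
                sitk.Resample(img, img, fwd, sitk.sitkNearestNeighbor, 0.0)) > 0.5
            inter = np.logical_and(rec, orig.mask).sum()
            dice = 2 * inter / (rec.sum() + orig.mask.sum())
            assert dice >= 0.98

    def test_angle_draws_are_uniform(self):
        spec = PhantomSpec(in_plane_size=64, mri_spacing=(1.6, 1.6, 4.0),
                           max_rotation_deg=25.0, noise_sd=0.0)
        stack = synthesize_histology(make_anatomy(spec), spec)
        angles = []
        for k in range(180):
            _, truth = apply_artifacts(
                stack, dataclasses.replace(spec, seed=k))
            angles += [t.angle_deg for t in truth.per_slice]
        assert len(angles) >= 1000
        ks = stats.kstest(angles, stats.uniform(loc=-25, scale=50).cdf)
        assert ks.pvalue > 0.01

    def test_landmarks_follow_the_artifact(self):
        stack, spec = self._clean_stack(max_rotation_deg=30.0, seed=9)
        out, truth = apply_artifacts(stack, spec)
        for orig, warped, art in zip(stack.slices, out.slices, truth.per_slice):
            for name, p in orig.landmarks.items():
                assert warped.landmarks[name] == pytest.approx(
                    art.apply_point(p), abs=1e-9)


def test_case_determinism():
    a = make_phantom_case(PhantomSpec(max_rotation_deg=10.0, seed=21))
    b = make_phantom_case(PhantomSpec(max_rotation_deg=10.0, seed=21))
    assert (a.mri.image == b.mri.image).all()
    for sa, sb in zip(a.stack.slices, b.stack.slices):
        assert (sa.image == sb.image).all()
    assert all(x.angle_deg == y.angle_deg
               for x, y in zip(a.truth.per_slice, b.truth.per_slice))


def test_flip_simulation_records_flag():
    spec = PhantomSpec(noise_sd=0.0, flip_lr=True)
    stack = synthesize_histology(make_anatomy(spec), spec)
    out, truth = apply_artifacts(stack, spec)
    assert all(t.flip for t in truth.per_slice)
    for a, b in zip(stack.slices, out.slices):
        assert (b.mask == a.mask[:, ::-1]).all()
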