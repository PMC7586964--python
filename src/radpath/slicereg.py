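"""Per-slice MRI-to-histology registration: masked affine, then free-form
(B-spline) deformable refinement.

Both stages run on a three-level multi-resolution pyramid (shrink factors
16/8/4, smoothing sigmas 4/2/1 pixels).  The affine stage sees only the
binary prostate masks and minimizes their sum of squared differences with
gradient descent (learning rate 0.01, 250 iterations per level), starting
from a moment-based similarity initialization (centroid + area-ratio scale +
exhaustive rotation search) that supplies the global pose plain descent
cannot reach.  The deformable stage optimizes a cubic B-spline displacement
field under Mattes mutual information with an LBFGSB optimizer (10
iterations per level) whose box constraints keep the field stiff.

Transforms map fixed-frame (histology) points to moving-frame (MRI) points,
the ITK resampling convention; the deformable is applied before the affine
(p_mri = affine(deformable(p_hist))).
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import SimpleITK as sitk

from .core import (
    AffineTransform2D,
    DeformableField2D,
    HistologySlice,
    HistologyStack,
    MriVolume,
    RigidTransform2D,
    SliceTransformChain,
    to_sitk2d,
)
from .reconstruct import initialize_similarity, reconstruct_stack

logger = logging.getLogger("radpath.slicereg")


@dataclass(frozen=True)
class RegistrationConfig:
    """Tunable knobs of the two-stage slice registration."""

    pyramid_shrink: Tuple[int, ...] = (16, 8, 4)
    pyramid_sigma: Tuple[float, ...] = (4.0, 2.0, 1.0)   # pixels
    affine_learning_rate: float = 0.01
    affine_iterations: int = 250
    deformable_iterations: int = 10
    mi_bins: int = 32
    bspline_mesh: int = 6              # control points per axis (fixed across levels:
                                       # LBFGSB box constraints require a constant
                                       # parameter count through the pyramid)
    displacement_cap_frac: float = 0.10  # of image width, per component
    angle_search_range_deg: float = 90.0
    deformable_use_mask: bool = True   # run MI on the masked grayscale images

    def __post_init__(self):
        if len(self.pyramid_shrink) != len(self.pyramid_sigma):
            raise ValueError("pyramid shrink and sigma lists must have equal length")
        if min(self.pyramid_shrink) < 1 or self.affine_iterations < 1 \
                or self.deformable_iterations < 1 or self.mi_bins < 2 \
                or self.bspline_mesh < 2:
            raise ValueError("pyramid, iteration, bin and mesh counts must be positive")

    @property
    def n_levels(self) -> int:
        return len(self.pyramid_shrink)


# ---------------------------------------------------------------------------
# preprocessing

def _rotate_slice(sl: HistologySlice, angle_deg: float,
                  spacing: Tuple[float, float]) -> HistologySlice:
    from .core import grid_center_mm
    center = grid_center_mm(sl.mask.shape, spacing)
    rot = RigidTransform2D(angle_deg=angle_deg, center=center)
    inv = rot.inverse().to_sitk()

    def res(arr, nearest):
        img = to_sitk2d(np.asarray(arr, np.float32), spacing)
        interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear
        return sitk.GetArrayFromImage(sitk.Resample(img, img, inv, interp, 0.0))

    rgb = np.stack([res(sl.image[..., c], False) for c in range(3)], -1)
    return HistologySlice(
        image=np.clip(np.rint(rgb), 0, 255).astype(np.uint8),
        mask=res(sl.mask, True) > 0.5,
        labels={k: res(v, True) > 0.5 for k, v in sl.labels.items()},
        landmarks={k: rot.apply(p) for k, p in sl.landmarks.items()},
    )


def _flip_slice(sl: HistologySlice, spacing: Tuple[float, float]) -> HistologySlice:
    from .core import grid_center_mm
    cx = grid_center_mm(sl.mask.shape, spacing)[0]
    return HistologySlice(
        image=sl.image[:, ::-1].copy(),
        mask=sl.mask[:, ::-1].copy(),
        labels={k: v[:, ::-1].copy() for k, v in sl.labels.items()},
        landmarks={k: (2 * cx - p[0], p[1]) for k, p in sl.landmarks.items()},
    )


def preprocess(mri: MriVolume, stack: HistologyStack,
               gross_rotation_deg: Optional[Sequence[float]] = None,
               flip_lr: Optional[Sequence[bool]] = None
               ) -> Tuple[List[np.ndarray], HistologyStack]:
    """Masked inputs with expert-stated gross rotation / left-right flip applied.

    Returns per-section masked MRI slices (selected through the
    correspondence table, intensities zeroed outside the prostate) and a
    histology stack whose images are zeroed outside the prostate mask with
    the stated flips/rotations applied to images, masks, labels and
    landmarks alike.  The gross corrections are expert inputs, never
    estimated here.
    """
    d = stack.n_slices
    rotation = list(gross_rotation_deg) if gross_rotation_deg is not None else [0.0] * d
    flips = list(flip_lr) if flip_lr is not None else [False] * d
    if len(rotation) != d or len(flips) != d:
        raise ValueError("gross rotation / flip tables must have one entry per slice")
    for j in stack.correspondence:
        if not (0 <= j < mri.n_slices):
            raise ValueError(f"correspondence references nonexistent MRI slice {j}")

    mri_slices = []
    for j in stack.correspondence:
        sl = mri.image[j].astype(np.float32).copy()
        sl[~mri.mask[j]] = 0.0
        mri_slices.append(sl)

    out = []
    for i, sl in enumerate(stack.slices):
        s = sl
        if flips[i]:
            s = _flip_slice(s, stack.pixel_size)
        if rotation[i] != 0.0:
            s = _rotate_slice(s, rotation[i], stack.pixel_size)
        img = s.image.copy()
        img[~s.mask] = 0
        out.append(dataclasses.replace(s, image=img))
    pstack = HistologyStack(slices=out, pixel_size=stack.pixel_size,
                            correspondence=list(stack.correspondence))
    return mri_slices, pstack


# ---------------------------------------------------------------------------
# affine stage (masks only)

def register_affine(fixed_mask: np.ndarray, moving_mask: np.ndarray,
                    spacing: Tuple[float, float],
                    config: Optional[RegistrationConfig] = None) -> AffineTransform2D:
    """Affine minimizing SSD between the prostate masks over the pyramid.

    ``fixed_mask`` is the (reconstructed) histology mask, ``moving_mask``
    the MRI mask; grayscale intensities are never consulted.
    """
    config = config or RegistrationConfig()
    if not np.any(fixed_mask):
        raise ValueError("fixed (histology) mask is empty")
    if not np.any(moving_mask):
        raise ValueError("moving (MRI) mask is empty")

    init = initialize_similarity(fixed_mask, moving_mask, spacing, with_scale=True,
                                 search_range_deg=config.angle_search_range_deg)
    affine = sitk.AffineTransform(2)
    affine.SetCenter(init.GetCenter())
    th, s = init.GetAngle(), init.GetScale()
    affine.SetMatrix((s * np.cos(th), -s * np.sin(th), s * np.sin(th), s * np.cos(th)))
    affine.SetTranslation(init.GetTranslation())

    fixed = to_sitk2d(np.asarray(fixed_mask, np.float32), spacing)
    moving = to_sitk2d(np.asarray(moving_mask, np.float32), spacing)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetShrinkFactorsPerLevel(list(config.pyramid_shrink))
    reg.SetSmoothingSigmasPerLevel(list(config.pyramid_sigma))
    reg.SetSmoothingSigmasAreSpecifiedInPhysicalUnits(False)
    reg.SetInitialTransform(affine, inPlace=True)
    reg.SetOptimizerAsGradientDescent(
        learningRate=config.affine_learning_rate,
        numberOfIterations=config.affine_iterations,
        estimateLearningRate=reg.Never)
    reg.SetOptimizerScalesFromPhysicalShift()
    try:
        reg.Execute(fixed, moving)
    except RuntimeError as exc:  # pragma: no cover
        logger.warning("affine optimizer failed (%s); keeping initializer", exc)

    result = AffineTransform2D.from_sitk(affine)
    det = np.linalg.det(np.asarray(result.matrix))
    if abs(det) < 1e-3:
        logger.warning("degenerate affine (det=%.2e); clamping to initializer", det)
        result = AffineTransform2D(
            matrix=((s * np.cos(th), -s * np.sin(th)), (s * np.sin(th), s * np.cos(th))),
            translation=tuple(init.GetTranslation()), center=tuple(init.GetCenter()))
    return result


# ---------------------------------------------------------------------------
# deformable stage (Mattes MI on grayscale)

def _mi_value(fixed: sitk.Image, moving: sitk.Image, transform: sitk.Transform,
              bins: int) -> float:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(transform)
    return float(reg.MetricEvaluate(fixed, moving))


def register_deformable(fixed_gray: np.ndarray, moving_gray: np.ndarray,
                        init: AffineTransform2D,
                        spacing: Tuple[float, float],
                        config: Optional[RegistrationConfig] = None,
                        fixed_mask: Optional[np.ndarray] = None,
                        moving_mask: Optional[np.ndarray] = None) -> DeformableField2D:
    """Free-form B-spline field refining the affine alignment under MI.

    The field lives in the fixed (histology) frame and composes before the
    affine.  If LBFGSB fails or mutual information does not improve on the
    affine-only value, the identity field is returned with a warning.  When
    the prostate masks are supplied, the field is additionally accepted only
    if it does not degrade their overlap — a safeguard that keeps the stiff
    deformable stage from trading boundary agreement for histogram effects.
    """
    config = config or RegistrationConfig()
    fixed = to_sitk2d(np.asarray(fixed_gray, np.float32), spacing)
    moving = to_sitk2d(np.asarray(moving_gray, np.float32), spacing)

    mesh = [config.bspline_mesh - 3, config.bspline_mesh - 3]  # mesh size excl. border
    bspline = sitk.BSplineTransformInitializer(fixed, mesh, order=3)
    width_mm = fixed_gray.shape[1] * spacing[0]
    cap = config.displacement_cap_frac * width_mm / np.sqrt(2.0)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=config.mi_bins)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetShrinkFactorsPerLevel(list(config.pyramid_shrink))
    reg.SetSmoothingSigmasPerLevel(list(config.pyramid_sigma))
    reg.SetSmoothingSigmasAreSpecifiedInPhysicalUnits(False)
    reg.SetMovingInitialTransform(init.to_sitk())
    reg.SetInitialTransform(bspline, inPlace=True)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7,
        numberOfIterations=config.deformable_iterations,
        maximumNumberOfCorrections=5,
        maximumNumberOfFunctionEvaluations=500,
        costFunctionConvergenceFactor=1e7,
        lowerBound=-cap,
        upperBound=cap,
    )
    try:
        reg.Execute(fixed, moving)
    except RuntimeError as exc:
        logger.warning("deformable registration failed (%s); using affine only", exc)
        return DeformableField2D()

    field = DeformableField2D(bspline)
    composite = sitk.CompositeTransform([init.to_sitk(), bspline])
    mi_affine = _mi_value(fixed, moving, init.to_sitk(), config.mi_bins)
    mi_full = _mi_value(fixed, moving, composite, config.mi_bins)
    if not np.isfinite(mi_full) or mi_full > mi_affine:  # ITK MI is negated
        logger.warning("deformable did not improve MI (%.4f -> %.4f); using affine only",
                       mi_affine, mi_full)
        return DeformableField2D()
    if fixed_mask is not None and moving_mask is not None:
        mimg = to_sitk2d(np.asarray(moving_mask, np.float32), spacing)
        ref = to_sitk2d(np.asarray(fixed_mask, np.float32), spacing)

        def mask_dice(tx: sitk.Transform) -> float:
            res = sitk.GetArrayFromImage(sitk.Resample(
                mimg, ref, tx, sitk.sitkNearestNeighbor, 0.0)) > 0.5
            fm = np.asarray(fixed_mask) > 0.5
            return 2.0 * np.logical_and(res, fm).sum() / (res.sum() + fm.sum())

        if mask_dice(composite) < mask_dice(init.to_sitk()):
            logger.debug("deformable degraded mask overlap; using affine only")
            return DeformableField2D()
    return field


# ---------------------------------------------------------------------------
# full case

def _resample_into_recon(arr: np.ndarray, rigid: RigidTransform2D,
                         spacing: Tuple[float, float], nearest: bool) -> np.ndarray:
    img = to_sitk2d(np.asarray(arr, np.float32), spacing)
    interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear
    return sitk.GetArrayFromImage(
        sitk.Resample(img, img, rigid.to_sitk(), interp, 0.0))


def register_case(mri: MriVolume, stack: HistologyStack,
                  config: Optional[RegistrationConfig] = None,
                  gross_rotation_deg: Optional[Sequence[float]] = None,
                  flip_lr: Optional[Sequence[bool]] = None
                  ) -> List[SliceTransformChain]:
    """End-to-end per-case registration: reconstruct, then affine + deformable
    per corresponding slice pair.

    Individual slice failures are recorded on the chain (identity transforms
    + warning) rather than raised; the case fails only if more than half of
    the slices fail.
    """
    config = config or RegistrationConfig()
    mri_slices, pstack = preprocess(mri, stack, gross_rotation_deg, flip_lr)
    rigids = reconstruct_stack(pstack, iterations=config.affine_iterations,
                               search_range_deg=config.angle_search_range_deg)

    chains: List[SliceTransformChain] = []
    failures = 0
    for i in range(pstack.n_slices):
        rigid = rigids[i]
        try:
            recon_mask = _resample_into_recon(pstack.slices[i].mask, rigid,
                                              pstack.pixel_size, nearest=True) > 0.5
            mri_mask = mri.mask[stack.correspondence[i]]
            affine = register_affine(recon_mask, mri_mask, pstack.pixel_size, config)

            fixed_gray = _resample_into_recon(pstack.slices[i].gray(), rigid,
                                              pstack.pixel_size, nearest=False)
            moving_gray = mri_slices[i]
            if config.deformable_use_mask:
                fixed_gray = fixed_gray * recon_mask
            deformable = register_deformable(fixed_gray, moving_gray, affine,
                                             pstack.pixel_size, config,
                                             fixed_mask=recon_mask,
                                             moving_mask=mri_mask)
            chains.append(SliceTransformChain(i, rigid, affine, deformable))
        except Exception as exc:  # noqa: BLE001 - per-slice containment
            logger.warning("slice %d registration failed: %s", i, exc)
            chain = SliceTransformChain.identity(i)
            chain.warnings.append(f"registration failed: {exc}")
            chains.append(chain)
            failures += 1
    if failures * 2 > pstack.n_slices:
        raise RuntimeError(
            f"registration failed on {failures}/{pstack.n_slices} slices")
    return chains
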