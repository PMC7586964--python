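"""Digital prostate phantom: paired synthetic MRI + histology with ground truth.

The phantom emulates the data a radiology-pathology fusion pipeline consumes:
a T2w-like MRI volume and a stack of whole-mount-like RGB sections, both
rendered from one shared labelled anatomy (prostate ellipsoid, posterior
peripheral-zone crescent, urethra tube, cancer ball) by filling each region
with its mean intensity and adding Gaussian noise.  Histologic-processing
artifacts — per-slice rotation, isotropic shrinkage, random translation,
optional left-right flip, and an out-of-plane slice-correspondence offset —
are injected with known ground-truth transforms so that registration
accuracy can be measured exactly.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import (
    AffineTransform2D,
    DeformableField2D,
    HistologySlice,
    HistologyStack,
    MriVolume,
    RigidTransform2D,
    grid_center_mm,
    to_sitk2d,
)

REGIONS = ("background", "prostate", "peripheral_zone", "cancer", "urethra")
LABEL_OF = {name: i for i, name in enumerate(REGIONS)}

DEFAULT_MRI_MEANS = {
    "background": 40.0,
    "prostate": 120.0,       # central gland, intermediate T2 signal
    "peripheral_zone": 200.0,  # PZ is T2-bright
    "cancer": 80.0,          # hypointense focus
    "urethra": 230.0,        # fluid-bright
}
DEFAULT_RGB_MEANS = {
    "background": (245.0, 245.0, 245.0),  # slide glass
    "prostate": (225.0, 160.0, 200.0),    # H&E pink
    "peripheral_zone": (205.0, 120.0, 175.0),
    "cancer": (150.0, 80.0, 140.0),       # dense, darker purple
    "urethra": (240.0, 220.0, 235.0),     # lumen
}


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions of one simulated case.

    ``max_rotation_deg`` is the half-width r of the uniform per-slice mounting
    rotation; ``shrink_factor`` is the fixation shrinkage s (every slice is
    scaled by 1-s); translation is drawn uniformly within
    ``translation_frac`` of the image width, in x and in y, and is applied
    only together with shrinkage (rotation-only experiments stay
    translation-free).  ``slice_offset_mm`` shifts the plane the histology is
    sampled from along the slice axis, emulating imperfect slice
    correspondence.
    """

    in_plane_size: int = 256
    n_slices: int = 6
    mri_spacing: Tuple[float, float, float] = (0.4, 0.4, 4.0)  # mm
    region_mri_means: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MRI_MEANS))
    region_rgb_means: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RGB_MEANS))
    noise_sd: float = 4.0              # ~5% of prostate/background MRI contrast
    max_rotation_deg: float = 0.0
    shrink_factor: float = 0.0
    translation_frac: float = 0.05
    slice_offset_mm: float = 0.0
    flip_lr: Union[bool, Sequence[bool]] = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.shrink_factor < 1.0):
            raise ValueError("shrink_factor must be in [0, 1)")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        if not (0.0 <= self.translation_frac < 0.5):
            raise ValueError("translation_frac must be in [0, 0.5)")
        if self.n_slices < 2:
            raise ValueError("n_slices must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        means = [self.region_mri_means[r] for r in REGIONS]
        if len(set(means)) != len(means):
            raise ValueError("region MRI means must be distinct")
        rgb = [tuple(self.region_rgb_means[r]) for r in REGIONS]
        if len(set(rgb)) != len(rgb):
            raise ValueError("region RGB means must be distinct")

    def flip_flags(self) -> List[bool]:
        if isinstance(self.flip_lr, bool):
            return [self.flip_lr] * self.n_slices
        flags = [bool(v) for v in self.flip_lr]
        if len(flags) != self.n_slices:
            raise ValueError("flip_lr list length must equal n_slices")
        return flags


# ---------------------------------------------------------------------------
# continuous anatomy model

@dataclass(frozen=True)
class AnatomyModel:
    """Analytic anatomy sampled at arbitrary axial planes (all mm).

    The prostate is an ellipsoid (wider left-right than antero-posterior, as
    in vivo); the peripheral zone a posterior band; the urethra a thin tube
    tilted in x so that out-of-plane offsets visibly displace it; the cancer
    a ball in the posterior lateral gland.
    """

    center_xy: Tuple[float, float]
    z_center: float
    semi_axes: Tuple[float, float, float] = (25.0, 20.0, 24.0)
    anterior_frac: float = 0.80          # flatter anterior border
    posterior_frac: float = 1.15         # fuller posterior lobe
    pz_band_frac: float = 0.25
    urethra_radius: float = 1.6
    urethra_tilt: float = 0.5            # mm of x-shift per mm of z
    urethra_dy: float = -3.0
    cancer_offset: Tuple[float, float, float] = (10.0, 6.0, 3.0)
    cancer_radius: float = 7.0

    def label_slice(self, z: float, shape: Tuple[int, int],
                    spacing: Tuple[float, float]) -> np.ndarray:
        rows, cols = shape
        x = np.arange(cols) * spacing[0]
        y = np.arange(rows) * spacing[1]
        xx, yy = np.meshgrid(x, y)
        cx, cy = self.center_xy
        ax, ay, az = self.semi_axes
        zr = z - self.z_center

        out = np.zeros(shape, np.uint8)
        shrink = 1.0 - (zr / az) ** 2
        if shrink <= 0:
            return out
        a_z, b_z = ax * np.sqrt(shrink), ay * np.sqrt(shrink)
        # egg profile: different antero-posterior radii break the rotational
        # ambiguity a pure ellipse would leave in the affine stage
        b_eff = np.where(yy >= cy, b_z * self.posterior_frac, b_z * self.anterior_frac)
        prostate = ((xx - cx) / a_z) ** 2 + ((yy - cy) / b_eff) ** 2 <= 1.0
        out[prostate] = LABEL_OF["prostate"]

        pz = prostate & (yy >= cy + self.pz_band_frac * b_z)
        out[pz] = LABEL_OF["peripheral_zone"]

        dzc = zr - self.cancer_offset[2]
        r2 = self.cancer_radius ** 2 - dzc ** 2
        if r2 > 0:
            ccx, ccy = cx + self.cancer_offset[0], cy + self.cancer_offset[1]
            cancer = prostate & ((xx - ccx) ** 2 + (yy - ccy) ** 2 <= r2)
            out[cancer] = LABEL_OF["cancer"]

        ux, uy = self.urethra_center(z)
        urethra = (xx - ux) ** 2 + (yy - uy) ** 2 <= self.urethra_radius ** 2
        out[urethra & prostate] = LABEL_OF["urethra"]
        return out

    def urethra_center(self, z: float) -> Tuple[float, float]:
        cx, cy = self.center_xy
        return (cx + self.urethra_tilt * (z - self.z_center), cy + self.urethra_dy)

    def inplane_semi_axes(self, z: float) -> Tuple[float, float]:
        ax, ay, az = self.semi_axes
        shrink = 1.0 - ((z - self.z_center) / az) ** 2
        if shrink <= 0:
            return (0.0, 0.0)
        return (ax * np.sqrt(shrink), ay * np.sqrt(shrink))

    def landmarks(self, z: float) -> Dict[str, Tuple[float, float]]:
        """Point landmarks on one plane: urethra centre, cancer axis, a tapered anchor."""
        cx, cy = self.center_xy
        a_z, b_z = self.inplane_semi_axes(z)
        if a_z == 0.0:
            return {}
        pts = {
            "urethra": self.urethra_center(z),
            "anchor": (cx - 0.5 * a_z, cy - 0.4 * b_z),
        }
        dzc = (z - self.z_center) - self.cancer_offset[2]
        if self.cancer_radius ** 2 - dzc ** 2 > 1.0:  # skip sliver sections
            pts["cancer"] = (cx + self.cancer_offset[0], cy + self.cancer_offset[1])
        return pts


@dataclass
class LabeledAnatomy:
    """Discrete anatomy on the MRI grid plus the continuous model it came from."""

    model: AnatomyModel
    z_positions: List[float]
    labels: np.ndarray                   # (slices, rows, cols) uint8
    masks: Dict[str, np.ndarray]         # region name -> bool volume

    @property
    def shape2d(self) -> Tuple[int, int]:
        return self.labels.shape[1:]


def make_anatomy(spec: PhantomSpec) -> LabeledAnatomy:
    """Build the labelled anatomy volume on the MRI slice grid.

    Raises if the prostate is empty on any slice (a degenerate spec), naming
    the offending slice.
    """
    n = spec.in_plane_size
    sx, sy, sz = spec.mri_spacing
    z_positions = [i * sz for i in range(spec.n_slices)]
    center = grid_center_mm((n, n), (sx, sy))
    model = AnatomyModel(center_xy=center, z_center=(spec.n_slices - 1) * sz / 2.0)

    labels = np.stack([model.label_slice(z, (n, n), (sx, sy)) for z in z_positions])
    for i in range(spec.n_slices):
        if not np.any(labels[i] >= LABEL_OF["prostate"]):
            raise ValueError(f"degenerate spec: prostate empty at slice {i}")
    masks = {name: labels == LABEL_OF[name] for name in REGIONS}
    masks["prostate_any"] = labels >= LABEL_OF["prostate"]  # whole gland incl. substructures
    return LabeledAnatomy(model=model, z_positions=z_positions, labels=labels, masks=masks)


# ---------------------------------------------------------------------------
# modality synthesis

def synthesize_mri(anatomy: LabeledAnatomy, spec: PhantomSpec,
                   rng: Optional[np.random.Generator] = None) -> MriVolume:
    """Region-mean-filled T2w-like volume with i.i.d. Gaussian noise."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lut = np.array([spec.region_mri_means[r] for r in REGIONS], np.float32)
    vol = lut[anatomy.labels]
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape).astype(np.float32)
    return MriVolume(image=vol.astype(np.float32),
                     mask=anatomy.masks["prostate_any"].copy(),
                     spacing=spec.mri_spacing)


def _render_histology_slice(model: AnatomyModel, z: float, spec: PhantomSpec) -> HistologySlice:
    n = spec.in_plane_size
    sx, sy, _ = spec.mri_spacing
    labels = model.label_slice(z, (n, n), (sx, sy))
    lut = np.array([spec.region_rgb_means[r] for r in REGIONS], np.float32)
    rgb = lut[labels]
    prostate = labels >= LABEL_OF["prostate"]
    return HistologySlice(
        image=np.clip(np.rint(rgb), 0, 255).astype(np.uint8),
        mask=prostate,
        labels={
            "cancer": labels == LABEL_OF["cancer"],
            "urethra": labels == LABEL_OF["urethra"],
        },
        landmarks=dict(model.landmarks(z)),
    )


def synthesize_histology(anatomy: LabeledAnatomy, spec: PhantomSpec,
                         rng: Optional[np.random.Generator] = None,
                         noise_sd: Optional[float] = None) -> HistologyStack:
    """Artifact-free RGB stack on the MRI slice grid (so that zero-artifact
    registration is exactly the identity), sampled ``slice_offset_mm`` away
    along the slice axis when imperfect correspondence is simulated."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    sd = spec.noise_sd if noise_sd is None else noise_sd
    slices = []
    for z in anatomy.z_positions:
        s = _render_histology_slice(anatomy.model, z + spec.slice_offset_mm, spec)
        if not np.any(s.mask):
            raise ValueError(f"degenerate spec: offset histology prostate empty at z={z}")
        if sd > 0:
            s = dataclasses.replace(s, image=_add_rgb_noise(s.image, sd, rng))
        slices.append(s)
    return HistologyStack(slices=slices,
                          pixel_size=(spec.mri_spacing[0], spec.mri_spacing[1]),
                          correspondence=list(range(spec.n_slices)))


def _add_rgb_noise(img: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    noisy = img.astype(np.float32) + rng.normal(0.0, sd, img.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# processing artifacts

@dataclass(frozen=True)
class SliceArtifact:
    """Ground-truth forward map applied to one section:
    ``p' = scale * R(angle) (flip(p) - c) + c + t``."""

    angle_deg: float
    translation: Tuple[float, float]     # mm
    scale: float
    flip: bool
    center: Tuple[float, float]          # mm

    def point_map(self) -> sitk.Transform:
        sim = sitk.Similarity2DTransform()
        sim.SetCenter(self.center)
        sim.SetScale(self.scale)
        sim.SetAngle(float(np.deg2rad(self.angle_deg)))
        sim.SetTranslation(self.translation)
        if not self.flip:
            return sim
        flip = sitk.AffineTransform(2)
        flip.SetCenter(self.center)
        flip.SetMatrix((-1.0, 0.0, 0.0, 1.0))
        return sitk.CompositeTransform([sim, flip])  # flip first, then similarity

    def apply_point(self, p: Tuple[float, float]) -> Tuple[float, float]:
        return tuple(self.point_map().TransformPoint(tuple(map(float, p))))


@dataclass
class GroundTruthTransforms:
    per_slice: List[SliceArtifact]
    slice_offset_mm: float = 0.0


def apply_artifacts(stack: HistologyStack, spec: PhantomSpec,
                    rng: Optional[np.random.Generator] = None
                    ) -> Tuple[HistologyStack, GroundTruthTransforms]:
    """Corrupt each section with rotation ~ U(-r, r), isotropic shrinkage s
    about the slice centre, and (only alongside shrinkage) random translation
    up to ``translation_frac`` of the width in x and y.  Purely geometric:
    noise is not re-drawn here, so identity conditions round-trip exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)
    flips = spec.flip_flags()
    r = spec.max_rotation_deg
    s = spec.shrink_factor
    shape = stack.slices[0].image.shape[:2]
    center = grid_center_mm(shape, stack.pixel_size)
    width_mm = shape[1] * stack.pixel_size[0]

    out_slices: List[HistologySlice] = []
    truth: List[SliceArtifact] = []
    for i, sl in enumerate(stack.slices):
        angle = float(rng.uniform(-r, r)) if r > 0 else 0.0
        if s > 0:
            t = (float(rng.uniform(-spec.translation_frac, spec.translation_frac) * width_mm),
                 float(rng.uniform(-spec.translation_frac, spec.translation_frac) * width_mm))
        else:
            t = (0.0, 0.0)
        art = SliceArtifact(angle_deg=angle, translation=t, scale=1.0 - s,
                            flip=flips[i], center=center)
        warped = _warp_slice(sl, art, stack.pixel_size)
        if not np.any(warped.mask):
            raise ValueError(f"artifact pushed prostate mask out of frame on slice {i}")
        out_slices.append(warped)
        truth.append(art)
    corrupted = HistologyStack(slices=out_slices, pixel_size=stack.pixel_size,
                               correspondence=list(stack.correspondence))
    return corrupted, GroundTruthTransforms(per_slice=truth,
                                            slice_offset_mm=spec.slice_offset_mm)


def _resample2d(arr: np.ndarray, transform: sitk.Transform,
                spacing: Tuple[float, float], nearest: bool) -> np.ndarray:
    img = to_sitk2d(np.asarray(arr, np.float32), spacing)
    interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear
    out = sitk.Resample(img, img, transform, interp, 0.0, sitk.sitkFloat32)
    return sitk.GetArrayFromImage(out)


def _warp_slice(sl: HistologySlice, art: SliceArtifact,
                spacing: Tuple[float, float]) -> HistologySlice:
    inv = sitk.Transform(art.point_map()).GetInverse()
    is_identity = (art.angle_deg == 0 and art.scale == 1.0
                   and art.translation == (0.0, 0.0) and not art.flip)
    if is_identity:
        return dataclasses.replace(sl)
    rgb = np.stack([_resample2d(sl.image[..., c], inv, spacing, nearest=False)
                    for c in range(3)], axis=-1)
    mask = _resample2d(sl.mask, inv, spacing, nearest=True) > 0.5
    labels = {k: _resample2d(v, inv, spacing, nearest=True) > 0.5
              for k, v in sl.labels.items()}
    landmarks = {k: art.apply_point(p) for k, p in sl.landmarks.items()}
    return HistologySlice(image=np.clip(np.rint(rgb), 0, 255).astype(np.uint8),
                          mask=mask, labels=labels, landmarks=landmarks)


# ---------------------------------------------------------------------------
# full case assembly

@dataclass
class PhantomCase:
    """One simulated case: inputs for registration plus evaluation references."""

    spec: PhantomSpec
    mri: MriVolume
    stack: HistologyStack                    # corrupted + noisy (the pipeline input)
    truth: GroundTruthTransforms
    ref_labels: Dict[str, np.ndarray]        # MRI-frame cancer/urethra volumes
    ref_landmarks: List[Dict[str, Tuple[float, float]]]  # per MRI slice


def make_phantom_case(spec: PhantomSpec) -> PhantomCase:
    """Generate MRI + corrupted histology + ground truth for one condition.

    Histology noise is drawn after the geometric artifacts are applied, so
    the corrupted sections carry fresh (not resampled) noise.
    """
    rng = np.random.default_rng(spec.seed)
    anatomy = make_anatomy(spec)
    mri = synthesize_mri(anatomy, spec, rng)
    clean = synthesize_histology(anatomy, spec, noise_sd=0.0)
    corrupted, truth = apply_artifacts(clean, spec, rng)
    if spec.noise_sd > 0:
        noisy = [dataclasses.replace(s, image=_add_rgb_noise(s.image, spec.noise_sd, rng))
                 for s in corrupted.slices]
        corrupted = HistologyStack(slices=noisy, pixel_size=corrupted.pixel_size,
                                   correspondence=list(corrupted.correspondence))
    ref_landmarks = [anatomy.model.landmarks(z) for z in anatomy.z_positions]
    ref_labels = {"cancer": anatomy.masks["cancer"].copy(),
                  "urethra": anatomy.masks["urethra"].copy()}
    return PhantomCase(spec=spec, mri=mri, stack=corrupted, truth=truth,
                       ref_labels=ref_labels, ref_landmarks=ref_landmarks)


# ---------------------------------------------------------------------------
# condition sweeps

def evaluate_phantom_case(case: PhantomCase, config=None) -> Dict[str, float]:
    """Run the full pipeline on one phantom case and score it against ground
    truth.  Returns a flat metric record (distances mm, Dice unitless)."""
    from . import mapping as mapping_mod
    from . import metrics as metrics_mod
    from .slicereg import RegistrationConfig, register_case

    config = config or RegistrationConfig()
    flips = case.spec.flip_flags()
    chains = register_case(case.mri, case.stack, config,
                           gross_rotation_deg=[0.0] * case.stack.n_slices,
                           flip_lr=flips)
    return score_registration(case, chains)


def score_registration(case: PhantomCase, chains) -> Dict[str, float]:
    """Metrics of a registered phantom case at the input/affine/full stages."""
    from . import mapping as mapping_mod
    from . import metrics as metrics_mod

    spacing = case.stack.pixel_size
    grid = case.mri.image.shape[1:]
    flips = case.spec.flip_flags()
    mri_masks = [case.mri.slice_mask(j) for j in case.stack.correspondence]

    def warp_all(use_affine: bool, use_def: bool, what: str) -> List[np.ndarray]:
        out = []
        for i, ch in enumerate(chains):
            chain = dataclasses.replace(
                ch,
                affine=ch.affine if use_affine else AffineTransform2D(),
                deformable=ch.deformable if use_def else DeformableField2D(),
            )
            src = (case.stack.slices[i].mask if what == "mask"
                   else case.stack.slices[i].labels[what])
            src = _preproc_label(src, flips[i], spacing)
            out.append(mapping_mod.warp_label(src, chain, grid, spacing))
        return out

    input_masks = [_preproc_label(s.mask, flips[i], spacing)
                   for i, s in enumerate(case.stack.slices)]
    affine_masks = warp_all(True, False, "mask")
    full_masks = warp_all(True, True, "mask")
    urethra = warp_all(True, True, "urethra")
    ref_urethra = [case.ref_labels["urethra"][j] for j in case.stack.correspondence]

    rec: Dict[str, float] = {}
    rec["dice_input"] = metrics_mod.dice_stack(input_masks, mri_masks)
    rec["dice_affine"] = metrics_mod.dice_stack(affine_masks, mri_masks)
    rec["dice"] = metrics_mod.dice_stack(full_masks, mri_masks)
    rec["hausdorff_mm"] = metrics_mod.hausdorff_stack(full_masks, mri_masks, spacing)
    try:
        rec["urethra_mm"] = metrics_mod.urethra_deviation(urethra, ref_urethra, spacing)
    except ValueError:
        rec["urethra_mm"] = float("nan")

    # landmarks: corrupted-histology points (flip undone as in preprocessing)
    # mapped through the chain vs. the MRI-frame anatomy points
    center = grid_center_mm(grid, spacing)
    dists, angle_errs = [], []
    for i, ch in enumerate(chains):
        fwd = mapping_mod.compose_chain(ch, reference_shape=grid, spacing=spacing)
        ref = case.ref_landmarks[case.stack.correspondence[i]]
        for name, p in case.stack.slices[i].landmarks.items():
            if name not in ref:
                continue
            q = (2 * center[0] - p[0], p[1]) if flips[i] else p
            mapped = fwd(q)
            dists.append(float(np.hypot(mapped[0] - ref[name][0],
                                        mapped[1] - ref[name][1])))
        angle_errs.append(_recovered_angle_error(fwd, center,
                                                 case.truth.per_slice[i].angle_deg))
    rec["landmark_mm"] = float(np.mean(dists)) if dists else float("nan")
    rec["max_angle_error_deg"] = float(np.max(angle_errs))
    return rec


def _preproc_label(arr: np.ndarray, flip: bool, spacing) -> np.ndarray:
    return arr[:, ::-1] if flip else arr


def _recovered_angle_error(fwd, center: Tuple[float, float], true_angle_deg: float,
                           eps: float = 0.5) -> float:
    """Angle of the chain's local linear action vs the injected rotation.

    The composite histology->MRI map should invert the artifact, so the
    rotation part (polar decomposition) of its local Jacobian at the gland
    centre is minus the applied mounting angle.
    """
    p0 = np.asarray(fwd(center))
    px = np.asarray(fwd((center[0] + eps, center[1])))
    py = np.asarray(fwd((center[0], center[1] + eps)))
    jac = np.column_stack([(px - p0) / eps, (py - p0) / eps])
    u, _, vt = np.linalg.svd(jac)
    rot = u @ vt
    recovered = -np.rad2deg(np.arctan2(rot[1, 0], rot[0, 0]))
    return abs(_wrap_angle(recovered - true_angle_deg))


def _wrap_angle(deg: float) -> float:
    return (deg + 180.0) % 360.0 - 180.0


def run_phantom_experiment(conditions: Sequence[PhantomSpec], n_reps: int,
                           seed: int = 0, config=None,
                           progress: bool = False) -> pd.DataFrame:
    """Condition sweep: for every condition x repetition (distinct seeds),
    generate a phantom, run the full pipeline, and score it.  A failed
    registration yields a failed row, never a crashed sweep."""
    rows = []
    for ci, cond in enumerate(conditions):
        for rep in range(n_reps):
            child = int(np.random.SeedSequence([seed, ci, rep]).generate_state(1)[0]
                        % (2 ** 31))
            spec = dataclasses.replace(cond, seed=child)
            row = {
                "condition": ci,
                "rotation_deg": spec.max_rotation_deg,
                "shrink": spec.shrink_factor,
                "slice_offset_mm": spec.slice_offset_mm,
                "rep": rep,
                "seed": child,
            }
            try:
                case = make_phantom_case(spec)
                row.update(evaluate_phantom_case(case, config))
                row["status"] = "ok"
            except Exception as exc:  # noqa: BLE001 - sweep must survive
                row["status"] = f"failed: {exc}"
            rows.append(row)
            if progress:
                print(f"condition {ci} rep {rep}: {row.get('dice', 'failed')}")
    return pd.DataFrame(rows)


def summarize_experiment(results: pd.DataFrame) -> pd.DataFrame:
    """Per-condition means and variances of every metric column."""
    metric_cols = [c for c in ("dice", "hausdorff_mm", "urethra_mm", "landmark_mm",
                               "dice_input", "dice_affine", "max_angle_error_deg")
                   if c in results.columns]
    ok = results[results["status"] == "ok"]
    return (ok.groupby(["rotation_deg", "shrink", "slice_offset_mm"])[metric_cols]
              .agg(["mean", "var"]).reset_index())
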