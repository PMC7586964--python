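"""Shared containers and 2D transform wrappers.

All coordinates are physical millimetres.  Image arrays are indexed
``[row, col]`` (y, x) and converted to/from SimpleITK with the usual
``x = col * spacing_x``, ``y = row * spacing_y`` convention and origin at
zero.  Transforms follow the ITK resampling convention: a transform attached
to a registration with fixed image F and moving image M maps *points of F's
frame to points of M's frame*.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import SimpleITK as sitk

Point = Tuple[float, float]


# ---------------------------------------------------------------------------
# numpy <-> SimpleITK helpers

def to_sitk2d(arr: np.ndarray, spacing: Tuple[float, float]) -> sitk.Image:
    """2D numpy array (rows, cols) -> sitk image with physical spacing (sx, sy)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing((float(spacing[0]), float(spacing[1])))
    return img


def from_sitk2d(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img)


def grid_center_mm(shape: Tuple[int, int], spacing: Tuple[float, float]) -> Point:
    """Physical centre of a (rows, cols) grid: midpoint of the pixel-centre lattice."""
    rows, cols = shape
    return ((cols - 1) / 2.0 * spacing[0], (rows - 1) / 2.0 * spacing[1])


def mask_centroid_mm(mask: np.ndarray, spacing: Tuple[float, float]) -> Point:
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("centroid of an empty mask is undefined")
    return (float(cc.mean() * spacing[0]), float(rr.mean() * spacing[1]))


# ---------------------------------------------------------------------------
# transforms

def _normalize_angle(deg: float) -> float:
    a = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class RigidTransform2D:
    """2D rotation + translation about a centre, angle in degrees.

    Point action: ``p' = R(angle) (p - c) + c + t``.
    """

    angle_deg: float = 0.0
    translation: Point = (0.0, 0.0)
    center: Point = (0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "angle_deg", _normalize_angle(float(self.angle_deg)))

    def to_sitk(self) -> sitk.Euler2DTransform:
        t = sitk.Euler2DTransform()
        t.SetCenter(tuple(map(float, self.center)))
        t.SetAngle(float(np.deg2rad(self.angle_deg)))
        t.SetTranslation(tuple(map(float, self.translation)))
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "RigidTransform2D":
        e = sitk.Euler2DTransform(t.Downcast() if hasattr(t, "Downcast") else t)
        return cls(
            angle_deg=float(np.rad2deg(e.GetAngle())),
            translation=tuple(e.GetTranslation()),
            center=tuple(e.GetCenter()),
        )

    def apply(self, p: Point) -> Point:
        return tuple(self.to_sitk().TransformPoint(tuple(map(float, p))))

    def inverse(self) -> "RigidTransform2D":
        return RigidTransform2D.from_sitk(self.to_sitk().GetInverse())

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """self after other: the rigid map p -> self(other(p)), centre at origin."""
        m = _rigid_matrix(self) @ _rigid_matrix(other)
        return RigidTransform2D(
            angle_deg=float(np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))),
            translation=(float(m[0, 2]), float(m[1, 2])),
            center=(0.0, 0.0),
        )

    def as_matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix of the point action."""
        return _rigid_matrix(self)


def _rigid_matrix(t: RigidTransform2D) -> np.ndarray:
    th = np.deg2rad(t.angle_deg)
    r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c = np.asarray(t.center, float)
    tr = np.asarray(t.translation, float)
    out = np.eye(3)
    out[:2, :2] = r
    out[:2, 2] = c + tr - r @ c
    return out


@dataclass(frozen=True)
class AffineTransform2D:
    """2D affine map ``p' = A (p - c) + c + t`` with invertible A."""

    matrix: Tuple[Tuple[float, float], Tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    translation: Point = (0.0, 0.0)
    center: Point = (0.0, 0.0)

    def __post_init__(self):
        if abs(np.linalg.det(np.asarray(self.matrix, float))) < 1e-12:
            raise ValueError("affine matrix must be invertible")

    def to_sitk(self) -> sitk.AffineTransform:
        t = sitk.AffineTransform(2)
        t.SetCenter(tuple(map(float, self.center)))
        t.SetMatrix([float(v) for row in self.matrix for v in row])
        t.SetTranslation(tuple(map(float, self.translation)))
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "AffineTransform2D":
        a = sitk.AffineTransform(t.Downcast() if hasattr(t, "Downcast") else t)
        m = a.GetMatrix()
        return cls(
            matrix=((m[0], m[1]), (m[2], m[3])),
            translation=tuple(a.GetTranslation()),
            center=tuple(a.GetCenter()),
        )

    def apply(self, p: Point) -> Point:
        return tuple(self.to_sitk().TransformPoint(tuple(map(float, p))))

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D.from_sitk(self.to_sitk().GetInverse())

    def as_matrix(self) -> np.ndarray:
        a = np.asarray(self.matrix, float)
        c = np.asarray(self.center, float)
        tr = np.asarray(self.translation, float)
        out = np.eye(3)
        out[:2, :2] = a
        out[:2, 2] = c + tr - a @ c
        return out


class DeformableField2D:
    """Free-form (B-spline) displacement field; ``None`` coefficients = identity."""

    def __init__(self, bspline: Optional[sitk.BSplineTransform] = None):
        self.bspline = bspline

    @property
    def is_identity(self) -> bool:
        if self.bspline is None:
            return True
        return not np.any(np.asarray(self.bspline.GetParameters()))

    def to_sitk(self) -> sitk.Transform:
        if self.bspline is None:
            return sitk.Transform(2, sitk.sitkIdentity)
        return self.bspline

    def apply(self, p: Point) -> Point:
        return tuple(self.to_sitk().TransformPoint(tuple(map(float, p))))

    def displacement_field(self, reference: sitk.Image) -> sitk.Image:
        """Dense displacement field sampled on the reference grid (vector image, mm)."""
        f = sitk.TransformToDisplacementFieldFilter()
        f.SetReferenceImage(reference)
        f.SetOutputPixelType(sitk.sitkVectorFloat64)
        return f.Execute(self.to_sitk())

    def max_displacement(self, reference: sitk.Image) -> float:
        field = sitk.GetArrayFromImage(self.displacement_field(reference))
        return float(np.sqrt((field ** 2).sum(axis=-1)).max())

    def inverse_transform(self, reference: sitk.Image,
                          tolerance_mm: float = 0.04,
                          max_iterations: int = 50) -> sitk.Transform:
        """Approximate inverse via fixed-point displacement-field inversion."""
        if self.is_identity:
            return sitk.Transform(2, sitk.sitkIdentity)
        field = self.displacement_field(reference)
        inv = sitk.InvertDisplacementField(
            field,
            maximumNumberOfIterations=max_iterations,
            maxErrorToleranceThreshold=tolerance_mm,
            meanErrorToleranceThreshold=tolerance_mm / 4.0,
            enforceBoundaryCondition=True,
        )
        return sitk.DisplacementFieldTransform(inv)


# ---------------------------------------------------------------------------
# image containers

@dataclass
class MriVolume:
    """T2w MRI volume: (slices, rows, cols) scalar grid + prostate mask."""

    image: np.ndarray
    mask: np.ndarray
    spacing: Tuple[float, float, float]  # (in-plane x, in-plane y, slice thickness) mm

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("MRI mask grid differs from MRI image grid")
        if self.image.ndim != 3:
            raise ValueError("MRI volume must be 3D (slices, rows, cols)")

    @property
    def n_slices(self) -> int:
        return self.image.shape[0]

    @property
    def in_plane_spacing(self) -> Tuple[float, float]:
        return (self.spacing[0], self.spacing[1])

    def slice_image(self, i: int) -> sitk.Image:
        return to_sitk2d(self.image[i].astype(np.float32), self.in_plane_spacing)

    def slice_mask(self, i: int) -> np.ndarray:
        return self.mask[i]


@dataclass
class HistologySlice:
    """One whole-mount section: RGB image + prostate mask + optional labels."""

    image: np.ndarray                      # (rows, cols, 3) uint8
    mask: np.ndarray                       # (rows, cols) bool
    labels: Dict[str, np.ndarray] = field(default_factory=dict)
    landmarks: Dict[str, Point] = field(default_factory=dict)  # physical mm

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("histology mask grid differs from image grid")

    def gray(self) -> np.ndarray:
        """Luminance conversion (0.299/0.587/0.114) for mutual-information scoring."""
        w = np.array([0.299, 0.587, 0.114])
        return (self.image.astype(np.float32) @ w).astype(np.float32)


@dataclass
class HistologyStack:
    """Ordered apex-to-base stack of sections with a slice-correspondence map."""

    slices: List[HistologySlice]
    pixel_size: Tuple[float, float]        # (x, y) mm per pixel
    correspondence: List[int]              # MRI axial slice index per section

    def __post_init__(self):
        if len(self.correspondence) != len(self.slices):
            raise ValueError("correspondence table length differs from slice count")
        shapes = {s.image.shape[:2] for s in self.slices}
        if len(shapes) > 1:
            raise ValueError("all histology slices must share one grid size")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def slice_sitk(self, i: int, channel: str = "gray") -> sitk.Image:
        s = self.slices[i]
        arr = s.gray() if channel == "gray" else s.image[..., "rgb".index(channel)]
        return to_sitk2d(np.asarray(arr, np.float32), self.pixel_size)

    def mask_sitk(self, i: int) -> sitk.Image:
        return to_sitk2d(self.slices[i].mask.astype(np.float32), self.pixel_size)


@dataclass
class SliceTransformChain:
    """Per-slice transform triple linking one histology section to its MRI slice.

    ``rigid`` maps reconstructed-frame points to raw-section points (the
    resampling direction used when stacking).  ``affine`` and ``deformable``
    map reconstructed-histology-frame points to MRI-frame points, with the
    deformable applied first (p_mri = affine(deformable(p_hist))).
    """

    slice_index: int
    rigid: RigidTransform2D
    affine: AffineTransform2D
    deformable: DeformableField2D
    warnings: List[str] = field(default_factory=list)

    @classmethod
    def identity(cls, slice_index: int = 0) -> "SliceTransformChain":
        return cls(slice_index, RigidTransform2D(), AffineTransform2D(), DeformableField2D())


@dataclass
class MetricsReport:
    """Slice-averaged registration accuracy summary (distances in mm)."""

    dice: float
    hausdorff_mm: float
    landmark_mm: Optional[float]
    urethra_mm: Optional[float]
    dice_per_slice: List[float] = field(default_factory=list)
    hausdorff_per_slice: List[float] = field(default_factory=list)
    n_slices: int = 0
    n_landmarks: int = 0
    n_urethra_slices: int = 0

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "hausdorff_mm": self.hausdorff_mm,
            "landmark_mm": self.landmark_mm,
            "urethra_mm": self.urethra_mm,
            "dice_per_slice": list(self.dice_per_slice),
            "hausdorff_per_slice": list(self.hausdorff_per_slice),
            "n_slices": self.n_slices,
            "n_landmarks": self.n_landmarks,
            "n_urethra_slices": self.n_urethra_slices,
        }
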