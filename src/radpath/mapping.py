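"""Compose per-slice transform chains and project histology-space labels,
landmarks and images onto the MRI grid.

Point mapping histology -> MRI is forward-evaluable (rigid inverse is
analytic, affine and B-spline act in that direction already); resampling a
histology label onto the MRI grid needs the opposite direction, so the
B-spline is inverted approximately by fixed-point displacement-field
inversion and the whole composite is applied in a single interpolation pass.
"""
from __future__ import annotations

import logging
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import SimpleITK as sitk

from .core import (
    HistologySlice,
    Point,
    SliceTransformChain,
    to_sitk2d,
)

logger = logging.getLogger("radpath.mapping")


def compose_chain(chain: SliceTransformChain,
                  reference_shape: Optional[Tuple[int, int]] = None,
                  spacing: Tuple[float, float] = (1.0, 1.0)
                  ) -> Callable[[Point], Point]:
    """Point map from raw histology slice coordinates to MRI slice
    coordinates (mm): ``p_mri = affine(deformable(rigid^-1(p_hist)))``.

    A chain of identities composes to the identity map.  ``reference_shape``
    bounds the valid domain: mapped points are returned regardless, but
    :func:`warp_landmarks` drops points that leave it.
    """
    rig_inv = chain.rigid.inverse().to_sitk()
    aff = chain.affine.to_sitk()
    deform = chain.deformable.to_sitk()
    composite = sitk.CompositeTransform([aff, deform, rig_inv])  # rigid^-1 first

    def forward(p: Point) -> Point:
        return tuple(composite.TransformPoint(tuple(map(float, p))))

    return forward


def _inverse_resampling_transform(chain: SliceTransformChain,
                                  reference: sitk.Image) -> sitk.Transform:
    """Transform fed to the resampler when pulling histology onto the MRI
    grid: maps MRI points to raw-histology points,
    ``rigid(deformable^-1(affine^-1(p_mri)))``."""
    aff_inv = chain.affine.inverse().to_sitk()
    def_inv = chain.deformable.inverse_transform(reference)
    rig = chain.rigid.to_sitk()
    return sitk.CompositeTransform([rig, def_inv, aff_inv])  # affine^-1 first


def warp_label(label: np.ndarray, chain: SliceTransformChain,
               target_shape: Tuple[int, int],
               spacing: Tuple[float, float]) -> np.ndarray:
    """Project a binary histology label onto the MRI slice grid.

    One nearest-neighbour resampling pass through the full composite, so no
    label values absent from the input can appear and interpolation blur is
    not compounded.  An empty label maps to an empty label.
    """
    label = np.asarray(label)
    if not np.any(label):
        return np.zeros(target_shape, bool)
    src = to_sitk2d(label.astype(np.float32), spacing)
    ref = to_sitk2d(np.zeros(target_shape, np.float32), spacing)
    tx = _inverse_resampling_transform(chain, ref)
    out = sitk.Resample(src, ref, tx, sitk.sitkNearestNeighbor, 0.0)
    return sitk.GetArrayFromImage(out) > 0.5


def warp_image(image: np.ndarray, chain: SliceTransformChain,
               target_shape: Tuple[int, int],
               spacing: Tuple[float, float]) -> np.ndarray:
    """Project a histology image (grayscale or RGB) onto the MRI slice grid
    with linear interpolation in a single pass."""
    image = np.asarray(image, np.float32)
    ref = to_sitk2d(np.zeros(target_shape, np.float32), spacing)
    tx = _inverse_resampling_transform(chain, ref)

    def one(channel: np.ndarray) -> np.ndarray:
        src = to_sitk2d(channel, spacing)
        return sitk.GetArrayFromImage(
            sitk.Resample(src, ref, tx, sitk.sitkLinear, 0.0))

    if image.ndim == 2:
        return one(image)
    return np.stack([one(image[..., c]) for c in range(image.shape[-1])], axis=-1)


def warp_landmarks(landmarks: Sequence[Tuple[str, int, Point]],
                   chains: Dict[int, SliceTransformChain],
                   domain_mm: Optional[Tuple[float, float]] = None
                   ) -> Tuple[List[Tuple[str, int, Point]], List[str]]:
    """Map named per-slice landmark points into MRI coordinates.

    ``landmarks`` is a sequence of (name, slice_index, (x_mm, y_mm)).  Every
    referenced slice must have a chain; points mapped outside ``domain_mm``
    are dropped and reported in the returned warning list.
    """
    missing = sorted({s for _, s, _ in landmarks} - set(chains))
    if missing:
        raise ValueError(f"no transform chain for slices {missing}")
    out: List[Tuple[str, int, Point]] = []
    warnings: List[str] = []
    cache: Dict[int, Callable[[Point], Point]] = {}
    for name, s, p in landmarks:
        if s not in cache:
            cache[s] = compose_chain(chains[s])
        q = cache[s](p)
        if domain_mm is not None and not (
                0.0 <= q[0] <= domain_mm[0] and 0.0 <= q[1] <= domain_mm[1]):
            warnings.append(f"landmark {name!r} on slice {s} mapped out of domain; dropped")
            continue
        out.append((name, s, q))
    for w in warnings:
        logger.warning("%s", w)
    return out, warnings
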