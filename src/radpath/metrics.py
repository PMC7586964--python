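"""Registration accuracy metrics: slice-averaged Dice, slice-averaged
boundary Hausdorff distance, landmark distance and urethra deviation.

Conventions: a slice where both prostate masks are empty contributes a Dice
of 1 (vacuous agreement at tapered apex/base sections) while asymmetric
emptiness contributes 0; the Hausdorff distance is the classic symmetric
max-of-sup-infs between the 8-connected boundary pixel centres, in mm, and
is undefined (an error) when exactly one mask of a pair is empty.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .core import MetricsReport, Point


def _check_counts(h: Sequence[np.ndarray], m: Sequence[np.ndarray]) -> int:
    if len(h) != len(m):
        raise ValueError(f"mismatched slice counts: {len(h)} vs {len(m)}")
    if len(h) == 0:
        raise ValueError("at least one slice required")
    return len(h)


def dice_slice(h: np.ndarray, m: np.ndarray) -> float:
    h, m = np.asarray(h) > 0, np.asarray(m) > 0
    denom = int(h.sum()) + int(m.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(h, m).sum()) / denom


def dice_stack(h_masks: Sequence[np.ndarray], m_masks: Sequence[np.ndarray]) -> float:
    """Mean over slices of 2|H∩M| / (|H|+|M|)."""
    d = _check_counts(h_masks, m_masks)
    return float(np.mean([dice_slice(h, m) for h, m in zip(h_masks, m_masks)]))


def boundary_points_mm(mask: np.ndarray, pixel_size: Tuple[float, float]) -> np.ndarray:
    """Centres of the 8-connected outer contour pixels, as (x_mm, y_mm) rows."""
    mask = np.asarray(mask) > 0
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    rr, cc = np.nonzero(mask & ~eroded)
    return np.column_stack([cc * pixel_size[0], rr * pixel_size[1]])


def hausdorff_slice(h: np.ndarray, m: np.ndarray,
                    pixel_size: Tuple[float, float]) -> float:
    hb = boundary_points_mm(h, pixel_size)
    mb = boundary_points_mm(m, pixel_size)
    if len(hb) == 0 and len(mb) == 0:
        return 0.0
    if len(hb) == 0 or len(mb) == 0:
        raise ValueError("Hausdorff undefined: one mask of the pair is empty")
    return float(max(directed_hausdorff(hb, mb)[0], directed_hausdorff(mb, hb)[0]))


def hausdorff_stack(h_masks: Sequence[np.ndarray], m_masks: Sequence[np.ndarray],
                    pixel_size: Tuple[float, float]) -> float:
    """Mean over slices of the symmetric boundary Hausdorff distance, mm."""
    d = _check_counts(h_masks, m_masks)
    vals = []
    for i, (h, m) in enumerate(zip(h_masks, m_masks)):
        try:
            vals.append(hausdorff_slice(h, m, pixel_size))
        except ValueError as exc:
            raise ValueError(f"slice {i}: {exc}") from exc
    return float(np.mean(vals))


def landmark_distance(lm_h: Dict[str, Point], lm_m: Dict[str, Point]) -> float:
    """Mean Euclidean distance between identically named landmark points, mm."""
    unmatched = set(lm_h) ^ set(lm_m)
    if unmatched:
        raise ValueError(f"unmatched landmark names: {sorted(unmatched)}")
    if not lm_h:
        raise ValueError("at least one landmark required")
    dists = [float(np.hypot(lm_h[k][0] - lm_m[k][0], lm_h[k][1] - lm_m[k][1]))
             for k in lm_h]
    return float(np.mean(dists))


def center_of_mass_mm(mask: np.ndarray, pixel_size: Tuple[float, float]) -> Point:
    rr, cc = np.nonzero(np.asarray(mask) > 0)
    if rr.size == 0:
        raise ValueError("centre of mass of an empty mask is undefined")
    return (float(cc.mean() * pixel_size[0]), float(rr.mean() * pixel_size[1]))


def urethra_deviation(h_urethra: Sequence[np.ndarray], m_urethra: Sequence[np.ndarray],
                      pixel_size: Tuple[float, float]) -> float:
    """Mean centre-of-mass distance over the slices where the urethra is
    visible on both modalities; slices lacking it in either are excluded."""
    d = _check_counts(h_urethra, m_urethra)
    dists = []
    for h, m in zip(h_urethra, m_urethra):
        if not (np.any(h) and np.any(m)):
            continue
        ch = center_of_mass_mm(h, pixel_size)
        cm = center_of_mass_mm(m, pixel_size)
        dists.append(float(np.hypot(ch[0] - cm[0], ch[1] - cm[1])))
    if not dists:
        raise ValueError("urethra visible on both modalities in zero slices")
    return float(np.mean(dists))


def evaluate_stacks(h_masks: Sequence[np.ndarray], m_masks: Sequence[np.ndarray],
                    pixel_size: Tuple[float, float],
                    lm_h: Optional[Dict[str, Point]] = None,
                    lm_m: Optional[Dict[str, Point]] = None,
                    h_urethra: Optional[Sequence[np.ndarray]] = None,
                    m_urethra: Optional[Sequence[np.ndarray]] = None) -> MetricsReport:
    """Full per-case report; landmark/urethra terms are optional."""
    d = _check_counts(h_masks, m_masks)
    dice_per = [dice_slice(h, m) for h, m in zip(h_masks, m_masks)]
    haus_per = [hausdorff_slice(h, m, pixel_size) for h, m in zip(h_masks, m_masks)]
    lm = None
    if lm_h is not None and lm_m is not None and lm_h:
        lm = landmark_distance(lm_h, lm_m)
    ure, n_ure = None, 0
    if h_urethra is not None and m_urethra is not None:
        try:
            ure = urethra_deviation(h_urethra, m_urethra, pixel_size)
            n_ure = sum(1 for h, m in zip(h_urethra, m_urethra)
                        if np.any(h) and np.any(m))
        except ValueError:
            ure = None
    return MetricsReport(
        dice=float(np.mean(dice_per)),
        hausdorff_mm=float(np.mean(haus_per)),
        landmark_mm=lm,
        urethra_mm=ure,
        dice_per_slice=dice_per,
        hausdorff_per_slice=haus_per,
        n_slices=d,
        n_landmarks=len(lm_h) if lm_h else 0,
        n_urethra_slices=n_ure,
    )
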