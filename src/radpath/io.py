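"""File formats and the end-to-end pipeline driver.

On-disk case layout (all coordinates physical mm; spacing always carried in
headers or sidecar metadata, never guessed):

.. code-block:: text

    case/
      mri.nii.gz                  float32 volume, spacing in header
      mri_mask.nii.gz             uint8 prostate mask, same grid
      histology/
        meta.json                 {"pixel_size_mm": [sx, sy]}  (required)
        slice_000.png             RGB section
        slice_000_mask.png        prostate mask (0/255)
        slice_000_<label>.png     optional label images (cancer, urethra)
      correspondence.json         {"histology_to_mri": [mri slice per section]}
      gross.json                  optional {"rotation_deg": [...], "flip_lr": [...]}
      landmarks.csv               optional histology-frame points (name,slice,x_mm,y_mm)
      ref/                        optional MRI-frame references for evaluation
        urethra.nii.gz, cancer.nii.gz, landmarks.csv
      truth.json                  phantom ground truth (written by the generator)
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import SimpleITK as sitk
from PIL import Image

from . import mapping as mapping_mod
from . import metrics as metrics_mod
from .core import (
    AffineTransform2D,
    DeformableField2D,
    HistologySlice,
    HistologyStack,
    MetricsReport,
    MriVolume,
    RigidTransform2D,
    SliceTransformChain,
)
from .phantom import PhantomCase
from .slicereg import RegistrationConfig, register_case

logger = logging.getLogger("radpath.io")


# ---------------------------------------------------------------------------
# volumes

def write_volume(path: Path, array: np.ndarray,
                 spacing: Tuple[float, float, float]) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(array))
    img.SetSpacing(tuple(map(float, spacing)))
    sitk.WriteImage(img, str(path))


def read_volume(path: Path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    img = sitk.ReadImage(str(path))
    spacing = tuple(float(s) for s in img.GetSpacing())
    if len(spacing) != 3:
        raise ValueError(f"{path}: expected a 3D volume")
    return sitk.GetArrayFromImage(img), spacing  # (slices, rows, cols)


# ---------------------------------------------------------------------------
# case layout

@dataclass
class CaseLayout:
    """Paths of one case; every referenced file is checked up front."""

    root: Path
    mri: Path = field(init=False)
    mri_mask: Path = field(init=False)
    histology_dir: Path = field(init=False)
    correspondence: Path = field(init=False)

    def __post_init__(self):
        self.root = Path(self.root)
        self.mri = self.root / "mri.nii.gz"
        self.mri_mask = self.root / "mri_mask.nii.gz"
        self.histology_dir = self.root / "histology"
        self.correspondence = self.root / "correspondence.json"

    @property
    def meta(self) -> Path:
        return self.histology_dir / "meta.json"

    @property
    def gross(self) -> Path:
        return self.root / "gross.json"

    @property
    def landmarks(self) -> Path:
        return self.root / "landmarks.csv"

    def slice_path(self, i: int, suffix: str = "") -> Path:
        tail = f"_{suffix}" if suffix else ""
        return self.histology_dir / f"slice_{i:03d}{tail}.png"

    def ref_path(self, name: str) -> Path:
        return self.root / "ref" / name

    def validate(self, n_slices: int, label_names: Sequence[str] = ()) -> None:
        required = [self.mri, self.mri_mask, self.correspondence, self.meta]
        required += [self.slice_path(i) for i in range(n_slices)]
        required += [self.slice_path(i, "mask") for i in range(n_slices)]
        missing = [str(p) for p in required if not p.exists()]
        if missing:
            raise FileNotFoundError("missing case files: " + ", ".join(missing))


def _read_png_gray(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def read_case(root: Path) -> Tuple[MriVolume, HistologyStack]:
    """Load a case directory; fails fast on missing files, missing spacing
    metadata or grid mismatches."""
    layout = CaseLayout(root)
    for p in (layout.mri, layout.mri_mask, layout.correspondence, layout.meta):
        if not p.exists():
            raise FileNotFoundError(f"missing case file: {p}")

    mri_arr, spacing = read_volume(layout.mri)
    mask_arr, mask_spacing = read_volume(layout.mri_mask)
    if mri_arr.shape != mask_arr.shape:
        raise ValueError(
            f"MRI mask grid {mask_arr.shape} differs from MRI grid {mri_arr.shape}")
    mri = MriVolume(image=mri_arr.astype(np.float32), mask=mask_arr > 0,
                    spacing=spacing)

    meta = json.loads(layout.meta.read_text())
    if "pixel_size_mm" not in meta:
        raise ValueError(f"{layout.meta}: pixel_size_mm metadata is required")
    pixel_size = tuple(float(v) for v in meta["pixel_size_mm"])

    corr = json.loads(layout.correspondence.read_text())["histology_to_mri"]
    lm_by_slice: Dict[int, Dict[str, Tuple[float, float]]] = {}
    if layout.landmarks.exists():
        df = pd.read_csv(layout.landmarks)
        for _, row in df.iterrows():
            lm_by_slice.setdefault(int(row["slice"]), {})[str(row["name"])] = (
                float(row["x_mm"]), float(row["y_mm"]))

    slices = []
    for i in range(len(corr)):
        img_path = layout.slice_path(i)
        if not img_path.exists():
            raise FileNotFoundError(f"correspondence references missing slice file: {img_path}")
        rgb = np.asarray(Image.open(img_path).convert("RGB"))
        mask = _read_png_gray(layout.slice_path(i, "mask")) > 127
        labels = {}
        for name in ("cancer", "urethra"):
            p = layout.slice_path(i, name)
            if p.exists():
                labels[name] = _read_png_gray(p) > 127
        slices.append(HistologySlice(image=rgb, mask=mask, labels=labels,
                                     landmarks=lm_by_slice.get(i, {})))
    stack = HistologyStack(slices=slices, pixel_size=pixel_size,
                           correspondence=[int(j) for j in corr])
    return mri, stack


def read_gross_table(root: Path, n_slices: int
                     ) -> Tuple[List[float], List[bool]]:
    path = CaseLayout(root).gross
    if not path.exists():
        return [0.0] * n_slices, [False] * n_slices
    data = json.loads(path.read_text())
    rotation = [float(v) for v in data.get("rotation_deg", [0.0] * n_slices)]
    flips = [bool(v) for v in data.get("flip_lr", [False] * n_slices)]
    if len(rotation) != n_slices or len(flips) != n_slices:
        raise ValueError("gross table length differs from slice count")
    return rotation, flips


# ---------------------------------------------------------------------------
# phantom case writer

def _write_png(path: Path, arr: np.ndarray) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr).save(path)


def write_phantom_case(case: PhantomCase, root: Path) -> None:
    """Serialize a generated phantom to the standard case layout, including
    MRI-frame references and ground-truth transforms."""
    root = Path(root)
    layout = CaseLayout(root)
    root.mkdir(parents=True, exist_ok=True)
    write_volume(layout.mri, case.mri.image.astype(np.float32), case.mri.spacing)
    write_volume(layout.mri_mask, case.mri.mask.astype(np.uint8), case.mri.spacing)

    layout.histology_dir.mkdir(parents=True, exist_ok=True)
    layout.meta.write_text(json.dumps(
        {"pixel_size_mm": list(case.stack.pixel_size)}, indent=1))
    lm_rows = []
    for i, sl in enumerate(case.stack.slices):
        _write_png(layout.slice_path(i), sl.image)
        _write_png(layout.slice_path(i, "mask"), sl.mask)
        for name, lab in sl.labels.items():
            _write_png(layout.slice_path(i, name), lab)
        for name, (x, y) in sl.landmarks.items():
            lm_rows.append({"name": name, "slice": i, "x_mm": x, "y_mm": y})
    pd.DataFrame(lm_rows).to_csv(layout.landmarks, index=False)

    layout.correspondence.write_text(json.dumps(
        {"histology_to_mri": list(case.stack.correspondence)}, indent=1))
    flips = case.spec.flip_flags()
    layout.gross.write_text(json.dumps(
        {"rotation_deg": [0.0] * case.stack.n_slices, "flip_lr": flips}, indent=1))

    ref_dir = root / "ref"
    ref_dir.mkdir(exist_ok=True)
    for name, vol in case.ref_labels.items():
        write_volume(layout.ref_path(f"{name}.nii.gz"), vol.astype(np.uint8),
                     case.mri.spacing)
    ref_rows = [{"name": name, "slice": j, "x_mm": p[0], "y_mm": p[1]}
                for j, lms in enumerate(case.ref_landmarks)
                for name, p in lms.items()]
    pd.DataFrame(ref_rows).to_csv(layout.ref_path("landmarks.csv"), index=False)

    truth = {
        "slice_offset_mm": case.truth.slice_offset_mm,
        "per_slice": [dataclasses.asdict(a) for a in case.truth.per_slice],
    }
    (root / "truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# transform (de)serialization

def chain_to_dict(chain: SliceTransformChain) -> dict:
    d = {
        "slice_index": chain.slice_index,
        "rigid": {
            "angle_deg": chain.rigid.angle_deg,
            "translation_mm": list(chain.rigid.translation),
            "center_mm": list(chain.rigid.center),
        },
        "affine": {
            "matrix": [list(r) for r in chain.affine.matrix],
            "translation_mm": list(chain.affine.translation),
            "center_mm": list(chain.affine.center),
        },
        "deformable": None,
        "warnings": list(chain.warnings),
    }
    if not chain.deformable.is_identity:
        b = chain.deformable.bspline
        d["deformable"] = {
            "fixed_parameters": list(b.GetFixedParameters()),
            "parameters": list(b.GetParameters()),
        }
    return d


def chain_from_dict(d: dict) -> SliceTransformChain:
    rigid = RigidTransform2D(angle_deg=d["rigid"]["angle_deg"],
                             translation=tuple(d["rigid"]["translation_mm"]),
                             center=tuple(d["rigid"]["center_mm"]))
    affine = AffineTransform2D(matrix=tuple(tuple(r) for r in d["affine"]["matrix"]),
                               translation=tuple(d["affine"]["translation_mm"]),
                               center=tuple(d["affine"]["center_mm"]))
    deformable = DeformableField2D()
    if d.get("deformable"):
        b = sitk.BSplineTransform(2, 3)
        b.SetFixedParameters(d["deformable"]["fixed_parameters"])
        b.SetParameters(d["deformable"]["parameters"])
        deformable = DeformableField2D(b)
    return SliceTransformChain(d["slice_index"], rigid, affine, deformable,
                               warnings=list(d.get("warnings", [])))


def write_transforms(path: Path, chains: Sequence[SliceTransformChain]) -> None:
    Path(path).write_text(json.dumps(
        {"slices": [chain_to_dict(c) for c in chains]}, indent=1, sort_keys=True))


def read_transforms(path: Path) -> List[SliceTransformChain]:
    data = json.loads(Path(path).read_text())
    return [chain_from_dict(d) for d in data["slices"]]


# ---------------------------------------------------------------------------
# full pipeline

def run_pipeline(root: Path, out_dir: Path,
                 config: Optional[RegistrationConfig] = None,
                 write_mapped: bool = True) -> MetricsReport:
    """preprocess -> reconstruct -> register -> map -> evaluate, with per-stage
    timing logs.  Deterministic: repeated runs write byte-identical reports.

    Evaluation always scores the warped prostate masks against the MRI
    prostate mask; urethra deviation and landmark distance are added when the
    case carries MRI-frame references (``ref/``).
    """
    config = config or RegistrationConfig()
    root, out_dir = Path(root), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    mri, stack = read_case(root)
    rotation, flips = read_gross_table(root, stack.n_slices)
    logger.info("read_case: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    chains = register_case(mri, stack, config,
                           gross_rotation_deg=rotation, flip_lr=flips)
    logger.info("register_case: %.2fs", time.perf_counter() - t0)
    write_transforms(out_dir / "transforms.json", chains)

    t0 = time.perf_counter()
    spacing = stack.pixel_size
    grid = mri.image.shape[1:]
    mri_masks = [mri.slice_mask(j) for j in stack.correspondence]

    from .slicereg import preprocess
    _, pstack = preprocess(mri, stack, rotation, flips)

    warped_masks, warped_labels = [], {"cancer": [], "urethra": []}
    for i, ch in enumerate(chains):
        warped_masks.append(mapping_mod.warp_label(pstack.slices[i].mask, ch,
                                                   grid, spacing))
        for name in warped_labels:
            lab = pstack.slices[i].labels.get(name)
            warped_labels[name].append(
                mapping_mod.warp_label(lab, ch, grid, spacing)
                if lab is not None else np.zeros(grid, bool))

    lm_list = [(name, i, p) for i, sl in enumerate(pstack.slices)
               for name, p in sl.landmarks.items()]
    domain = (grid[1] * spacing[0], grid[0] * spacing[1])
    mapped_lms, _ = mapping_mod.warp_landmarks(
        lm_list, {c.slice_index: c for c in chains}, domain_mm=domain)
    logger.info("map: %.2fs", time.perf_counter() - t0)

    if write_mapped:
        mapped_dir = out_dir / "mapped"
        mapped_dir.mkdir(exist_ok=True)
        write_volume(mapped_dir / "prostate.nii.gz",
                     np.stack(warped_masks).astype(np.uint8), mri.spacing)
        for name, labs in warped_labels.items():
            if any(l.any() for l in labs):
                write_volume(mapped_dir / f"{name}.nii.gz",
                             np.stack(labs).astype(np.uint8), mri.spacing)
        pd.DataFrame([{"name": n, "slice": s, "x_mm": p[0], "y_mm": p[1]}
                      for n, s, p in mapped_lms]).to_csv(
            mapped_dir / "landmarks.csv", index=False)

    # evaluation against available references
    layout = CaseLayout(root)
    ure_ref = None
    ure_path = layout.ref_path("urethra.nii.gz")
    if ure_path.exists():
        arr, _ = read_volume(ure_path)
        ure_ref = [arr[j] > 0 for j in stack.correspondence]
    lm_h, lm_m = {}, {}
    ref_lm_path = layout.ref_path("landmarks.csv")
    if ref_lm_path.exists():
        ref_df = pd.read_csv(ref_lm_path)
        ref_pts = {(str(r["name"]), int(r["slice"])): (float(r["x_mm"]), float(r["y_mm"]))
                   for _, r in ref_df.iterrows()}
        for name, s, p in mapped_lms:
            key = (name, stack.correspondence[s])
            if key in ref_pts:
                lm_h[f"{name}:{s}"] = p
                lm_m[f"{name}:{s}"] = ref_pts[key]

    report = metrics_mod.evaluate_stacks(
        warped_masks, mri_masks, spacing,
        lm_h=lm_h or None, lm_m=lm_m or None,
        h_urethra=warped_labels["urethra"] if ure_ref is not None else None,
        m_urethra=ure_ref)
    (out_dir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True))
    return report
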