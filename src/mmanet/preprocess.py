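"""Data reading, preprocessing, augmentation, and case-level CV folds.

Pipeline order is fixed: center crop -> per-case max-min normalization ->
augmentation (training only) -> half-resolution derivation. The half-
resolution branch input is always derived from the final full-resolution
image so both encoder branches see consistent content.

Coordinate convention: row-major, 0-based, half-open windows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .synthetic import SliceSample

__all__ = [
    "CaseVolume", "FoldAssignment", "AugmentConfig",
    "read_volume", "center_crop", "minmax_normalize", "augment",
    "make_folds", "make_half_resolution", "prepare_case",
]


@dataclass
class CaseVolume:
    """One case: a stack of slices with optional aligned label stack."""

    voxels: np.ndarray                     # (S, H, W) float
    labels: Optional[np.ndarray] = None    # (S, H, W) int or None
    case_id: str = ""
    pixel_spacing: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if self.labels is not None and self.labels.shape != self.voxels.shape:
            raise ValueError(
                f"case {self.case_id!r}: labels {self.labels.shape} do not match "
                f"voxels {self.voxels.shape}"
            )


@dataclass
class FoldAssignment:
    """Case-id -> fold-index partition for k-fold cross-validation."""

    assignment: dict[str, int]
    k: int

    def fold_cases(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.assignment.items() if f == fold)

    def train_cases(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.assignment.items() if f != fold)


@dataclass
class AugmentConfig:
    """Slight geometric augmentation: the degradations are deliberately mild."""

    max_translate: float = 10.0            # px
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_deg: float = 15.0


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _read_manifest_dir(path: Path) -> list[CaseVolume]:
    from PIL import Image

    manifest = path / "manifest.csv"
    rows_by_case: dict[str, list[dict]] = {}
    with open(manifest) as fh:
        for row in csv.DictReader(fh):
            rows_by_case.setdefault(row["case_id"], []).append(row)
    volumes = []
    for case_id, rows in sorted(rows_by_case.items()):
        rows.sort(key=lambda r: int(r["slice_index"]))
        imgs, masks = [], []
        for r in rows:
            img = np.asarray(Image.open(path / r["image_path"]), dtype=np.float64) / 255.0
            msk = np.asarray(Image.open(path / r["mask_path"]), dtype=np.int64)
            if img.shape != msk.shape:
                raise ValueError(
                    f"{r['image_path']}: image {img.shape} and mask {msk.shape} differ")
            imgs.append(img)
            masks.append(msk)
        volumes.append(CaseVolume(np.stack(imgs), np.stack(masks), case_id=case_id))
    return volumes


def read_volume(path: str | Path, label_path: str | Path | None = None):
    """Read a case from a NIfTI file or a PNG-manifest directory.

    For a NIfTI image, a label companion is looked for at ``label_path`` or,
    failing that, at the ACDC-style ``<stem>_gt`` sibling; absent labels are
    allowed. A manifest directory yields a list of CaseVolume (one per case).
    The slice axis of a 3D NIfTI is taken to be the last axis.
    """
    path = Path(path)
    if path.is_dir():
        if not (path / "manifest.csv").exists():
            raise ValueError(f"{path} is a directory without a manifest.csv")
        return _read_manifest_dir(path)

    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 2:
        data = data[None]
    elif data.ndim == 3:
        data = np.moveaxis(data, -1, 0)   # (H, W, S) -> (S, H, W)
    else:
        raise ValueError(f"{path}: expected a 2D or 3D volume, got shape {data.shape}")

    labels = None
    if label_path is None:
        stem = path.name
        for ext in (".nii.gz", ".nii"):
            if stem.endswith(ext):
                cand = path.with_name(stem[: -len(ext)] + "_gt" + ext)
                if cand.exists():
                    label_path = cand
                break
    if label_path is not None:
        lab = np.asanyarray(nib.load(str(label_path)).dataobj)
        lab = lab[None] if lab.ndim == 2 else np.moveaxis(lab, -1, 0)
        if lab.shape != data.shape:
            raise ValueError(
                f"{path}: labels in {label_path} have shape {lab.shape}, "
                f"expected {data.shape}")
        labels = lab.astype(np.int64)

    spacing = None
    try:
        zooms = img.header.get_zooms()
        if len(zooms) >= 2:
            spacing = (float(zooms[0]), float(zooms[1]))
    except Exception:
        pass
    case_id = path.name.split(".")[0]
    return CaseVolume(data, labels, case_id=case_id, pixel_spacing=spacing)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def center_crop(image: np.ndarray, target_side: int) -> np.ndarray:
    """Center crop to target_side x target_side; undersized axes are first
    symmetrically zero-padded (background label 0 for masks)."""
    if target_side <= 0:
        raise ValueError("target_side must be positive")
    out = image
    for axis in (0, 1):
        deficit = target_side - out.shape[axis]
        if deficit > 0:
            before = deficit // 2
            after = deficit - before
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, after)
            out = np.pad(out, pad, mode="constant", constant_values=0)
    r0 = (out.shape[0] - target_side) // 2
    c0 = (out.shape[1] - target_side) // 2
    return out[r0:r0 + target_side, c0:c0 + target_side]


def minmax_normalize(volume: CaseVolume) -> CaseVolume:
    """Max-min normalize intensities to [0, 1] over the WHOLE case.

    A constant-intensity case maps to all zeros.
    """
    v = volume.voxels
    lo, hi = float(v.min()), float(v.max())
    if hi > lo:
        out = (v - lo) / (hi - lo)
    else:
        out = np.zeros_like(v)
    return CaseVolume(out, volume.labels, volume.case_id, volume.pixel_spacing)


def augment(sample: SliceSample, params: AugmentConfig, seed: int) -> SliceSample:
    """Apply one random translate/scale/rotate draw to image and mask alike.

    The image is interpolated bilinearly, the mask by nearest neighbor;
    out-of-frame regions are filled with 0 / background.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    ty, tx = rng.uniform(-params.max_translate, params.max_translate, size=2)
    s = rng.uniform(*params.scale_range)
    theta = np.deg2rad(rng.uniform(-params.rotation_deg, params.rotation_deg))
    return apply_affine(sample, translate=(ty, tx), scale=s, rotation_rad=theta)


def apply_affine(sample: SliceSample, translate=(0.0, 0.0), scale: float = 1.0,
                 rotation_rad: float = 0.0) -> SliceSample:
    """Deterministic rotate-scale-translate about the image center."""
    h, w = sample.image.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    t = np.asarray(translate, dtype=np.float64)
    ct, st = np.cos(rotation_rad), np.sin(rotation_rad)
    fwd = scale * np.array([[ct, -st], [st, ct]])       # content transform
    inv = np.linalg.inv(fwd)                            # output -> input mapping
    offset = c - inv @ (c + t)
    img = ndimage.affine_transform(sample.image, inv, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    mask = None
    if sample.mask is not None:
        mask = ndimage.affine_transform(sample.mask, inv, offset=offset, order=0,
                                        mode="constant", cval=0)
    return SliceSample(img, mask, case_id=sample.case_id,
                       slice_index=sample.slice_index)


def make_folds(case_ids: Sequence[str], k: int, seed: int) -> FoldAssignment:
    """Balanced case-level k-fold split (fold sizes differ by at most 1)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = list(case_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case_ids in fold assignment")
    if len(ids) < k:
        raise ValueError(f"need at least k={k} cases, got {len(ids)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    order = list(rng.permutation(len(ids)))
    n, rem = divmod(len(ids), k)
    assignment: dict[str, int] = {}
    pos = 0
    for fold in range(k):
        size = n + (1 if fold < rem else 0)
        for j in order[pos:pos + size]:
            assignment[ids[j]] = fold
        pos += size
    return FoldAssignment(assignment, k)


def make_half_resolution(image: np.ndarray) -> np.ndarray:
    """Halve both sides by 2x2 block (bilinear) averaging."""
    h, w = image.shape[-2:]
    if h % 2 or w % 2:
        raise ValueError(f"both sides must be even, got {h}x{w}")
    return image.reshape(*image.shape[:-2], h // 2, 2, w // 2, 2).mean(axis=(-3, -1))


def prepare_case(volume: CaseVolume, target_side: int) -> list[SliceSample]:
    """Crop every slice (and label) to target_side, then normalize per case."""
    imgs = np.stack([center_crop(s, target_side) for s in volume.voxels])
    labels = None
    if volume.labels is not None:
        labels = np.stack([center_crop(s, target_side) for s in volume.labels])
    vol = minmax_normalize(CaseVolume(imgs, labels, volume.case_id,
                                      volume.pixel_spacing))
    return [
        SliceSample(vol.voxels[i],
                    None if vol.labels is None else vol.labels[i],
                    case_id=volume.case_id, slice_index=i)
        for i in range(vol.voxels.shape[0])
    ]
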