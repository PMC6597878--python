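"""Patch corpora: build, augment, balance and split.

Two corpora feed the two network branches:

* 71x71x3 labeled classification patches, augmented by rotations at
  0/45/90/180 degrees;
* 128x128x4 segmentation patches (channels R, G, B, blue-ratio) with a
  two-layer binary mask (layer 0 = mitotic cell, layer 1 = non-mitotic
  cell).

Splitting operates on source-patch identity before augmentation, so
rotations of one source patch never straddle a train/test boundary. Class
balancing follows the reference recipe: hold the test set out first, then
down-sample the majority class to the minority count, then split the
remainder into train/validation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import rotate as sk_rotate

from mitoscope.candidates import BlueRatioMap, crop_centered
from mitoscope.errors import ValidationError

ALLOWED_ANGLES = (0, 45, 90, 180)
CLASSIFICATION_SIZE = 71
SEGMENTATION_SIZE = 128


@dataclass(frozen=True)
class ClassificationPatch:
    pixels: np.ndarray  # (71, 71, 3) uint8
    label: str  # "mitosis" | "not_mitosis"
    frame_id: str = ""
    centroid: tuple[float, float] = (0.0, 0.0)
    rotation_deg: int = 0

    def __post_init__(self):
        if self.label not in ("mitosis", "not_mitosis"):
            raise ValidationError(f"unknown label {self.label!r}")
        if self.rotation_deg not in ALLOWED_ANGLES:
            raise ValidationError(f"rotation must be one of {ALLOWED_ANGLES}")

    @property
    def source_id(self) -> str:
        """Identity of the un-augmented source patch (for leakage-free splits)."""
        return f"{self.frame_id}:{self.centroid[0]:.1f}:{self.centroid[1]:.1f}"


@dataclass(frozen=True)
class SegmentationPatch:
    pixels: np.ndarray  # (128, 128, 4) float32, channels R,G,B,BR on [0,255]
    mask: np.ndarray    # (128, 128, 2) bool, layers (mitosis, non-mitosis)
    center_label: str
    frame_id: str = ""
    centroid: tuple[float, float] = (0.0, 0.0)

    # the trainer treats this like the classification corpus
    @property
    def label(self) -> str:
        return self.center_label


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[int, ...]
    val_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    seed: int

    def __post_init__(self):
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValidationError("split parts overlap")


def _rotate45(pixels: np.ndarray) -> np.ndarray:
    out = sk_rotate(pixels.astype(np.float64), 45, resize=False, order=1,
                    mode="reflect", preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(pixels.dtype)


def rotate_pixels(pixels: np.ndarray, angle: int) -> np.ndarray:
    """Rotate a patch by one of the supported angles.

    0/90/180 are exact grid rotations; 45 resamples bilinearly about the
    patch center with reflection fill, cropped back to the original size.
    """
    if angle == 0:
        return pixels.copy()
    if angle == 90:
        return np.rot90(pixels, 1).copy()
    if angle == 180:
        return np.rot90(pixels, 2).copy()
    if angle == 45:
        return _rotate45(pixels)
    raise ValidationError(f"unsupported rotation {angle}; allowed: {ALLOWED_ANGLES}")


def augment_rotations(patches: list[ClassificationPatch],
                      angles=ALLOWED_ANGLES) -> list[ClassificationPatch]:
    """Expand each patch into one copy per angle; output size = |patches| x |angles|."""
    bad = [a for a in angles if a not in ALLOWED_ANGLES]
    if bad:
        raise ValidationError(f"unsupported angles {bad}; allowed: {ALLOWED_ANGLES}")
    out = []
    for patch in patches:
        for angle in angles:
            out.append(replace(patch, pixels=rotate_pixels(patch.pixels, angle),
                               rotation_deg=int(angle)))
    return out


def build_segmentation_patch(frame: np.ndarray, br: BlueRatioMap,
                             mitosis_mask: np.ndarray, nonmitosis_mask: np.ndarray,
                             centroid: tuple[float, float], label: str,
                             frame_id: str = "",
                             size: int = SEGMENTATION_SIZE) -> SegmentationPatch:
    """Cut aligned (R,G,B,BR) and two-layer mask crops around ``centroid``."""
    stacked = np.concatenate(
        [np.asarray(frame, dtype=np.float32),
         br.values.astype(np.float32)[..., None]], axis=2)
    pixels = crop_centered(stacked, centroid, size)
    mask = np.stack([crop_centered(np.asarray(mitosis_mask, dtype=bool), centroid, size),
                     crop_centered(np.asarray(nonmitosis_mask, dtype=bool), centroid, size)],
                    axis=2)
    return SegmentationPatch(pixels=pixels, mask=mask, center_label=label,
                             frame_id=frame_id,
                             centroid=(float(centroid[0]), float(centroid[1])))


def balance_classes(patches: list, seed: int) -> list:
    """Down-sample the majority class to the minority count, seeded.

    Every minority item is preserved; the kept majority items are a uniform
    random subset; the original relative order of kept items is preserved.
    Output length is exactly twice the minority count.
    """
    labels = [p.label for p in patches]
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes present, got {classes}")
    idx_by_class = {c: [i for i, lab in enumerate(labels) if lab == c] for c in classes}
    minority, majority = sorted(classes, key=lambda c: len(idx_by_class[c]))
    n_min = len(idx_by_class[minority])
    rng = np.random.default_rng(seed)
    keep_major = rng.choice(len(idx_by_class[majority]), size=n_min, replace=False)
    kept = set(idx_by_class[minority]) | {idx_by_class[majority][k] for k in keep_major}
    return [p for i, p in enumerate(patches) if i in kept]


def holdout_test(patches: list, n_test_by_class: dict[str, int], seed: int
                 ) -> tuple[list, list]:
    """Seeded uniform hold-out of ``n_test_by_class[label]`` items per class.

    Returns ``(test, remaining)``, each preserving original order.
    """
    rng = np.random.default_rng(seed)
    test_idx: set[int] = set()
    for label, n_test in n_test_by_class.items():
        idx = [i for i, p in enumerate(patches) if p.label == label]
        if n_test > len(idx):
            raise ValidationError(
                f"cannot hold out {n_test} {label!r} items from {len(idx)}")
        chosen = rng.choice(len(idx), size=n_test, replace=False)
        test_idx |= {idx[k] for k in chosen}
    test = [p for i, p in enumerate(patches) if i in test_idx]
    remaining = [p for i, p in enumerate(patches) if i not in test_idx]
    return test, remaining


def _largest_remainder(n: int, fractions) -> list[int]:
    raw = [n * f for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    short = n - sum(base)
    order = np.argsort([b - x for b, x in zip(base, raw)])  # largest remainder first
    for k in order[:short]:
        base[k] += 1
    return base


def split_dataset(corpus: list, fractions: tuple[float, float, float],
                  seed: int) -> DatasetSplit:
    """Stratified seeded train/val/test split by index.

    Per-class shuffle followed by a contiguous largest-remainder partition,
    so per-class fractions match the global ones within one item.
    """
    if any(f < 0 for f in fractions) or len(fractions) != 3:
        raise ValidationError("fractions must be three non-negative numbers")
    if not (0.999 <= sum(fractions) <= 1.001):
        raise ValidationError(f"fractions must sum to 1, got {sum(fractions)}")
    labels = [getattr(p, "label", p) for p in corpus]
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in sorted(set(labels)):
        idx = np.asarray([i for i, lab in enumerate(labels) if lab == cls])
        rng.shuffle(idx)
        n_tr, n_va, n_te = _largest_remainder(len(idx), fractions)
        train += idx[:n_tr].tolist()
        val += idx[n_tr:n_tr + n_va].tolist()
        test += idx[n_tr + n_va:].tolist()
    return DatasetSplit(train_ids=tuple(sorted(train)), val_ids=tuple(sorted(val)),
                        test_ids=tuple(sorted(test)), seed=seed)


def save_split(split: DatasetSplit, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump({"train": list(split.train_ids), "val": list(split.val_ids),
                   "test": list(split.test_ids), "seed": split.seed}, fh)


def load_split(path: str | os.PathLike) -> DatasetSplit:
    with open(path) as fh:
        d = json.load(fh)
    return DatasetSplit(tuple(d["train"]), tuple(d["val"]), tuple(d["test"]), d["seed"])


def save_manifest(patches: list[ClassificationPatch], split: DatasetSplit,
                  path: str | os.PathLike) -> None:
    """Write the corpus manifest CSV (one row per patch, with its split part)."""
    part = {}
    for name, ids in (("train", split.train_ids), ("val", split.val_ids),
                      ("test", split.test_ids)):
        for i in ids:
            part[i] = name
    rows = [{"patch_id": i, "frame_id": p.frame_id,
             "centroid_row": p.centroid[0], "centroid_col": p.centroid[1],
             "label": p.label, "rotation_deg": p.rotation_deg,
             "split": part.get(i, "")} for i, p in enumerate(patches)]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_patch_images(patches: list, out_dir: str | os.PathLike) -> Path:
    """Persist patches as PNGs (RGB, BR channel, mask layers) for inspection."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, p in enumerate(patches):
        if isinstance(p, SegmentationPatch):
            rgb = np.clip(np.rint(p.pixels[..., :3]), 0, 255).astype(np.uint8)
            br = np.clip(np.rint(p.pixels[..., 3]), 0, 255).astype(np.uint8)
            iio.imwrite(out / f"patch_{i:05d}_rgb.png", rgb, extension=".png")
            iio.imwrite(out / f"patch_{i:05d}_br.png", br, extension=".png")
            for k, layer in enumerate(("mitosis", "nonmitosis")):
                iio.imwrite(out / f"patch_{i:05d}_mask_{layer}.png",
                            np.where(p.mask[..., k], 255, 0).astype(np.uint8),
                            extension=".png")
        else:
            iio.imwrite(out / f"patch_{i:05d}_rgb.png", p.pixels.astype(np.uint8),
                        extension=".png")
    return out
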