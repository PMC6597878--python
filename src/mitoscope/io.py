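"""Reading and writing of frames, masks and centroid annotations.

Frames are 8-bit RGB PNG; class masks are 8-bit single-channel PNG with
0 = background and 255 = foreground, one file per class layer. Annotations
travel as CSV with header ``frame_id,centroid_row,centroid_col,label`` where
``label`` is ``mitosis`` or ``not_mitosis``. Coordinates are 0-based
(row, col) with pixel centers at integer coordinates; every module shares
this convention.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

from mitoscope.errors import ValidationError

ANNOTATION_COLUMNS = ["frame_id", "centroid_row", "centroid_col", "label"]
LABELS = ("mitosis", "not_mitosis")


def write_frame(path: str | os.PathLike, frame: np.ndarray) -> None:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValidationError(f"expected an HxWx3 RGB frame, got shape {frame.shape}")
    iio.imwrite(path, frame.astype(np.uint8), extension=".png")


def read_frame(path: str | os.PathLike) -> np.ndarray:
    frame = iio.imread(path)
    if frame.ndim == 3 and frame.shape[2] == 4:  # drop alpha if present
        frame = frame[..., :3]
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValidationError(f"{path} is not an RGB image (shape {frame.shape})")
    return np.asarray(frame, dtype=np.uint8)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError(f"expected a 2-D binary mask, got shape {mask.shape}")
    iio.imwrite(path, np.where(mask.astype(bool), 255, 0).astype(np.uint8), extension=".png")


def read_mask(path: str | os.PathLike) -> np.ndarray:
    mask = iio.imread(path)
    if mask.ndim != 2:
        raise ValidationError(f"{path} is not a single-channel mask (shape {mask.shape})")
    return mask > 127


def write_annotations(path: str | os.PathLike, rows: list[dict]) -> None:
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValidationError(f"unknown annotation labels: {sorted(bad)}")
    df.to_csv(path, index=False)


def read_annotations(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation CSV {path} lacks columns {missing}")
    return df[ANNOTATION_COLUMNS]
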