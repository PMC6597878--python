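"""Blue-ratio candidate detection.

Hematoxylin stains nuclei blue-purple, so a per-pixel transform that boosts
blue-dominant pixels separates nuclei from the pink eosin-stained stroma.
The blue-ratio map

    I_BR = (c1 * B / (1 + R + G)) * (c2 / (1 + R + G + B))

with defaults (c1, c2) = (100, 256) is thresholded, cleaned with a
morphological opening, and its 8-connected components become candidate
nuclei. Candidates are handed to the classifier as patches centered on
their centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, opening

from mitoscope.errors import ValidationError

DEFAULT_BR_CONSTANTS = (100.0, 256.0)
#: alternative scaling preset with both factors on the 8-bit scale
BR_CONSTANTS_255 = (255.0, 255.0)


@dataclass(frozen=True)
class DetectConfig:
    """Candidate-detection parameters (threshold and opening radius were
    kept as fixed defaults of the method)."""

    threshold: float = 30.0
    opening_radius: int = 1
    br_constants: tuple[float, float] = DEFAULT_BR_CONSTANTS
    min_area: int = 0
    patch_size: int = 71

    def validate(self) -> None:
        if not (0 <= self.threshold <= 255):
            raise ValidationError("threshold must be in [0, 255]")
        if self.opening_radius < 0:
            raise ValidationError("opening_radius must be >= 0")
        if self.min_area < 0:
            raise ValidationError("min_area must be >= 0")
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ValidationError("patch_size must be a positive odd integer")
        if len(self.br_constants) != 2 or any(c <= 0 for c in self.br_constants):
            raise ValidationError("br_constants must be two positive numbers")


@dataclass(frozen=True)
class BlueRatioMap:
    """Frame-sized non-negative blue-ratio image, clipped to [0, 255]."""

    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class Candidate:
    centroid_row: float
    centroid_col: float
    area_px: int
    bounding_box: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) half-open


@dataclass
class CandidateSet:
    frame_id: str = ""
    candidates: list[Candidate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def centroids(self) -> np.ndarray:
        return np.asarray([(c.centroid_row, c.centroid_col) for c in self.candidates],
                          dtype=float).reshape(-1, 2)


def blue_ratio(frame: np.ndarray,
               constants: tuple[float, float] = DEFAULT_BR_CONSTANTS) -> BlueRatioMap:
    """Blue-ratio transform of an 8-bit RGB frame.

    Denominators are >= 1 by construction, so the map is defined everywhere;
    values are clipped to [0, 255].
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValidationError(f"expected an HxWx3 RGB frame, got shape {frame.shape}")
    c1, c2 = constants
    r = frame[..., 0].astype(np.float64)
    g = frame[..., 1].astype(np.float64)
    b = frame[..., 2].astype(np.float64)
    values = (c1 * b / (1.0 + r + g)) * (c2 / (1.0 + r + g + b))
    return BlueRatioMap(values=np.clip(values, 0.0, 255.0))


def segment_candidates(br: BlueRatioMap, config: DetectConfig,
                       frame_id: str = "") -> CandidateSet:
    """Threshold, open, and label the blue-ratio map into candidates.

    The binary mask is ``br >= threshold``, opened with a digital disk of
    radius ``opening_radius`` (radius 1 is the 3x3 cross); 8-connected
    components with area >= ``min_area`` become candidates whose centroid
    is the unweighted mean of component pixel coordinates.
    """
    config.validate()
    mask = br.values >= config.threshold
    if config.opening_radius > 0:
        mask = opening(mask, disk(config.opening_radius))
    out = CandidateSet(frame_id=frame_id)
    if not mask.any():
        return out
    labeled = cc_label(mask, connectivity=2)
    for region in regionprops(labeled):
        if region.area < max(config.min_area, 1):
            continue
        r0, c0 = region.centroid
        out.candidates.append(Candidate(
            centroid_row=float(r0), centroid_col=float(c0),
            area_px=int(region.area), bounding_box=tuple(int(v) for v in region.bbox)))
    return out


def crop_centered(image: np.ndarray, centroid: tuple[float, float], size: int) -> np.ndarray:
    """``size``-square crop centered on the rounded centroid, reflection-padded.

    Works for 2-D (mask/BR) and 3-D (multi-channel) arrays; padding uses
    edge-excluding reflection.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    r = int(np.rint(centroid[0]))
    c = int(np.rint(centroid[1]))
    if not (0 <= r < h and 0 <= c < w):
        raise ValidationError(f"centroid {centroid} outside frame of shape {(h, w)}")
    half = size // 2
    pad = [(half, half), (half, half)] + [(0, 0)] * (image.ndim - 2)
    padded = np.pad(image, pad, mode="reflect")
    return padded[r:r + size, c:c + size, ...]


def extract_patch(frame: np.ndarray, centroid: tuple[float, float], size: int) -> np.ndarray:
    """Crop a size x size x 3 classification patch centered on ``centroid``."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValidationError(f"expected an HxWx3 RGB frame, got shape {frame.shape}")
    return crop_centered(frame, centroid, size)


def match_candidates(candidates: CandidateSet, truth_centroids, tolerance: float
                     ) -> tuple[int, int, int]:
    """Greedy nearest-distance one-to-one matching of candidates to truths.

    Returns ``(n_matched, n_missed, n_spurious)``; the three counts
    partition both lists (matched + missed = truths, matched + spurious =
    candidates).
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")
    cand = candidates.centroids()
    truth = np.asarray(truth_centroids, dtype=float).reshape(-1, 2)
    n_c, n_t = len(cand), len(truth)
    if n_c == 0 or n_t == 0:
        return 0, n_t, n_c
    d = np.linalg.norm(cand[:, None, :] - truth[None, :, :], axis=2)
    pairs = [(d[i, j], i, j) for i in range(n_c) for j in range(n_t) if d[i, j] <= tolerance]
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    for _, i, j in pairs:
        if i not in used_c and j not in used_t:
            used_c.add(i)
            used_t.add(j)
    n_matched = len(used_t)
    return n_matched, n_t - n_matched, n_c - n_matched
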