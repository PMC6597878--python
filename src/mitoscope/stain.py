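"""Color normalization by per-channel statistics transfer.

Each RGB frame is converted to a perceptual opponent color space, its
per-channel mean and standard deviation are matched to those of a target
(derived from a frame collection), and the result is converted back to RGB:

    I_n(i) = (I_s(i) - mu_s(i)) * sigma_t(i) / sigma_s(i) + mu_t(i)

for channel i. The working space is CIE L*a*b* (D65) by default; Reinhard's
original l-alpha-beta decorrelated log space is available via ``space``.
Target statistics are pooled-pixel moments over the whole collection (not
the moments of an averaged image, which would collapse sigma_t toward
zero). The variance convention is population (divide by N) throughout.
Normalization is applied to whole frames before any patch generation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import yaml
from skimage.color import lab2rgb, rgb2lab

from mitoscope.errors import DegenerateStatisticsError, ValidationError

SPACES = ("lab", "lalphabeta")

# Ruderman et al. RGB <-> l-alpha-beta pipeline, as used by Reinhard's
# original statistics-transfer method.
_RGB2LMS = np.array([[0.3811, 0.5783, 0.0402],
                     [0.1967, 0.7244, 0.0782],
                     [0.0241, 0.1288, 0.8444]])
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LOGLMS2LAB = (np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)])
               @ np.array([[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float))
_LAB2LOGLMS = np.linalg.inv(_LOGLMS2LAB)
_LMS_EPS = 1.0 / 255.0


@dataclass(frozen=True)
class LabStats:
    """Per-channel mean and standard deviation in the working color space."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]
    space: str = "lab"

    def __post_init__(self):
        if self.space not in SPACES:
            raise ValidationError(f"unknown color space {self.space!r}; use one of {SPACES}")
        if len(self.mean) != 3 or len(self.std) != 3:
            raise ValidationError("mean and std must each have 3 channels")
        if any(s <= 0 for s in self.std):
            raise DegenerateStatisticsError(f"non-positive channel std: {self.std}")

    def to_dict(self) -> dict:
        return {"space": self.space,
                "mean": [float(m) for m in self.mean],
                "std": [float(s) for s in self.std]}

    @classmethod
    def from_dict(cls, d: dict) -> "LabStats":
        return cls(mean=tuple(d["mean"]), std=tuple(d["std"]), space=d.get("space", "lab"))

    def save(self, path: str | os.PathLike) -> None:
        text = (json.dumps(self.to_dict(), indent=2) if str(path).endswith(".json")
                else yaml.safe_dump(self.to_dict()))
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "LabStats":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _to_space(frame: np.ndarray, space: str) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValidationError(f"expected an HxWx3 RGB frame, got shape {frame.shape}")
    if frame.size == 0:
        raise ValidationError("frame is empty")
    rgb = frame.astype(np.float64) / 255.0
    if space == "lab":
        return rgb2lab(rgb)
    if space == "lalphabeta":
        lms = np.clip(rgb @ _RGB2LMS.T, _LMS_EPS, None)
        return np.log10(lms) @ _LOGLMS2LAB.T
    raise ValidationError(f"unknown color space {space!r}")


def _from_space(values: np.ndarray, space: str) -> np.ndarray:
    if space == "lab":
        rgb = lab2rgb(values)
    else:
        lms = np.power(10.0, values @ _LAB2LOGLMS.T)
        rgb = lms @ _LMS2RGB.T
    rgb = np.clip(rgb, 0.0, 1.0)  # gamut clipping
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def channel_moments(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Population mean and std per channel over all pixels of an (..., 3) array."""
    flat = np.asarray(values, dtype=np.float64).reshape(-1, 3)
    return flat.mean(axis=0), flat.std(axis=0, ddof=0)


def compute_lab_stats(frame: np.ndarray, space: str = "lab") -> LabStats:
    """Per-channel mean/std over all pixels of the frame's color transform.

    Raises DegenerateStatisticsError when any channel has zero variance
    (e.g., a constant-color frame), because such a frame cannot be a source
    for statistics transfer.
    """
    mean, std = channel_moments(_to_space(frame, space))
    if np.any(std <= 0):
        raise DegenerateStatisticsError(
            f"zero variance on channel(s) {np.where(std <= 0)[0].tolist()}")
    return LabStats(mean=tuple(mean), std=tuple(std), space=space)


def compute_target_stats(frames, space: str = "lab") -> LabStats:
    """Pooled per-channel moments over all pixels of all frames.

    Exact pooling via per-frame sums and sums of squares, so frames of
    different sizes are weighted by pixel count.
    """
    n = 0
    s = np.zeros(3)
    s2 = np.zeros(3)
    for frame in frames:
        vals = _to_space(frame, space).reshape(-1, 3)
        n += vals.shape[0]
        s += vals.sum(axis=0)
        s2 += np.square(vals).sum(axis=0)
    if n == 0:
        raise ValidationError("compute_target_stats needs at least one frame")
    mean = s / n
    var = np.maximum(s2 / n - mean ** 2, 0.0)
    std = np.sqrt(var)
    if np.any(std <= 0):
        raise DegenerateStatisticsError("pooled statistics are degenerate")
    return LabStats(mean=tuple(mean), std=tuple(std), space=space)


def transfer_channels(values: np.ndarray, source_mean, source_std,
                      target_mean, target_std) -> np.ndarray:
    """Per-channel statistics transfer on an (..., 3) array (or scalars):
    ``(values - mu_s) * sigma_t / sigma_s + mu_t``."""
    values = np.asarray(values, dtype=np.float64)
    mu_s, sd_s = np.asarray(source_mean), np.asarray(source_std)
    mu_t, sd_t = np.asarray(target_mean), np.asarray(target_std)
    return (values - mu_s) * (sd_t / sd_s) + mu_t


def normalize_frame(source: np.ndarray, target: LabStats) -> np.ndarray:
    """Transfer the target's per-channel statistics onto ``source``.

    The source's own moments provide (mu_s, sigma_s); output is converted
    back to RGB with gamut clipping and has the source's dimensions.
    """
    space = target.space
    vals = _to_space(source, space)
    mu_s, sigma_s = channel_moments(vals)
    if np.any(sigma_s <= 0):
        raise DegenerateStatisticsError("source frame has a zero-variance channel")
    out = transfer_channels(vals, mu_s, sigma_s, target.mean, target.std)
    return _from_space(out, space)
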