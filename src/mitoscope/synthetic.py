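"""Seeded synthetic H&E-like high-power-field generator.

Emulates the statistical structure the pipeline assumes about
hematoxylin-and-eosin frames: bluish-purple nuclei on pinkish stroma, a
darker and more irregular palette for mitotic figures, per-nucleus color
jitter, per-pixel texture noise, and a per-frame global stain shift that
mimics inter-scanner/inter-staining variability. Ground truth (centroids,
per-class masks) is exact by construction.

Nuclei are star-convex perturbed ellipses: an ellipse boundary is dented
inward by a smooth random radial modulation, so each nucleus stays inside
its nominal ellipse (which is what makes the ``min_separation`` overlap
guarantee provable) while mitotic figures get visibly rougher outlines.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon

from mitoscope import io as mio
from mitoscope.errors import PlacementError, ValidationError

#: radial dent amplitude bounds (fraction of local radius) per class
_IRREGULARITY = {"mitosis": 0.15, "not_mitosis": 0.06}
_BOUNDARY_POINTS = 72


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic frame.

    Defaults give a 512x512 frame whose palettes are linearly separable in
    mean color: mitotic nuclei are darker and bluer than non-mitotic nuclei,
    and both are far from the pink stroma in blue-ratio terms.
    """

    frame_height: int = 512
    frame_width: int = 512
    n_mitotic: int = 8
    n_nonmitotic: int = 12
    nucleus_radius_range: tuple[float, float] = (9.0, 15.0)
    mitotic_color_mean: tuple[float, float, float] = (60.0, 40.0, 110.0)
    nonmitotic_color_mean: tuple[float, float, float] = (110.0, 80.0, 160.0)
    stroma_color_mean: tuple[float, float, float] = (230.0, 150.0, 200.0)
    color_jitter_sd: float = 8.0
    stain_shift_sd: float = 12.0
    texture_noise_sd: float = 6.0
    min_separation: float = 36.0

    def validate(self) -> None:
        if self.frame_height < 32 or self.frame_width < 32:
            raise ValidationError("frame must be at least 32x32 pixels")
        if self.n_mitotic < 0 or self.n_nonmitotic < 0:
            raise ValidationError("nucleus counts must be non-negative")
        rmin, rmax = self.nucleus_radius_range
        if rmin < 2 or rmax < rmin:
            raise ValidationError("nucleus radii must satisfy 2 <= rmin <= rmax")
        for name in ("mitotic_color_mean", "nonmitotic_color_mean", "stroma_color_mean"):
            col = getattr(self, name)
            if len(col) != 3 or any(not (0 <= c <= 255) for c in col):
                raise ValidationError(f"{name} must be an RGB triplet in [0, 255]")
        if self.color_jitter_sd < 0 or self.stain_shift_sd < 0 or self.texture_noise_sd < 0:
            raise ValidationError("noise standard deviations must be non-negative")
        if self.min_separation <= 2 * rmax:
            raise ValidationError(
                f"min_separation ({self.min_separation}) must exceed twice the "
                f"maximum nucleus radius ({2 * rmax}) to prevent overlap")


@dataclass(frozen=True)
class Nucleus:
    """Ground truth for one rendered nucleus."""

    centroid_row: int
    centroid_col: int
    semi_axes: tuple[float, float]
    orientation: float  # radians, in [0, pi)
    label: str  # "mitosis" | "not_mitosis"


@dataclass
class SceneTruth:
    """Exact ground truth of a generated frame."""

    nuclei: list[Nucleus] = field(default_factory=list)
    mitosis_mask: np.ndarray | None = None
    nonmitosis_mask: np.ndarray | None = None

    def centroids(self, label: str | None = None) -> np.ndarray:
        pts = [(n.centroid_row, n.centroid_col) for n in self.nuclei
               if label is None or n.label == label]
        return np.asarray(pts, dtype=float).reshape(-1, 2)


def _nucleus_mask(rng: np.random.Generator, center: tuple[int, int],
                  semi_axes: tuple[float, float], theta: float, label: str,
                  shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of a star-convex dented ellipse (inward dents only)."""
    a, b = semi_axes
    amp = _IRREGULARITY[label]
    t = np.linspace(0.0, 2 * np.pi, _BOUNDARY_POINTS, endpoint=False)
    # smooth periodic radial modulation from two low-order harmonics
    a1, a2 = rng.uniform(0, amp, 2)
    p1, p2 = rng.uniform(0, 2 * np.pi, 2)
    dent = np.abs(a1 * np.sin(2 * t + p1) + a2 * np.sin(3 * t + p2))
    scale = 1.0 - dent
    x = a * np.cos(t) * scale
    y = b * np.sin(t) * scale
    rows = center[0] + x * np.sin(theta) + y * np.cos(theta)
    cols = center[1] + x * np.cos(theta) - y * np.sin(theta)
    return draw_polygon(rows, cols, shape=shape)


def generate_scene(config: SceneConfig, seed: int) -> tuple[np.ndarray, SceneTruth]:
    """Render one frame and its exact ground truth, deterministically.

    Returns an (H, W, 3) uint8 frame and a :class:`SceneTruth` whose two
    masks are disjoint and mark exactly the rendered nucleus pixels
    (before noise; noise never moves mask membership).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    h, w = config.frame_height, config.frame_width
    rmin, rmax = config.nucleus_radius_range

    margin = int(np.ceil(rmax)) + 2
    if 2 * margin >= min(h, w):
        raise ValidationError("frame too small for the configured nucleus radii")

    n_total = config.n_mitotic + config.n_nonmitotic
    centers: list[tuple[int, int]] = []
    max_attempts = 200 * max(n_total, 1) + 200
    attempts = 0
    while len(centers) < n_total:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {len(centers)}/{n_total} nuclei after {attempts} attempts; "
                "reduce counts or min_separation")
        attempts += 1
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if all((r - rr) ** 2 + (c - cc) ** 2 >= config.min_separation ** 2
               for rr, cc in centers):
            centers.append((r, c))

    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = np.asarray(config.stroma_color_mean, dtype=np.float64)
    mito_mask = np.zeros((h, w), dtype=bool)
    nonmito_mask = np.zeros((h, w), dtype=bool)

    labels = ["mitosis"] * config.n_mitotic + ["not_mitosis"] * config.n_nonmitotic
    nuclei: list[Nucleus] = []
    for (r, c), label in zip(centers, labels):
        a = float(rng.uniform(rmin, rmax))
        b = float(rng.uniform(rmin, a))
        theta = float(rng.uniform(0, np.pi))
        rr, cc = _nucleus_mask(rng, (r, c), (a, b), theta, label, (h, w))
        mean = config.mitotic_color_mean if label == "mitosis" else config.nonmitotic_color_mean
        color = np.asarray(mean) + rng.normal(0, config.color_jitter_sd, 3)
        canvas[rr, cc] = color
        (mito_mask if label == "mitosis" else nonmito_mask)[rr, cc] = True
        nuclei.append(Nucleus(r, c, (a, b), theta, label))

    canvas += rng.normal(0, config.stain_shift_sd, 3)           # per-frame stain shift
    canvas += rng.normal(0, config.texture_noise_sd, (h, w, 3))  # per-pixel texture
    frame = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return frame, SceneTruth(nuclei=nuclei, mitosis_mask=mito_mask,
                             nonmitosis_mask=nonmito_mask)


def frame_seeds(master_seed: int, n_frames: int) -> list[int]:
    """Deterministic per-frame seeds (< 2^31) derived from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_frames, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def generate_dataset(n_frames: int, config: SceneConfig, seed: int,
                     out_dir: str | os.PathLike) -> Path:
    """Write ``n_frames`` frames with masks and annotation CSVs to ``out_dir``.

    Layout per frame ``i``: ``frame_{i:03d}.png``,
    ``frame_{i:03d}_mitosis.png`` / ``_nonmitosis.png`` mask layers, and
    ``frame_{i:03d}.csv`` in the shared annotation dialect.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, fseed in enumerate(frame_seeds(seed, n_frames)):
        frame_id = f"frame_{i:03d}"
        frame, truth = generate_scene(config, fseed)
        mio.write_frame(out / f"{frame_id}.png", frame)
        mio.write_mask(out / f"{frame_id}_mitosis.png", truth.mitosis_mask)
        mio.write_mask(out / f"{frame_id}_nonmitosis.png", truth.nonmitosis_mask)
        rows = [{"frame_id": frame_id, "centroid_row": n.centroid_row,
                 "centroid_col": n.centroid_col, "label": n.label}
                for n in truth.nuclei]
        mio.write_annotations(out / f"{frame_id}.csv", rows)
    return out
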