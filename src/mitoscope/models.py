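"""The two network architectures as pure builders.

* :func:`build_classifier` — an AlexNet-style binary patch classifier:
  five convolutional stages and two hidden dense layers, with the input
  stem adapted to 71x71x3 color-normalized patches and a two-way
  softmax-normalized head.
* :func:`build_segmenter` — a U-Net-style encoder-decoder on 128x128x4
  (R, G, B, blue-ratio) patches producing two per-pixel probability maps
  (mitotic cell, non-mitotic cell) at input resolution, using
  same-padded convolutions so the output matches the mask size.

A ``width_multiplier``/``base_width`` knob lets full-size and reduced
"desk" instances (the test defaults) share one code path.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from mitoscope.errors import ValidationError
from mitoscope.nn import (
    Center,
    Conv2d,
    Dense,
    Dropout,
    Flatten,
    MaxPool2,
    ReLU,
    Sequential,
    Upsample2,
    sigmoid,
    softmax,
)

FULL_CONV_WIDTHS = (96, 256, 384, 384, 256)
FULL_DENSE_WIDTHS = (4096, 4096)


@dataclass(frozen=True)
class ClassifierSpec:
    """Five conv stages + two hidden dense layers, two-class head."""

    input_size: int = 71
    conv_stage_widths: tuple[int, ...] = FULL_CONV_WIDTHS
    dense_widths: tuple[int, ...] = FULL_DENSE_WIDTHS
    n_classes: int = 2
    width_multiplier: float = 1.0
    dropout: float = 0.5

    def validate(self) -> None:
        if len(self.conv_stage_widths) != 5:
            raise ValidationError("classifier needs exactly 5 convolutional stages")
        if len(self.dense_widths) != 2:
            raise ValidationError("classifier needs exactly 2 hidden dense layers")
        if not (0 < self.width_multiplier <= 1):
            raise ValidationError("width_multiplier must be in (0, 1]")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.input_size < 16:
            raise ValidationError("input_size too small for the five-stage topology")

    def scaled_widths(self) -> tuple[list[int], list[int]]:
        m = self.width_multiplier
        conv = [max(1, int(round(w * m))) for w in self.conv_stage_widths]
        dense = [max(1, int(round(w * m))) for w in self.dense_widths]
        return conv, dense

    @classmethod
    def desk(cls) -> "ClassifierSpec":
        """Reduced preset for CPU-scale runs and tests."""
        return cls(width_multiplier=0.25)


@dataclass(frozen=True)
class SegmenterSpec:
    """Encoder-decoder with one skip connection per level."""

    input_size: int = 128
    input_channels: int = 4
    depth: int = 4
    base_width: int = 64
    out_channels: int = 2

    def validate(self) -> None:
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.base_width < 1:
            raise ValidationError("base_width must be >= 1")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValidationError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2 ** self.depth}")

    @classmethod
    def desk(cls) -> "SegmenterSpec":
        """Reduced preset for CPU-scale runs and tests."""
        return cls(base_width=8)


class Classifier:
    """Sequential patch classifier; ``predict_proba`` rows sum to 1."""

    def __init__(self, spec: ClassifierSpec, seed: int):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        conv_w, dense_w = spec.scaled_widths()
        layers = [Center(0.5)]
        in_ch = 3
        # stem: 7x7 stride 2 + pool; then 5x5 + pool; three 3x3; final pool
        stage_geom = [(7, 2, True), (5, 1, True), (3, 1, False), (3, 1, False), (3, 1, True)]
        size = spec.input_size
        for width, (k, s, pool) in zip(conv_w, stage_geom):
            layers += [Conv2d(in_ch, width, k, rng, stride=s), ReLU()]
            size = -(-size // s)
            if pool:
                layers.append(MaxPool2())
                size //= 2
            in_ch = width
        layers.append(Flatten())
        feat = size * size * in_ch
        for width in dense_w:
            layers += [Dense(feat, width, rng), ReLU(), Dropout(spec.dropout, rng)]
            feat = width
        layers.append(Dense(feat, spec.n_classes, rng))
        self.net = Sequential(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = [softmax(self.net.forward(x[i:i + batch_size]))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    # checkpointing plumbing
    def parametrized(self):
        return self.net.parametrized()

    def num_params(self) -> int:
        return self.net.num_params()

    def get_state(self):
        return self.net.get_state()

    def set_state(self, state):
        self.net.set_state(state)


class _EncLevel:
    def __init__(self, in_ch, out_ch, rng):
        self.conv1, self.act1 = Conv2d(in_ch, out_ch, 3, rng), ReLU()
        self.conv2, self.act2 = Conv2d(out_ch, out_ch, 3, rng), ReLU()
        self.pool = MaxPool2()


class _DecLevel:
    def __init__(self, in_ch, skip_ch, out_ch, rng):
        self.up = Upsample2()
        self.upconv, self.upact = Conv2d(in_ch, out_ch, 3, rng), ReLU()
        self.conv1, self.act1 = Conv2d(skip_ch + out_ch, out_ch, 3, rng), ReLU()
        self.conv2, self.act2 = Conv2d(out_ch, out_ch, 3, rng), ReLU()
        self.skip_channels = skip_ch


class Segmenter:
    """U-Net-style network; ``predict_proba`` maps are per-channel sigmoids."""

    def __init__(self, spec: SegmenterSpec, seed: int):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = [spec.base_width * (2 ** i) for i in range(spec.depth)]
        self.enc: list[_EncLevel] = []
        in_ch = spec.input_channels
        for w in widths:
            self.enc.append(_EncLevel(in_ch, w, rng))
            in_ch = w
        bott = widths[-1] * 2
        self.bconv1, self.bact1 = Conv2d(in_ch, bott, 3, rng), ReLU()
        self.bconv2, self.bact2 = Conv2d(bott, bott, 3, rng), ReLU()
        self.dec: list[_DecLevel] = []
        in_ch = bott
        for w in reversed(widths):
            self.dec.append(_DecLevel(in_ch, w, w, rng))
            in_ch = w
        self.final = Conv2d(in_ch, spec.out_channels, 1, rng)

    # -- graph plumbing -------------------------------------------------
    def _layers(self):
        for lvl in self.enc:
            yield from (lvl.conv1, lvl.conv2)
        yield from (self.bconv1, self.bconv2)
        for lvl in self.dec:
            yield from (lvl.upconv, lvl.conv1, lvl.conv2)
        yield self.final

    def parametrized(self):
        return list(self._layers())

    def num_params(self) -> int:
        return sum(v.size for l in self._layers() for v in l.params.values())

    def get_state(self):
        return [{k: v.copy() for k, v in l.params.items()} for l in self._layers()]

    def set_state(self, state):
        for layer, st in zip(self.parametrized(), state, strict=True):
            for k, v in st.items():
                layer.params[k][...] = v

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        h = np.asarray(x, dtype=np.float32)
        for lvl in self.enc:
            h = lvl.act1.forward(lvl.conv1.forward(h))
            h = lvl.act2.forward(lvl.conv2.forward(h))
            skips.append(h)
            h = lvl.pool.forward(h)
        h = self.bact1.forward(self.bconv1.forward(h))
        h = self.bact2.forward(self.bconv2.forward(h))
        for lvl, skip in zip(self.dec, reversed(skips)):
            h = lvl.up.forward(h)
            h = lvl.upact.forward(lvl.upconv.forward(h))
            h = np.concatenate([skip, h], axis=3)
            h = lvl.act1.forward(lvl.conv1.forward(h))
            h = lvl.act2.forward(lvl.conv2.forward(h))
        return self.final.forward(h)  # logits, (N, H, W, out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.final.backward(dout)
        dskips = []  # gradient into skips, shallowest level first
        for lvl in reversed(self.dec):
            d = lvl.conv2.backward(lvl.act2.backward(d))
            d = lvl.conv1.backward(lvl.act1.backward(d))
            dskips.append(d[..., :lvl.skip_channels])
            d = lvl.up.backward(lvl.upconv.backward(lvl.upact.backward(
                d[..., lvl.skip_channels:])))
        d = self.bconv2.backward(self.bact2.backward(d))
        d = self.bconv1.backward(self.bact1.backward(d))
        for i in reversed(range(len(self.enc))):
            lvl = self.enc[i]
            d = lvl.pool.backward(d) + dskips[i]
            d = lvl.conv2.backward(lvl.act2.backward(d))
            d = lvl.conv1.backward(lvl.act1.backward(d))
        return d

    def predict_proba(self, x: np.ndarray, batch_size: int = 4) -> np.ndarray:
        out = [sigmoid(self.forward(x[i:i + batch_size]))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)


def build_classifier(spec: ClassifierSpec, seed: int = 0) -> Classifier:
    """Instantiate a classifier with seeded He-initialized weights."""
    return Classifier(spec, seed)


def build_segmenter(spec: SegmenterSpec, seed: int = 0) -> Segmenter:
    """Instantiate a segmenter with seeded He-initialized weights."""
    return Segmenter(spec, seed)


def save_weights(model, path: str | os.PathLike, spec_path: str | os.PathLike | None = None
                 ) -> None:
    """Save weights as .npz; optionally serialize the architecture spec as YAML."""
    arrays = {}
    for i, st in enumerate(model.get_state()):
        for k, v in st.items():
            arrays[f"layer{i:03d}.{k}"] = v
    np.savez(path, **arrays)
    if spec_path is not None:
        with open(spec_path, "w") as fh:
            yaml.safe_dump({"kind": type(model).__name__.lower(),
                            "spec": asdict(model.spec)}, fh)


def load_weights(model, path: str | os.PathLike) -> None:
    with np.load(path) as data:
        state = model.get_state()
        for i, st in enumerate(state):
            for k in st:
                st[k] = data[f"layer{i:03d}.{k}"]
        model.set_state(state)
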