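"""Layers with explicit forward/backward passes (NHWC, float32).

Each layer instance caches what its backward pass needs, so an instance
belongs to exactly one site in a network graph.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: parameter-free identity."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for 'same' convolution."""
    out = -(-n // s)  # ceil
    total = max((out - 1) * s + k - n, 0)
    return out, total // 2, total - total // 2


class Conv2d(Layer):
    """2-D convolution with 'same' zero padding, square kernel, He init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        fan_in = kernel_size * kernel_size * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, out_channels))
        self.params = {"w": w.astype(np.float32),
                       "b": np.zeros(out_channels, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def _w4(self) -> np.ndarray:
        # flat (k*k*c, out) weight viewed as one (c, out) block per tap
        return self.params["w"].reshape(self.k, self.k, self.in_channels,
                                        self.out_channels)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, h, w_in, c = x.shape
        assert c == self.in_channels, (c, self.in_channels)
        k, s = self.k, self.stride
        ho, pt, pb = _same_pad(h, k, s)
        wo, pl, pr = _same_pad(w_in, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        # convolution as a sum of k*k shifted (c -> out) matmuls; avoids
        # materializing an im2col buffer and keeps GEMM inputs contiguous
        w4 = self._w4()
        out = np.empty((n * ho * wo, self.out_channels), dtype=np.float32)
        out[:] = self.params["b"]
        for i in range(k):
            for j in range(k):
                sl = np.ascontiguousarray(
                    xp[:, i:i + s * ho:s, j:j + s * wo:s, :]).reshape(-1, c)
                out += sl @ w4[i, j]
        self._cache = (xp, (pt, pl), (n, h, w_in, c), (ho, wo))
        return out.reshape(n, ho, wo, self.out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, (pt, pl), (n, h, w_in, c), (ho, wo) = self._cache
        k, s = self.k, self.stride
        d2 = np.ascontiguousarray(dout, dtype=np.float32).reshape(-1, self.out_channels)
        w4 = self._w4()
        gw4 = self.grads["w"].reshape(k, k, c, self.out_channels)
        self.grads["b"][...] = d2.sum(axis=0)
        dxp = np.zeros(xp.shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                sl = np.ascontiguousarray(
                    xp[:, i:i + s * ho:s, j:j + s * wo:s, :]).reshape(-1, c)
                gw4[i, j] = sl.T @ d2
                dxp[:, i:i + s * ho:s, j:j + s * wo:s, :] += (
                    d2 @ w4[i, j].T).reshape(n, ho, wo, c)
        return dxp[:, pt:pt + h, pl:pl + w_in, :]


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        self.params = {"w": w.astype(np.float32),
                       "b": np.zeros(out_features, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = np.ascontiguousarray(x, dtype=np.float32)
        return self._x @ self.params["w"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.ascontiguousarray(dout, dtype=np.float32)
        self.grads["w"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["w"].T


class Center(Layer):
    """Fixed input centering: subtracts a constant offset (gradient-transparent)."""

    def __init__(self, offset: float = 0.5):
        super().__init__()
        self.offset = np.float32(offset)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x - self.offset

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, np.float32(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.asarray(dout, dtype=np.float32) * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :h2 * 2, :w2 * 2, :]
        win = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, h2, w2, c, 4)
        idx = win.argmax(axis=4)
        self._cache = (x.shape, idx)
        return np.take_along_axis(win, idx[..., None], axis=4)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (n, h, w, c), idx = self._cache
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, h2, w2, c, 4), dtype=np.float32)
        np.put_along_axis(dwin, idx[..., None], dout[..., None].astype(np.float32), axis=4)
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, :h2 * 2, :w2 * 2, :] = dwin.reshape(n, h2, w2, c, 2, 2).transpose(
            0, 1, 4, 2, 5, 3).reshape(n, h2 * 2, w2 * 2, c)
        return dx


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time.

    Draws from its own seeded generator, so a fixed build seed yields a
    reproducible mask sequence.
    """

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential:
    """Plain layer chain with checkpointable parameter state."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parametrized(self) -> list[Layer]:
        return [l for l in self.layers if l.params]

    def num_params(self) -> int:
        return sum(v.size for l in self.parametrized() for v in l.params.values())

    def get_state(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params.items()} for l in self.parametrized()]

    def set_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, st in zip(self.parametrized(), state, strict=True):
            for k, v in st.items():
                layer.params[k][...] = v
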