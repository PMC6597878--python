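"""Numerically stable losses operating on raw logits."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy for integer class labels.

    Returns (loss, dlogits, probabilities); dlogits is the gradient of the
    mean loss with respect to the logits.
    """
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32), probs


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def sigmoid_bce(logits: np.ndarray, targets: np.ndarray
                ) -> tuple[float, np.ndarray, np.ndarray]:
    """Element-mean binary cross-entropy on logits (log-sum-exp form).

    Used for the two-channel per-pixel maps: the loss sums over both mask
    channels and averages over all elements.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    probs = sigmoid(z)
    dlogits = ((probs - y) / z.size).astype(np.float32)
    return float(loss.mean()), dlogits, probs
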