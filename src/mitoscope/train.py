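"""Training and evaluation loops for the two branches.

The classifier follows the reference recipe: stochastic gradient descent,
batch size 128, cross-entropy on the two-way softmax, with a step-decay
learning-rate schedule. The segmenter uses Adam with unitary batch size
and per-pixel binary cross-entropy summed over the two mask channels.

Both loops record per-epoch train loss, validation loss and a validation
metric, and perform checkpoint-restore early stopping: the returned
weights are those of the epoch with minimum validation loss. This
mechanizes the retrospective "use the weights saved at the best epoch"
procedure with a configurable patience. All randomness (shuffling,
dropout, initialization) flows from ``TrainConfig.seed``; runs are
bit-reproducible in single-threaded mode.

Stored patch tensors are on the [0, 255] scale; the trainer divides by 255
exactly once (:func:`prepare_inputs`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mitoscope.errors import DivergenceError, ValidationError
from mitoscope.metrics import (
    ConfusionMatrix,
    MetricsReport,
    classification_metrics,
    confusion_from_predictions,
    dice,
)
from mitoscope.models import (
    Classifier,
    ClassifierSpec,
    Segmenter,
    SegmenterSpec,
    build_classifier,
    build_segmenter,
)
from mitoscope.nn import SGD, Adam, sigmoid_bce, softmax_cross_entropy
from mitoscope.patches import DatasetSplit


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "sgd"  # "sgd" | "adam"
    batch_size: int = 128
    max_epochs: int = 100
    learning_rate: float = 0.01
    lr_decay_epochs: tuple[int, ...] = (33, 66)
    lr_decay_factor: float = 0.1
    momentum: float = 0.9
    early_stop_patience: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")
        if self.optimizer not in ("sgd", "adam"):
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")

    @classmethod
    def classifier_default(cls, seed: int = 0, max_epochs: int = 100) -> "TrainConfig":
        return cls(optimizer="sgd", batch_size=128, max_epochs=max_epochs, seed=seed)

    @classmethod
    def segmenter_default(cls, seed: int = 0, max_epochs: int = 100) -> "TrainConfig":
        return cls(optimizer="adam", batch_size=1, max_epochs=max_epochs,
                   learning_rate=1e-3, seed=seed)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    selected_epoch: int = 0  # 1-based epoch whose weights were restored

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)

    def to_rows(self) -> list[dict]:
        return [{"epoch": i + 1, "train_loss": tl, "val_loss": vl, "val_acc": va}
                for i, (tl, vl, va) in enumerate(
                    zip(self.train_loss, self.val_loss, self.val_acc))]


def prepare_inputs(pixels: np.ndarray) -> np.ndarray:
    """Scale stored [0, 255] channels to [0, 1] float32 (exactly once)."""
    return np.asarray(pixels, dtype=np.float32) / np.float32(255.0)


def _stack_classification(patches, ids):
    x = prepare_inputs(np.stack([patches[i].pixels for i in ids]))
    y = np.asarray([1 if patches[i].label == "mitosis" else 0 for i in ids])
    return x, y


def _stack_segmentation(patches, ids):
    x = prepare_inputs(np.stack([patches[i].pixels for i in ids]))
    y = np.stack([patches[i].mask for i in ids]).astype(np.float32)
    return x, y


def _make_optimizer(model, config: TrainConfig):
    if config.optimizer == "sgd":
        return SGD(model.parametrized(), lr=config.learning_rate,
                   momentum=config.momentum)
    return Adam(model.parametrized(), lr=config.learning_rate)


def _lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    lr = config.learning_rate
    for boundary in config.lr_decay_epochs:
        if epoch >= boundary:
            lr *= config.lr_decay_factor
    return lr


def _train_loop(model, corpus, split: DatasetSplit, config: TrainConfig,
                stacker, loss_fn, val_metric) -> TrainHistory:
    config.validate()
    if len(split.train_ids) == 0:
        raise ValidationError("train split is empty")
    if len(split.val_ids) == 0:
        raise ValidationError("validation split is empty")
    rng = np.random.default_rng(config.seed)
    opt = _make_optimizer(model, config)
    history = TrainHistory()
    best_loss = math.inf
    best_state = None
    best_epoch = 0
    train_ids = np.asarray(split.train_ids)
    x_val, y_val = stacker(corpus, split.val_ids)

    for epoch in range(1, config.max_epochs + 1):
        if config.optimizer == "sgd":
            opt.lr = _lr_at_epoch(config, epoch)
        order = rng.permutation(len(train_ids))
        losses = []
        for start in range(0, len(order), config.batch_size):
            ids = train_ids[order[start:start + config.batch_size]]
            x, y = stacker(corpus, ids)
            logits = model.forward(x, train=True)
            loss, dlogits, _ = loss_fn(logits, y)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_logits = _forward_batched(model, x_val)
        vloss, _, _ = loss_fn(val_logits, y_val)
        if not np.isfinite(vloss):
            raise DivergenceError(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(float(vloss))
        history.val_acc.append(float(val_metric(val_logits, y_val)))
        if vloss < best_loss:
            best_loss = vloss
            best_state = model.get_state()
            best_epoch = epoch
        elif epoch - best_epoch >= config.early_stop_patience:
            break
    model.set_state(best_state)
    history.selected_epoch = best_epoch
    return history


def _forward_batched(model, x, batch_size: int = 8) -> np.ndarray:
    outs = [model.forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


def _cls_val_metric(logits, labels) -> float:
    return float((logits.argmax(axis=1) == labels).mean())


def _seg_val_metric(logits, masks) -> float:
    # pixel accuracy over both binarized channels
    pred = logits > 0  # sigmoid(z) >= 0.5  <=>  z >= 0
    return float((pred == (masks > 0.5)).mean())


def train_classifier(spec: ClassifierSpec, corpus, split: DatasetSplit,
                     config: TrainConfig | None = None
                     ) -> tuple[Classifier, TrainHistory]:
    """Train the patch classifier; returns (model at best epoch, history)."""
    config = config or TrainConfig.classifier_default()
    model = build_classifier(spec, seed=config.seed)
    history = _train_loop(model, corpus, split, config, _stack_classification,
                          softmax_cross_entropy, _cls_val_metric)
    return model, history


def train_segmenter(spec: SegmenterSpec, corpus, split: DatasetSplit,
                    config: TrainConfig | None = None
                    ) -> tuple[Segmenter, TrainHistory]:
    """Train the segmenter; returns (model at best epoch, history)."""
    config = config or TrainConfig.segmenter_default()
    model = build_segmenter(spec, seed=config.seed)
    history = _train_loop(model, corpus, split, config, _stack_segmentation,
                          sigmoid_bce, _seg_val_metric)
    return model, history


def evaluate_classifier(model: Classifier, patches
                        ) -> tuple[ConfusionMatrix, MetricsReport]:
    """Argmax decision per patch; confusion counts with mitosis positive."""
    if len(patches) == 0:
        raise ValidationError("cannot evaluate on an empty patch set")
    x = prepare_inputs(np.stack([p.pixels for p in patches]))
    probs = model.predict_proba(x)
    preds = probs.argmax(axis=1)
    labels = [1 if p.label == "mitosis" else 0 for p in patches]
    cm = confusion_from_predictions(labels, preds.tolist())
    return cm, classification_metrics(cm)


def evaluate_segmenter(model: Segmenter, patches, threshold: float = 0.5
                       ) -> tuple[float, float]:
    """(mean Dice on the thresholded mitosis channel, pixel accuracy).

    Dice is computed per patch then averaged; accuracy is over both
    channels' binarized predictions against the two-layer masks.
    """
    if len(patches) == 0:
        raise ValidationError("cannot evaluate on an empty patch set")
    x = prepare_inputs(np.stack([p.pixels for p in patches]))
    masks = np.stack([p.mask for p in patches]).astype(bool)
    probs = model.predict_proba(x)
    pred = probs >= threshold
    dices = [dice(pred[i, :, :, 0], masks[i, :, :, 0]) for i in range(len(patches))]
    accuracy = float((pred == masks).mean())
    return float(np.mean(dices)), accuracy
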