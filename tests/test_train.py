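"""Trainer loops, checkpoint-restore early stopping, evaluation plumbing."""

import numpy as np
import pytest

from mitoscope.errors import ValidationError
from mitoscope.metrics import dice
from mitoscope.models import ClassifierSpec, SegmenterSpec, build_classifier
from mitoscope.patches import ClassificationPatch, SegmentationPatch, split_dataset
from mitoscope.train import (
    TrainConfig,
    evaluate_classifier,
    evaluate_segmenter,
    prepare_inputs,
    train_classifier,
    train_segmenter,
)

TINY_CLF = ClassifierSpec(width_multiplier=0.05)
TINY_SEG = SegmenterSpec(input_size=32, depth=2, base_width=2)


def toy_classification_corpus(rng, n_per_class=12):
    """Separable toy task: dark patches are mitotic, light ones are not."""
    corpus = []
    for i in range(n_per_class):
        corpus.append(ClassificationPatch(
            pixels=rng.integers(0, 80, (71, 71, 3)).astype(np.uint8),
            label="mitosis", frame_id="f0", centroid=(float(i), 0.0)))
        corpus.append(ClassificationPatch(
            pixels=rng.integers(160, 256, (71, 71, 3)).astype(np.uint8),
            label="not_mitosis", frame_id="f0", centroid=(float(i), 1.0)))
    return corpus


def toy_segmentation_corpus(rng, n=6, size=32):
    corpus = []
    for i in range(n):
        pixels = rng.integers(150, 220, (size, size, 4)).astype(np.float32)
        mask = np.zeros((size, size, 2), dtype=bool)
        if i % 2 == 0:
            pixels[8:20, 8:20, :] = 40.0  # dark blob = mitotic region
            mask[8:20, 8:20, 0] = True
        corpus.append(SegmentationPatch(pixels=pixels, mask=mask,
                                        center_label="mitosis" if i % 2 == 0
                                        else "not_mitosis"))
    return corpus


class TestConfigValidation:
    def test_zero_epochs_rejected(self):
        with pytest.raises(ValidationError):
            TrainConfig(max_epochs=0).validate()

    @pytest.mark.parametrize("bad", [dict(batch_size=0), dict(optimizer="rmsprop"),
                                     dict(learning_rate=0.0)])
    def test_bad_fields_rejected(self, bad):
        import dataclasses

        with pytest.raises(ValidationError):
            dataclasses.replace(TrainConfig(), **bad).validate()

    def test_defaults_follow_recipes(self):
        c = TrainConfig.classifier_default()
        assert (c.optimizer, c.batch_size, c.learning_rate) == ("sgd", 128, 0.01)
        assert c.lr_decay_epochs == (33, 66) and c.lr_decay_factor == 0.1
        s = TrainConfig.segmenter_default()
        assert (s.optimizer, s.batch_size, s.learning_rate) == ("adam", 1, 1e-3)


class TestTrainingLoop:
    def test_single_epoch_history(self, rng):
        corpus = toy_classification_corpus(rng)
        split = split_dataset(corpus, (0.7, 0.3, 0.0), seed=0)
        config = TrainConfig(optimizer="sgd", batch_size=8, max_epochs=1,
                             learning_rate=0.01, seed=0)
        _, history = train_classifier(TINY_CLF, corpus, split, config)
        assert history.epochs_run == 1
        assert history.selected_epoch == 1
        assert len(history.val_loss) == len(history.val_acc) == 1

    def test_determinism(self, rng):
        corpus = toy_classification_corpus(rng)
        split = split_dataset(corpus, (0.7, 0.3, 0.0), seed=0)
        config = TrainConfig(optimizer="sgd", batch_size=8, max_epochs=3, seed=4)
        m1, h1 = train_classifier(TINY_CLF, corpus, split, config)
        m2, h2 = train_classifier(TINY_CLF, corpus, split, config)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        for s1, s2 in zip(m1.get_state(), m2.get_state()):
            for k in s1:
                assert np.array_equal(s1[k], s2[k])

    def test_early_stop_restores_best_epoch(self, rng):
        corpus = toy_classification_corpus(rng)
        split = split_dataset(corpus, (0.7, 0.3, 0.0), seed=0)
        config = TrainConfig(optimizer="sgd", batch_size=8, max_epochs=12,
                             learning_rate=0.05, early_stop_patience=3, seed=1)
        model, history = train_classifier(TINY_CLF, corpus, split, config)
        assert history.selected_epoch == int(np.argmin(history.val_loss)) + 1
        # stop happened no later than patience epochs past the best one
        assert history.epochs_run <= history.selected_epoch + 3
        # restored weights reproduce the selected epoch's validation loss
        from mitoscope.nn import softmax_cross_entropy
        from mitoscope.train import _forward_batched, _stack_classification

        x_val, y_val = _stack_classification(corpus, split.val_ids)
        vloss, _, _ = softmax_cross_entropy(_forward_batched(model, x_val), y_val)
        assert vloss == pytest.approx(history.val_loss[history.selected_epoch - 1],
                                      rel=1e-6)

    def test_empty_split_rejected(self, rng):
        corpus = toy_classification_corpus(rng)
        split = split_dataset(corpus, (1.0, 0.0, 0.0), seed=0)
        with pytest.raises(ValidationError):
            train_classifier(TINY_CLF, corpus, split, TrainConfig(max_epochs=1))

    def test_history_rows(self, rng):
        corpus = toy_classification_corpus(rng)
        split = split_dataset(corpus, (0.7, 0.3, 0.0), seed=0)
        _, history = train_classifier(
            TINY_CLF, corpus, split,
            TrainConfig(batch_size=8, max_epochs=2, seed=0))
        rows = history.to_rows()
        assert [r["epoch"] for r in rows] == [1, 2]
        assert rows[0]["val_loss"] == history.val_loss[0]


def test_segmenter_loss_decreases(rng):
    corpus = toy_segmentation_corpus(rng)
    split = split_dataset(corpus, (0.7, 0.3, 0.0), seed=0)
    config = TrainConfig(optimizer="adam", batch_size=1, max_epochs=8,
                         learning_rate=1e-3, seed=0)
    model, history = train_segmenter(TINY_SEG, corpus, split, config)
    assert min(history.val_loss) < history.val_loss[0]
    assert history.selected_epoch == int(np.argmin(history.val_loss)) + 1


class StubClassifier:
    """predict_proba driven by a fixed decision function on the patch mean."""

    def __init__(self, decide):
        self.decide = decide

    def predict_proba(self, x, batch_size=64):
        out = np.zeros((len(x), 2))
        for i, patch in enumerate(x):
            out[i, 1 if self.decide(patch) else 0] = 1.0
        return out


class TestEvaluateClassifier:
    def make_patches(self, rng):
        return toy_classification_corpus(rng, n_per_class=10)

    def test_perfect_predictor(self, rng):
        patches = self.make_patches(rng)
        model = StubClassifier(lambda p: p.mean() < 0.5)  # dark = mitosis
        cm, report = evaluate_classifier(model, patches)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (10, 0, 0, 10)
        assert report.accuracy == report.f1 == 1.0

    def test_constant_mitosis_predictor(self, rng):
        patches = self.make_patches(rng)
        model = StubClassifier(lambda p: True)
        cm, report = evaluate_classifier(model, patches)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (10, 0, 10, 0)
        assert report.sensitivity == 1.0
        assert report.specificity == 0.0

    def test_bookkeeping_totals(self, rng):
        patches = self.make_patches(rng)
        model = StubClassifier(lambda p: bool(p[0, 0, 0] > 0.3))
        cm, _ = evaluate_classifier(model, patches)
        assert cm.positives == 10 and cm.negatives == 10
        assert cm.total == 20

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_classifier(StubClassifier(lambda p: True), [])


class StubSegmenter:
    def __init__(self, prob_maps):
        self.prob_maps = np.asarray(prob_maps)

    def predict_proba(self, x, batch_size=4):
        return self.prob_maps


class TestEvaluateSegmenter:
    def test_perfect_prediction(self, rng):
        corpus = toy_segmentation_corpus(rng, n=4)
        probs = np.stack([p.mask.astype(float) for p in corpus])
        mean_dice, acc = evaluate_segmenter(StubSegmenter(probs), corpus)
        assert mean_dice == 1.0
        assert acc == 1.0

    def test_empty_prediction_on_empty_truth(self, rng):
        corpus = [p for p in toy_segmentation_corpus(rng) if not p.mask.any()]
        probs = np.zeros((len(corpus), 32, 32, 2))
        mean_dice, acc = evaluate_segmenter(StubSegmenter(probs), corpus)
        assert mean_dice == 1.0  # both-empty convention
        assert acc == 1.0

    def test_mean_is_mean_of_per_patch(self, rng):
        corpus = toy_segmentation_corpus(rng, n=4)
        probs = rng.random((4, 32, 32, 2))
        mean_dice, _ = evaluate_segmenter(StubSegmenter(probs), corpus)
        per_patch = [dice(probs[i, :, :, 0] >= 0.5, corpus[i].mask[:, :, 0])
                     for i in range(4)]
        assert mean_dice == pytest.approx(np.mean(per_patch))


def test_prepare_inputs_scales_once():
    pixels = np.array([[0, 255, 51]], dtype=np.uint8)
    out = prepare_inputs(pixels)
    assert out.dtype == np.float32
    assert np.allclose(out, [[0.0, 1.0, 0.2]])
    # applying to stored patches keeps everything inside [0, 1]
    assert prepare_inputs(np.full((2, 2), 255)).max() == 1.0
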