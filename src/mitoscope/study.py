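"""Desk-scale study conditions: the standard synthetic experiments.

These functions fix the problem sizes used for CPU-scale verification of
the pipeline (frame counts, corpus sizes, epoch budgets) so that the test
suite and the reproduction script exercise identical conditions. Sizes
are chosen so each experiment runs in minutes on one core while leaving
the statistical structure of the task intact: the candidate-detection
experiment covers >= 500 mitotic figures, and both training experiments
use the reduced ("desk") model presets on corpora whose class palettes
are separable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mitoscope.candidates import DetectConfig, blue_ratio, match_candidates, segment_candidates
from mitoscope.models import ClassifierSpec, SegmenterSpec
from mitoscope.patches import balance_classes, holdout_test, split_dataset
from mitoscope.pipeline import build_classification_corpus, build_segmentation_corpus
from mitoscope.stain import compute_target_stats, normalize_frame
from mitoscope.synthetic import SceneConfig, frame_seeds, generate_scene
from mitoscope.train import (
    TrainConfig,
    evaluate_classifier,
    evaluate_segmenter,
    train_classifier,
    train_segmenter,
)

#: scene used for the detection-recall experiment: mitosis-rich frames so
#: 20 frames provide 500 mitotic figures
RECALL_SCENE = SceneConfig(n_mitotic=25, n_nonmitotic=10)

#: scene used for the training experiments (pipeline defaults)
TRAIN_SCENE = SceneConfig()

MATCH_TOLERANCE_PX = 12.0


def _frames(scene: SceneConfig, n_frames: int, seed: int):
    frames, truths = [], []
    for fseed in frame_seeds(seed, n_frames):
        frame, truth = generate_scene(scene, fseed)
        frames.append(frame)
        truths.append(truth)
    return frames, truths


def detection_recall(seed: int, n_frames: int = 20,
                     detect: DetectConfig | None = None) -> dict:
    """Candidate recall of the blue-ratio detector over synthetic mitoses.

    Runs threshold-and-open candidate detection on ``n_frames`` frames of
    the mitosis-rich scene and matches candidates to ground-truth mitotic
    centroids (greedy one-to-one, 12 px tolerance).
    """
    detect = detect or DetectConfig()
    frames, truths = _frames(RECALL_SCENE, n_frames, seed)
    n_matched = n_total = 0
    for frame, truth in zip(frames, truths):
        br = blue_ratio(frame, detect.br_constants)
        cands = segment_candidates(br, detect)
        matched, missed, _ = match_candidates(cands, truth.centroids("mitosis"),
                                              MATCH_TOLERANCE_PX)
        n_matched += matched
        n_total += matched + missed
    return {"recall": n_matched / n_total, "n_mitoses": n_total}


def _normalized_corpus_frames(n_frames: int, seed: int):
    frames, truths = _frames(TRAIN_SCENE, n_frames, seed)
    target = compute_target_stats(frames)
    normed = [normalize_frame(f, target) for f in frames]
    fids = [f"frame_{i:03d}" for i in range(n_frames)]
    return normed, truths, fids


def classifier_experiment(seed: int, n_frames: int = 4, max_epochs: int = 20) -> dict:
    """Train the desk-preset classifier on the separable synthetic corpus.

    Returns the validation accuracy of the restored (best-epoch) model plus
    corpus and history bookkeeping.
    """
    normed, truths, fids = _normalized_corpus_frames(n_frames, seed)
    detect = DetectConfig()
    patches, split = build_classification_corpus(
        normed, truths, fids, detect, MATCH_TOLERANCE_PX,
        angles=(0, 45, 90, 180), fractions=(0.7, 0.2, 0.1), seed=seed)
    config = TrainConfig.classifier_default(seed=seed, max_epochs=max_epochs)
    model, history = train_classifier(ClassifierSpec.desk(), patches, split, config)
    val_patches = [patches[i] for i in split.val_ids]
    _, report = evaluate_classifier(model, val_patches)
    return {"val_accuracy": report.accuracy, "n_patches": len(patches),
            "n_val": len(val_patches), "epochs_run": history.epochs_run,
            "selected_epoch": history.selected_epoch, "history": history,
            "model": model}


def segmenter_experiment(seed: int, n_frames: int = 4, max_per_class: int = 16,
                         max_epochs: int = 30) -> dict:
    """Train the desk-preset segmenter and report validation Dice.

    Dice is per-patch on the thresholded (0.5) mitosis channel, averaged
    over the validation patches.
    """
    normed, truths, fids = _normalized_corpus_frames(n_frames, seed)
    corpus = build_segmentation_corpus(normed, truths, fids, DetectConfig(),
                                       max_per_class=max_per_class, seed=seed)
    split = split_dataset(corpus, (0.9, 0.1, 0.0), seed)
    config = TrainConfig.segmenter_default(seed=seed, max_epochs=max_epochs)
    model, history = train_segmenter(SegmenterSpec.desk(), corpus, split, config)
    val_patches = [corpus[i] for i in split.val_ids]
    mean_dice, pixel_acc = evaluate_segmenter(model, val_patches)
    return {"mean_dice": mean_dice, "pixel_accuracy": pixel_acc,
            "n_patches": len(corpus), "n_val": len(val_patches),
            "epochs_run": history.epochs_run,
            "selected_epoch": history.selected_epoch, "history": history,
            "model": model}


@dataclass(frozen=True)
class _Record:
    label: str


def balanced_corpus_size(n_mitotic: int, n_nonmitotic: int,
                         test_mitotic: int, test_nonmitotic: int,
                         seed: int = 0) -> dict:
    """Run the hold-out-then-balance procedure on a corpus of given counts.

    Builds a labeled corpus of the given sizes, holds out the per-class
    test counts, balances the remainder by majority down-sampling, and
    returns the resulting pool sizes.
    """
    corpus = ([_Record("mitosis")] * n_mitotic
              + [_Record("not_mitosis")] * n_nonmitotic)
    test, remaining = holdout_test(
        corpus, {"mitosis": test_mitotic, "not_mitosis": test_nonmitotic}, seed)
    balanced = balance_classes(remaining, seed)
    return {"n_test": len(test), "n_remaining": len(remaining),
            "n_balanced": len(balanced),
            "n_balanced_mitotic": sum(p.label == "mitosis" for p in balanced),
            "n_balanced_nonmitotic": sum(p.label == "not_mitosis" for p in balanced)}
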