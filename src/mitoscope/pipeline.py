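"""End-to-end pipeline: synth -> normalize -> detect -> patchify -> train -> evaluate.

Every stage is a thin call into the library modules; the pipeline only
wires them together, writes intermediate artifacts, and records a
manifest with versions, seeds, and per-stage summaries. The manifest
contains no timestamps, so deterministic runs produce bit-identical
manifests.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import mitoscope
from mitoscope import io as mio
from mitoscope.candidates import DetectConfig, blue_ratio, extract_patch, match_candidates, \
    segment_candidates
from mitoscope.errors import MitoscopeError, ValidationError
from mitoscope.metrics import dice  # noqa: F401  (re-exported for run reports)
from mitoscope.models import ClassifierSpec, SegmenterSpec, save_weights
from mitoscope.patches import (
    ClassificationPatch,
    DatasetSplit,
    balance_classes,
    build_segmentation_patch,
    holdout_test,
    rotate_pixels,
    save_manifest,
    split_dataset,
)
from mitoscope.stain import compute_target_stats, normalize_frame
from mitoscope.synthetic import SceneConfig, frame_seeds, generate_scene
from mitoscope.train import (
    TrainConfig,
    evaluate_classifier,
    evaluate_segmenter,
    train_classifier,
    train_segmenter,
)

STAGES = ("synth", "normalize", "detect", "patchify", "train", "evaluate")


def _dataclass_from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValidationError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Schema-validated configuration of one full pipeline run."""

    seed: int = 0
    n_frames: int = 6
    scene: SceneConfig = field(default_factory=SceneConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    classifier_spec: ClassifierSpec = field(default_factory=ClassifierSpec.desk)
    segmenter_spec: SegmenterSpec = field(default_factory=SegmenterSpec.desk)
    classifier_train: TrainConfig = field(
        default_factory=lambda: TrainConfig.classifier_default(max_epochs=5))
    segmenter_train: TrainConfig = field(
        default_factory=lambda: TrainConfig.segmenter_default(max_epochs=5))
    match_tolerance: float = 12.0
    angles: tuple[int, ...] = (0, 45, 90, 180)
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.match_tolerance <= 0:
            raise ValidationError("match_tolerance must be positive")
        self.scene.validate()
        self.detect.validate()
        self.classifier_spec.validate()
        self.segmenter_spec.validate()
        self.classifier_train.validate()
        self.segmenter_train.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {"scene": SceneConfig, "detect": DetectConfig,
               "classifier_spec": ClassifierSpec, "segmenter_spec": SegmenterSpec,
               "classifier_train": TrainConfig, "segmenter_train": TrainConfig}
        kwargs = {}
        for key, value in d.items():
            if key in sub:
                kwargs[key] = _dataclass_from_dict(sub[key], value)
            elif key in ("angles", "fractions"):
                kwargs[key] = tuple(value)
            elif key in ("seed", "n_frames", "match_tolerance"):
                kwargs[key] = value
            else:
                raise ValidationError(f"unknown RunConfig key {key!r}")
        config = cls(**kwargs)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def label_candidates(candidate_set, truth, tolerance: float) -> list[str]:
    """Label each candidate by proximity to a mitotic ground-truth centroid."""
    mito = truth.centroids("mitosis")
    labels = []
    for cand in candidate_set.candidates:
        pos = np.array([cand.centroid_row, cand.centroid_col])
        if len(mito) and np.linalg.norm(mito - pos, axis=1).min() <= tolerance:
            labels.append("mitosis")
        else:
            labels.append("not_mitosis")
    return labels


def build_classification_corpus(frames, truths, frame_ids, detect_cfg: DetectConfig,
                                tolerance: float, angles, fractions, seed: int
                                ) -> tuple[list[ClassificationPatch], DatasetSplit]:
    """Detect candidates, label them against truth, split, then augment.

    The split is computed on the un-augmented source patches and rotations
    inherit their source's part, so augmented copies of one patch never
    straddle a train/test boundary.
    """
    sources: list[ClassificationPatch] = []
    for frame, truth, fid in zip(frames, truths, frame_ids):
        br = blue_ratio(frame, detect_cfg.br_constants)
        cands = segment_candidates(br, detect_cfg, frame_id=fid)
        labels = label_candidates(cands, truth, tolerance)
        for cand, label in zip(cands.candidates, labels):
            pixels = extract_patch(frame, (cand.centroid_row, cand.centroid_col),
                                   detect_cfg.patch_size)
            sources.append(ClassificationPatch(
                pixels=pixels, label=label, frame_id=fid,
                centroid=(cand.centroid_row, cand.centroid_col)))
    if not sources:
        raise ValidationError("no candidate patches were produced")
    src_split = split_dataset(sources, fractions, seed)
    patches: list[ClassificationPatch] = []
    parts: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for part, ids in (("train", src_split.train_ids), ("val", src_split.val_ids),
                      ("test", src_split.test_ids)):
        for i in ids:
            for angle in angles:
                parts[part].append(len(patches))
                patches.append(dataclasses.replace(
                    sources[i], pixels=rotate_pixels(sources[i].pixels, angle),
                    rotation_deg=int(angle)))
    split = DatasetSplit(tuple(parts["train"]), tuple(parts["val"]),
                         tuple(parts["test"]), seed)
    return patches, split


def build_segmentation_corpus(frames, truths, frame_ids, detect_cfg: DetectConfig,
                              max_per_class: int | None = None, seed: int = 0):
    """Four-channel patches with two-layer masks, centered on truth centroids."""
    patches = []
    for frame, truth, fid in zip(frames, truths, frame_ids):
        br = blue_ratio(frame, detect_cfg.br_constants)
        for nucleus in truth.nuclei:
            patches.append(build_segmentation_patch(
                frame, br, truth.mitosis_mask, truth.nonmitosis_mask,
                (nucleus.centroid_row, nucleus.centroid_col), nucleus.label,
                frame_id=fid))
    if max_per_class is not None:
        rng = np.random.default_rng(seed)
        kept = []
        for cls in ("mitosis", "not_mitosis"):
            idx = [i for i, p in enumerate(patches) if p.label == cls]
            take = min(max_per_class, len(idx))
            kept += [idx[k] for k in rng.choice(len(idx), size=take, replace=False)]
        patches = [patches[i] for i in sorted(kept)]
    return patches


def run_pipeline(config: RunConfig, out_dir: str | os.PathLike) -> Path:
    """Execute all six stages, writing artifacts and a manifest to ``out_dir``."""
    config.validate()  # schema errors surface before any computation
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, dict] = {}
    stage = "synth"
    try:
        frames, truths, frame_ids = [], [], []
        (out / "frames").mkdir(exist_ok=True)
        for i, fseed in enumerate(frame_seeds(config.seed, config.n_frames)):
            fid = f"frame_{i:03d}"
            frame, truth = generate_scene(config.scene, fseed)
            mio.write_frame(out / "frames" / f"{fid}.png", frame)
            frames.append(frame)
            truths.append(truth)
            frame_ids.append(fid)
        summary[stage] = {"n_frames": config.n_frames,
                          "n_nuclei": sum(len(t.nuclei) for t in truths)}

        stage = "normalize"
        target = compute_target_stats(frames)
        target.save(out / "target_stats.yaml")
        normed = [normalize_frame(f, target) for f in frames]
        (out / "normalized").mkdir(exist_ok=True)
        for fid, frame in zip(frame_ids, normed):
            mio.write_frame(out / "normalized" / f"{fid}.png", frame)
        summary[stage] = {"target_mean": [round(m, 4) for m in target.mean],
                          "target_std": [round(s, 4) for s in target.std]}

        stage = "detect"
        n_matched = n_missed = n_spurious = 0
        rows = []
        for frame, truth, fid in zip(normed, truths, frame_ids):
            br = blue_ratio(frame, config.detect.br_constants)
            cands = segment_candidates(br, config.detect, frame_id=fid)
            m, mi, sp = match_candidates(cands, truth.centroids("mitosis"),
                                         config.match_tolerance)
            n_matched, n_missed, n_spurious = (n_matched + m, n_missed + mi,
                                               n_spurious + sp)
            for cand, label in zip(cands.candidates,
                                   label_candidates(cands, truth, config.match_tolerance)):
                rows.append({"frame_id": fid, "centroid_row": cand.centroid_row,
                             "centroid_col": cand.centroid_col, "label": label,
                             "area_px": cand.area_px})
        pd.DataFrame(rows).to_csv(out / "candidates.csv", index=False)
        recall = n_matched / max(n_matched + n_missed, 1)
        summary[stage] = {"n_candidates": len(rows), "mitosis_recall": round(recall, 4),
                          "n_missed": n_missed, "n_spurious": n_spurious}

        stage = "patchify"
        cls_patches, cls_split = build_classification_corpus(
            normed, truths, frame_ids, config.detect, config.match_tolerance,
            config.angles, config.fractions, config.seed)
        save_manifest(cls_patches, cls_split, out / "classification_manifest.csv")
        seg_patches = build_segmentation_corpus(normed, truths, frame_ids, config.detect)
        n_test = {"mitosis": max(1, len([p for p in seg_patches if p.label == "mitosis"]) // 10),
                  "not_mitosis": max(1, len([p for p in seg_patches
                                             if p.label == "not_mitosis"]) // 10)}
        seg_test, seg_rest = holdout_test(seg_patches, n_test, config.seed)
        seg_balanced = balance_classes(seg_rest, config.seed)
        seg_split = split_dataset(seg_balanced, (0.9, 0.1, 0.0), config.seed)
        # the residual "test" slot of the 90/10 split stays empty; the held-out
        # set built above is the segmentation test set
        summary[stage] = {"n_classification_patches": len(cls_patches),
                          "n_segmentation_patches": len(seg_patches),
                          "n_segmentation_balanced": len(seg_balanced),
                          "n_segmentation_test": len(seg_test)}

        stage = "train"
        cls_model, cls_hist = train_classifier(
            config.classifier_spec, cls_patches, cls_split, config.classifier_train)
        seg_model, seg_hist = train_segmenter(
            config.segmenter_spec, seg_balanced, seg_split, config.segmenter_train)
        for name, hist in (("classifier", cls_hist), ("segmenter", seg_hist)):
            pd.DataFrame(hist.to_rows()).to_csv(out / f"{name}_history.csv", index=False)
        save_weights(cls_model, out / "classifier_weights.npz",
                     out / "classifier_spec.yaml")
        save_weights(seg_model, out / "segmenter_weights.npz",
                     out / "segmenter_spec.yaml")
        summary[stage] = {
            "classifier": {"epochs_run": cls_hist.epochs_run,
                           "selected_epoch": cls_hist.selected_epoch,
                           "best_val_acc": round(max(cls_hist.val_acc), 4)},
            "segmenter": {"epochs_run": seg_hist.epochs_run,
                          "selected_epoch": seg_hist.selected_epoch}}

        stage = "evaluate"
        test_patches = [cls_patches[i] for i in cls_split.test_ids]
        cm, report = evaluate_classifier(cls_model, test_patches)
        mean_dice, pix_acc = evaluate_segmenter(seg_model, seg_test)
        evaluation = {
            "classifier": {"confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp,
                                         "tn": cm.tn},
                           "metrics_percent": report.percent()},
            "segmenter": {"mean_dice": round(mean_dice, 4),
                          "pixel_accuracy_percent": round(100 * pix_acc, 2)}}
        with open(out / "evaluation.json", "w") as fh:
            json.dump(evaluation, fh, indent=2)
        summary[stage] = evaluation
    except Exception as exc:
        raise MitoscopeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {"version": mitoscope.__version__, "seed": config.seed,
                "stages": list(STAGES), "summary": summary}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
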