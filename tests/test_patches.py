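"""Patch corpus mechanics: augmentation, balancing, splitting, leakage."""

import numpy as np
import pytest

from mitoscope.candidates import blue_ratio
from mitoscope.errors import ValidationError
from mitoscope.patches import (
    ClassificationPatch,
    DatasetSplit,
    augment_rotations,
    balance_classes,
    build_segmentation_patch,
    holdout_test,
    load_split,
    rotate_pixels,
    save_split,
    split_dataset,
)


def make_patch(value, label="mitosis", frame_id="f0", centroid=(100.0, 100.0)):
    pixels = np.full((71, 71, 3), value, dtype=np.uint8)
    return ClassificationPatch(pixels=pixels, label=label, frame_id=frame_id,
                               centroid=centroid)


def random_patch(rng, **kw):
    kw.setdefault("label", "mitosis")
    kw.setdefault("frame_id", "f0")
    kw.setdefault("centroid", (float(rng.integers(0, 500)), float(rng.integers(0, 500))))
    return ClassificationPatch(pixels=rng.integers(0, 256, (71, 71, 3), dtype=np.uint8),
                               **kw)


class TestAugmentation:
    def test_count_multiplies(self, rng):
        patches = [random_patch(rng) for _ in range(3)]
        out = augment_rotations(patches)
        assert len(out) == 12
        assert sorted({p.rotation_deg for p in out}) == [0, 45, 90, 180]

    def test_zero_rotation_identity(self, rng):
        p = random_patch(rng)
        assert np.array_equal(rotate_pixels(p.pixels, 0), p.pixels)

    def test_two_quarter_turns_equal_half_turn(self, rng):
        pix = rng.integers(0, 256, (71, 71, 3), dtype=np.uint8)
        assert np.array_equal(rotate_pixels(rotate_pixels(pix, 90), 90),
                              rotate_pixels(pix, 180))

    def test_45_preserves_shape_dtype_and_center(self, rng):
        pix = rng.integers(0, 256, (71, 71, 3), dtype=np.uint8)
        out = rotate_pixels(pix, 45)
        assert out.shape == pix.shape and out.dtype == pix.dtype
        assert not np.array_equal(out, pix)

    def test_bad_angle_rejected(self, rng):
        with pytest.raises(ValidationError):
            rotate_pixels(random_patch(rng).pixels, 30)
        with pytest.raises(ValidationError):
            augment_rotations([random_patch(rng)], angles=(0, 30))

    def test_augmented_share_source_id(self, rng):
        out = augment_rotations([random_patch(rng)])
        assert len({p.source_id for p in out}) == 1


class TestSegmentationPatch:
    def test_channels_and_mask_alignment(self, small_scene):
        frame, truth = small_scene
        br = blue_ratio(frame)
        nucleus = truth.nuclei[0]
        centroid = (nucleus.centroid_row, nucleus.centroid_col)
        patch = build_segmentation_patch(frame, br, truth.mitosis_mask,
                                         truth.nonmitosis_mask, centroid,
                                         nucleus.label, frame_id="f0")
        assert patch.pixels.shape == (128, 128, 4)
        assert patch.mask.shape == (128, 128, 2)
        assert patch.pixels.dtype == np.float32 and patch.mask.dtype == bool
        # BR channel agrees with recomputing BR on the RGB channels (interior)
        rgb = np.clip(np.rint(patch.pixels[..., :3]), 0, 255).astype(np.uint8)
        recomputed = blue_ratio(rgb).values
        assert np.allclose(patch.pixels[..., 3], recomputed, atol=1e-3)
        # center pixel carries the centroid's own mask value
        r, c = int(np.rint(centroid[0])), int(np.rint(centroid[1]))
        layer = 0 if nucleus.label == "mitosis" else 1
        assert patch.mask[64, 64, layer] == (truth.mitosis_mask if layer == 0
                                             else truth.nonmitosis_mask)[r, c]
        assert patch.mask[64, 64, layer]

    def test_absent_class_layer_empty(self):
        frame = np.full((256, 256, 3), 200, dtype=np.uint8)
        br = blue_ratio(frame)
        empty = np.zeros((256, 256), dtype=bool)
        blob = empty.copy()
        blob[120:136, 120:136] = True
        patch = build_segmentation_patch(frame, br, blob, empty, (128, 128), "mitosis")
        assert patch.mask[..., 0].any()
        assert not patch.mask[..., 1].any()


class TestBalancing:
    def test_reference_arithmetic(self):
        """1273 mitotic / 3585 non-mitotic, hold out 197 / 701, balance -> 2152."""
        patches = ([make_patch(i % 200, "mitosis") for i in range(327 + 946)]
                   + [make_patch(i % 200, "not_mitosis") for i in range(3585)])
        test, remaining = holdout_test(
            patches, {"mitosis": 197, "not_mitosis": 701}, seed=0)
        assert len(test) == 197 + 701
        labels = [p.label for p in remaining]
        assert labels.count("mitosis") == 1076
        assert labels.count("not_mitosis") == 2884
        balanced = balance_classes(remaining, seed=0)
        assert len(balanced) == 2152
        blabels = [p.label for p in balanced]
        assert blabels.count("mitosis") == blabels.count("not_mitosis") == 1076

    def test_small_hand_case(self):
        patches = ([make_patch(i, "mitosis") for i in range(10)]
                   + [make_patch(i, "not_mitosis") for i in range(25)])
        test, remaining = holdout_test(patches, {"mitosis": 2, "not_mitosis": 5}, seed=1)
        balanced = balance_classes(remaining, seed=1)
        assert len(balanced) == 16
        labels = [p.label for p in balanced]
        assert labels.count("mitosis") == labels.count("not_mitosis") == 8

    def test_balanced_input_is_noop(self):
        patches = ([make_patch(i, "mitosis") for i in range(6)]
                   + [make_patch(i, "not_mitosis") for i in range(6)])
        assert balance_classes(patches, seed=3) == patches

    def test_minority_fully_preserved(self):
        minority = [make_patch(i, "mitosis") for i in range(4)]
        patches = minority + [make_patch(i, "not_mitosis") for i in range(20)]
        balanced = balance_classes(patches, seed=9)
        kept_minority = [p for p in balanced if p.label == "mitosis"]
        assert kept_minority == minority

    def test_deterministic_in_seed(self):
        patches = ([make_patch(i, "mitosis") for i in range(5)]
                   + [make_patch(i, "not_mitosis") for i in range(40)])
        b1 = balance_classes(patches, seed=7)
        b2 = balance_classes(patches, seed=7)
        assert b1 == b2

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            balance_classes([make_patch(0, "mitosis")] * 4, seed=0)

    def test_holdout_too_many_rejected(self):
        patches = [make_patch(i, "mitosis") for i in range(3)]
        with pytest.raises(ValidationError):
            holdout_test(patches, {"mitosis": 4}, seed=0)


class TestSplitting:
    def test_sizes_70_20_10(self):
        labels = ["mitosis"] * 50 + ["not_mitosis"] * 50
        split = split_dataset(labels, (0.7, 0.2, 0.1), seed=2)
        assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) \
            == (70, 20, 10)

    def test_partition_and_determinism(self):
        labels = ["mitosis"] * 33 + ["not_mitosis"] * 44
        s1 = split_dataset(labels, (0.7, 0.2, 0.1), seed=5)
        s2 = split_dataset(labels, (0.7, 0.2, 0.1), seed=5)
        assert s1 == s2
        all_ids = set(s1.train_ids) | set(s1.val_ids) | set(s1.test_ids)
        assert all_ids == set(range(77))

    def test_stratification(self):
        labels = ["mitosis"] * 40 + ["not_mitosis"] * 60
        split = split_dataset(labels, (0.8, 0.1, 0.1), seed=0)
        for ids, frac in ((split.train_ids, 0.8), (split.val_ids, 0.1),
                          (split.test_ids, 0.1)):
            n_mito = sum(1 for i in ids if labels[i] == "mitosis")
            assert abs(n_mito - 40 * frac) <= 1

    @pytest.mark.parametrize("fractions", [(0.5, 0.5, 0.5), (-0.1, 0.9, 0.2),
                                           (0.7, 0.2,)])
    def test_bad_fractions_rejected(self, fractions):
        with pytest.raises(ValidationError):
            split_dataset(["mitosis"] * 4 + ["not_mitosis"] * 4, fractions, seed=0)

    def test_overlapping_split_rejected(self):
        with pytest.raises(ValidationError):
            DatasetSplit(train_ids=(0, 1), val_ids=(1,), test_ids=(2,), seed=0)

    def test_split_serialization_roundtrip(self, tmp_path):
        split = split_dataset(["mitosis"] * 8 + ["not_mitosis"] * 8,
                              (0.5, 0.25, 0.25), seed=4)
        save_split(split, tmp_path / "split.json")
        assert load_split(tmp_path / "split.json") == split


def test_no_leakage_between_split_parts(rng):
    """Rotated copies of a source patch must stay on one side of any split."""
    sources = [random_patch(rng, frame_id=f"f{i % 3}",
                            centroid=(float(10 * i), float(5 * i)),
                            label="mitosis" if i % 2 else "not_mitosis")
               for i in range(12)]
    # split on sources, then augment each part independently (the pipeline's order)
    split = split_dataset(sources, (0.5, 0.25, 0.25), seed=1)
    parts = [augment_rotations([sources[i] for i in ids])
             for ids in (split.train_ids, split.val_ids, split.test_ids)]
    id_sets = [{p.source_id for p in part} for part in parts]
    assert not (id_sets[0] & id_sets[1])
    assert not (id_sets[0] & id_sets[2])
    assert not (id_sets[1] & id_sets[2])


def test_patch_png_roundtrip(tmp_path, rng):
    import imageio.v3 as iio

    from mitoscope.patches import save_patch_images

    patches = [random_patch(rng) for _ in range(2)]
    out = save_patch_images(patches, tmp_path)
    back = iio.imread(out / "patch_00000_rgb.png")
    assert np.array_equal(back, patches[0].pixels)
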