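"""Tile classifier, class matrix, majority filter, metrics."""

import numpy as np
import pytest

from hetier import (
    ClassifierConfig,
    ClassMatrix,
    TileClassifier,
    classify_slide,
    evaluate_classifier,
    majority_filter,
    matrix_to_mask,
    train_classifier,
)
from hetier.segmentation import CLASS_ORDER, EXCLUDED
from hetier.tiling import Tile, TileDataset

PINK = (230, 150, 200)
PURPLE = (120, 60, 160)
BROWN = (170, 110, 80)


def solid_dataset(split, n_per_class=8, noise=5, seed=0):
    rng = np.random.default_rng(seed)
    tiles = []
    for cls, rgb in zip(CLASS_ORDER, (PURPLE, PINK, BROWN)):
        for i in range(n_per_class):
            px = np.clip(
                np.full((48, 48, 3), rgb, float) + rng.normal(0, noise, (48, 48, 3)),
                0,
                255,
            ).astype(np.uint8)
            tiles.append(
                Tile(
                    origin=(0, 0),
                    side_px=48,
                    pixels=px,
                    class_label=cls,
                    patient_id=f"{split}-{i}",
                )
            )
    return TileDataset(split=split, tiles=tiles)


@pytest.fixture(scope="module")
def solid_classifier():
    clf, _ = train_classifier(solid_dataset("train", seed=1), solid_dataset("validation", seed=2))
    return clf


class TestClassifierConfig:
    def test_defaults_echo_tuned_configuration(self):
        cfg = ClassifierConfig()
        assert cfg.trainable_end_layers == 12
        assert cfg.dense_units == 1024
        assert cfg.dropout_rate == 0.2
        assert cfg.optimizer == {"name": "adam", "learning_rate": 1e-7, "decay": 0.0}
        assert cfg.batch_size == 32
        assert cfg.input_side == 48

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            ClassifierConfig(backbone="alexnet")


class TestTileClassifier:
    def test_probabilities_sum_to_one(self, solid_classifier):
        X, _ = solid_dataset("test", seed=3).as_arrays()
        proba = solid_classifier.predict_proba(X)
        assert proba.shape == (len(X), 3)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_unfitted_prediction_rejected(self):
        with pytest.raises(RuntimeError):
            TileClassifier().predict(np.zeros((1, 48, 48, 3), np.uint8))

    def test_missing_class_rejected(self):
        ds = solid_dataset("train")
        ds.tiles = [t for t in ds.tiles if t.class_label != "others"]
        with pytest.raises(ValueError, match="others"):
            train_classifier(ds, solid_dataset("validation"))

    def test_deep_backbone_unavailable_suggests_baseline(self):
        cfg = ClassifierConfig(backbone="vgg19_transfer")
        with pytest.raises(RuntimeError, match="color_baseline"):
            train_classifier(solid_dataset("train"), solid_dataset("validation"), cfg)


class TestClassifySlide:
    def test_grid_arithmetic(self, solid_classifier):
        image = np.full((480, 480, 3), PINK, np.uint8)
        m = classify_slide(image, solid_classifier)
        assert m.labels.shape == (10, 10)

    @pytest.mark.parametrize("shape", [(97, 200), (300, 151), (48, 48), (530, 49)])
    def test_grid_matches_closed_form(self, solid_classifier, shape):
        image = np.full((*shape, 3), PINK, np.uint8)
        m = classify_slide(image, solid_classifier)
        assert m.labels.shape == (
            (shape[0] - 48) // 48 + 1,
            (shape[1] - 48) // 48 + 1,
        )

    def test_all_white_slide_fully_excluded(self, solid_classifier):
        image = np.full((240, 240, 3), 255, np.uint8)
        m = classify_slide(image, solid_classifier)
        assert np.all(m.labels == EXCLUDED)

    def test_solid_stroma_slide_labeled_stroma(self, solid_classifier):
        rng = np.random.default_rng(0)
        image = np.clip(
            np.full((240, 240, 3), PINK, float) + rng.normal(0, 5, (240, 240, 3)), 0, 255
        ).astype(np.uint8)
        m = classify_slide(image, solid_classifier)
        stroma_code = CLASS_ORDER.index("stroma")
        labels = m.labels[m.labels != EXCLUDED]
        assert (labels == stroma_code).mean() >= 0.95

    def test_too_small_image_rejected(self, solid_classifier):
        with pytest.raises(ValueError):
            classify_slide(np.zeros((30, 30, 3), np.uint8), solid_classifier)


def matrix_from(labels, side=48):
    labels = np.asarray(labels)
    h, w = labels.shape
    return ClassMatrix(
        labels=labels,
        tile_side_px=side,
        stride_px=side,
        slide_shape=(h * side, w * side),
    )


class TestMajorityFilter:
    def test_constant_matrix_unchanged(self):
        m = matrix_from(np.ones((5, 5), int))
        assert np.array_equal(majority_filter(m).labels, m.labels)

    def test_isolated_cell_absorbed(self):
        lab = np.ones((3, 3), int)
        lab[1, 1] = 0  # lone epithelium cell inside stroma
        out = majority_filter(matrix_from(lab))
        assert out.labels[1, 1] == 1

    def test_tie_keeps_original_label(self):
        # centre stroma cell whose eight neighbours split 4-4 between
        # stroma and epithelium: the tie keeps the original label
        lab = np.array([[1, 0, 1], [0, 1, 0], [1, 0, 1]])
        out = majority_filter(matrix_from(lab))
        assert out.labels[1, 1] == 1

    def test_tied_island_between_other_labels_is_removed(self):
        # centre cell with a 4-vs-4 epithelium/others neighbourhood: the
        # original is not among the tied winners, so the cell flips
        lab = np.array([[0, 0, 2], [2, 1, 0], [0, 2, 2]])
        out = majority_filter(matrix_from(lab))
        assert out.labels[1, 1] == 0

    def test_excluded_cells_frozen_and_silent(self):
        lab = np.full((3, 3), EXCLUDED, int)
        lab[1, 1] = 0
        out = majority_filter(matrix_from(lab))
        # excluded neighbours cast no votes, so the lone real cell survives
        assert out.labels[1, 1] == 0
        assert np.all(out.labels[0] == EXCLUDED)

    def test_never_introduces_new_labels(self, rng):
        for _ in range(20):
            lab = rng.integers(0, 2, size=(7, 7))  # only labels {0, 1}
            out = majority_filter(matrix_from(lab))
            assert set(np.unique(out.labels)) <= set(np.unique(lab))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            majority_filter(matrix_from(np.zeros((3, 3), int)), window=4)


class TestMatrixToMask:
    def test_block_expansion(self):
        lab = np.arange(4).reshape(2, 2) % 3
        mask = matrix_to_mask(matrix_from(lab))
        assert mask.shape == (96, 96)
        assert np.all(mask[:48, :48] == lab[0, 0])
        assert np.all(mask[48:, 48:] == lab[1, 1])

    def test_label_counts_scale_by_block_area(self):
        lab = np.array([[0, 1], [1, 2]])
        mask = matrix_to_mask(matrix_from(lab))
        for code in (0, 1, 2):
            assert (mask == code).sum() == (lab == code).sum() * 48 * 48

    def test_block_mode_recovers_matrix(self, rng):
        lab = rng.integers(0, 3, size=(4, 5))
        mask = matrix_to_mask(matrix_from(lab))
        rec = np.empty_like(lab)
        for i in range(4):
            for j in range(5):
                block = mask[i * 48 : (i + 1) * 48, j * 48 : (j + 1) * 48]
                rec[i, j] = np.bincount(block.ravel()).argmax()
        assert np.array_equal(rec, lab)

    def test_overlapping_stride_rejected(self):
        m = ClassMatrix(
            labels=np.zeros((2, 2), int), tile_side_px=48, stride_px=24, slide_shape=(72, 72)
        )
        with pytest.raises(NotImplementedError):
            matrix_to_mask(m)


class TestEvaluateClassifier:
    def test_perfect_predictions(self, solid_classifier):
        # solid-color tiles are trivially separable for the baseline
        metrics = evaluate_classifier(solid_classifier, solid_dataset("test", seed=9))
        assert metrics["accuracy"] == 1.0
        assert metrics["macro_f1"] == 1.0

    def test_metrics_match_hand_counted_confusion(self, solid_classifier):
        ds = solid_dataset("test", seed=4, n_per_class=10)
        metrics = evaluate_classifier(solid_classifier, ds)
        X, y = ds.as_arrays()
        pred = solid_classifier.predict(X)
        # independent brute-force confusion count
        conf = np.zeros((3, 3), int)
        for yt, yp in zip(y, pred):
            conf[CLASS_ORDER.index(yt), CLASS_ORDER.index(yp)] += 1
        assert conf.tolist() == metrics["confusion"]
        acc = np.trace(conf) / conf.sum()
        assert metrics["accuracy"] == pytest.approx(acc)
        f1s = []
        for i in range(3):
            tp = conf[i, i]
            prec = tp / conf[:, i].sum() if conf[:, i].sum() else 0.0
            rec = tp / conf[i].sum() if conf[i].sum() else 0.0
            f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
        assert metrics["macro_f1"] == pytest.approx(np.mean(f1s))
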