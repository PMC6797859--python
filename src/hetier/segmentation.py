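"""Three-class tile classifier and slide-level class-matrix construction.

A classifier labels 48 x 48 tiles as epithelium, stroma or others.  Swept
over a slide on a tile grid it yields a class matrix (one cell per tile
position); background-heavy tiles are marked ``excluded`` rather than
classified, mirroring the training-side background filter.  A majority
filter then removes isolated misclassified cells: in real tissue epithelium
sits in ducts and lobules, so a lone epithelial tile surrounded by stroma
is almost certainly noise.

Two backbones honour the same contract:

* ``vgg19_transfer`` — the transfer-learning configuration (pretrained
  convolutional base with only the last 12 layers trainable, flatten →
  dense(1024, ReLU) → dropout(0.2) → softmax(3); Adam, lr 1e-7, no decay,
  batch 32).  Requires a Keras backend at run time.
* ``color_baseline`` — per-tile color/texture summary features plus a
  multinomial logistic regression.  Deterministic and fits in seconds on a
  CPU, which is what the test suite exercises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .tiling import (
    BACKGROUND_MAX_FRACTION,
    TILE_MIN_SIDE,
    TileDataset,
    background_fraction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_ORDER",
    "EXCLUDED",
    "COMPARISON_BACKBONES",
    "ClassifierConfig",
    "TileClassifier",
    "ClassMatrix",
    "train_classifier",
    "classify_slide",
    "majority_filter",
    "matrix_to_mask",
    "evaluate_classifier",
]

#: Fixed output order of the three tissue classes.
CLASS_ORDER = ("epithelium", "stroma", "others")

#: Class-matrix code for background-heavy tiles that are not classified.
EXCLUDED = 3

#: Alternative transfer-learning backbones considered at 197 x 197 input;
#: recorded as configuration constants only (not benchmarked here).
COMPARISON_BACKBONES = {
    "resnet50": {"input_side": 197},
    "inception_resnet_v2": {"input_side": 197},
    "vgg19": {"input_side": 48},
}


@dataclass
class ClassifierConfig:
    """Hyper-parameters for the tile classifier.

    Defaults follow the tuned transfer-learning setup: 12 trainable end
    layers, a 1024-unit ReLU dense head, dropout 0.2, Adam with learning
    rate 1e-7 and no decay, batch size 32, and 48 x 48 inputs (the smallest
    size the pretrained VGG19 base accepts, which keeps the slide-level
    class matrix finely rasterized).
    """

    backbone: str = "color_baseline"  # or "vgg19_transfer"
    trainable_end_layers: int = 12
    dense_units: int = 1024
    dropout_rate: float = 0.2
    optimizer: dict = field(
        default_factory=lambda: {"name": "adam", "learning_rate": 1e-7, "decay": 0.0}
    )
    batch_size: int = 32
    input_side: int = TILE_MIN_SIDE
    epochs: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.dropout_rate < 1):
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.optimizer.get("learning_rate", 0) <= 0:
            raise ValueError("optimizer learning_rate must be > 0")
        if self.input_side < TILE_MIN_SIDE:
            raise ValueError(f"input_side must be >= {TILE_MIN_SIDE}")
        if self.backbone not in ("color_baseline", "vgg19_transfer"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


def _color_features(X: np.ndarray) -> np.ndarray:
    """Summary color/texture features for a batch of tiles.

    Per channel: mean, std, and an 8-bin intensity histogram; plus the
    grayscale mean/std and the mean absolute horizontal/vertical gradient
    (a cheap texture cue).  Shape (n, 3*2 + 3*8 + 4) = (n, 34).
    """
    Xf = X.astype(np.float64)
    n = Xf.shape[0]
    flat = Xf.reshape(n, -1, 3)
    means = flat.mean(axis=1)
    stds = flat.std(axis=1)
    hists = np.empty((n, 3, 8))
    edges = np.linspace(0, 256, 9)
    for c in range(3):
        # vectorized per-channel histogram via binned counts
        idx = np.clip(np.searchsorted(edges, flat[:, :, c], side="right") - 1, 0, 7)
        for b in range(8):
            hists[:, c, b] = (idx == b).mean(axis=1)
    gray = Xf.mean(axis=3)
    gmean = gray.reshape(n, -1).mean(axis=1)
    gstd = gray.reshape(n, -1).std(axis=1)
    dx = np.abs(np.diff(gray, axis=2)).reshape(n, -1).mean(axis=1)
    dy = np.abs(np.diff(gray, axis=1)).reshape(n, -1).mean(axis=1)
    return np.hstack(
        [means, stds, hists.reshape(n, -1), gmean[:, None], gstd[:, None], dx[:, None], dy[:, None]]
    )


class TileClassifier:
    """Backend-agnostic 3-class tile classifier.

    ``predict_proba`` returns one probability row per tile in the fixed
    ``CLASS_ORDER`` (rows sum to 1); prediction is only available once
    fitted.
    """

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.fitted = False
        self.class_order = CLASS_ORDER
        self._model = None

    # -- fitting -----------------------------------------------------------
    def fit(self, train: TileDataset, val: TileDataset) -> dict:
        if len(train) == 0 or len(val) == 0:
            raise ValueError("train and validation datasets must be nonempty")
        _, y_train = train.as_arrays()
        missing = set(CLASS_ORDER) - set(y_train)
        if missing:
            raise ValueError(f"training set is missing classes: {sorted(missing)}")
        if self.config.backbone == "color_baseline":
            self._fit_baseline(train)
        else:
            self._fit_vgg19(train, val)
        self.fitted = True
        return evaluate_classifier(self, val)

    def _fit_baseline(self, train: TileDataset) -> None:
        X, y = train.as_arrays()
        feats = _color_features(X)
        self._model = make_pipeline(
            StandardScaler(),
            LogisticRegression(
                max_iter=2000,
                C=1.0,
                random_state=self.config.seed,
            ),
        )
        self._model.fit(feats, y)
        self._classes = list(self._model.named_steps["logisticregression"].classes_)

    def _fit_vgg19(self, train: TileDataset, val: TileDataset) -> None:
        try:  # pragma: no cover - requires a deep-learning backend
            from tensorflow import keras
        except ImportError as exc:
            raise RuntimeError(
                "backbone 'vgg19_transfer' needs a Keras/TensorFlow backend, "
                "which is not installed; use backbone='color_baseline' instead"
            ) from exc
        cfg = self.config  # pragma: no cover
        base = keras.applications.VGG19(  # pragma: no cover
            include_top=False,
            weights="imagenet",
            input_shape=(cfg.input_side, cfg.input_side, 3),
        )
        for layer in base.layers[: len(base.layers) - cfg.trainable_end_layers]:  # pragma: no cover
            layer.trainable = False
        model = keras.Sequential(  # pragma: no cover
            [
                base,
                keras.layers.Flatten(),
                keras.layers.Dense(cfg.dense_units, activation="relu"),
                keras.layers.Dropout(cfg.dropout_rate),
                keras.layers.Dense(len(CLASS_ORDER), activation="softmax"),
            ]
        )
        model.compile(  # pragma: no cover
            optimizer=keras.optimizers.Adam(
                learning_rate=cfg.optimizer["learning_rate"],
                weight_decay=cfg.optimizer.get("decay", 0.0) or None,
            ),
            loss="sparse_categorical_crossentropy",
            metrics=["accuracy"],
        )
        code = {c: i for i, c in enumerate(CLASS_ORDER)}  # pragma: no cover
        Xt, yt = train.as_arrays()  # pragma: no cover
        Xv, yv = val.as_arrays()  # pragma: no cover
        model.fit(  # pragma: no cover
            Xt / 255.0,
            np.array([code[c] for c in yt]),
            validation_data=(Xv / 255.0, np.array([code[c] for c in yv])),
            batch_size=cfg.batch_size,
            epochs=cfg.epochs,
            verbose=0,
        )
        self._model = model  # pragma: no cover
        self._classes = list(CLASS_ORDER)  # pragma: no cover

    # -- prediction --------------------------------------------------------
    def predict_proba(self, tiles: np.ndarray) -> np.ndarray:
        """Class probabilities for (n, 48, 48, 3) tile rasters, in CLASS_ORDER."""
        if not self.fitted:
            raise RuntimeError("classifier is not fitted")
        tiles = np.asarray(tiles)
        if tiles.ndim == 3:
            tiles = tiles[None]
        if self.config.backbone == "color_baseline":
            raw = self._model.predict_proba(_color_features(tiles))
        else:  # pragma: no cover
            raw = self._model.predict(tiles / 255.0, verbose=0)
        out = np.zeros((tiles.shape[0], len(CLASS_ORDER)))
        for j, cls in enumerate(self._classes):
            out[:, CLASS_ORDER.index(cls)] = raw[:, j]
        return out / out.sum(axis=1, keepdims=True)

    def predict(self, tiles: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(tiles)
        return np.array([CLASS_ORDER[i] for i in proba.argmax(axis=1)])


def train_classifier(
    train: TileDataset,
    val: TileDataset,
    config: ClassifierConfig | None = None,
) -> tuple[TileClassifier, dict]:
    """Fit a tile classifier and report validation metrics."""
    clf = TileClassifier(config)
    m = clf.fit(train, val)
    logger.info(
        "trained %s: val accuracy %.4f, macro F1 %.4f",
        clf.config.backbone,
        m["accuracy"],
        m["macro_f1"],
    )
    return clf, m


@dataclass
class ClassMatrix:
    """Grid of per-tile class codes covering a slide.

    Codes 0/1/2 follow ``CLASS_ORDER``; ``EXCLUDED`` (3) marks
    background-heavy tiles.  Cell (i, j) covers pixels
    rows [i*stride, i*stride+side), cols [j*stride, j*stride+side).
    """

    labels: np.ndarray  # (rows, cols) int
    tile_side_px: int
    stride_px: int
    slide_shape: tuple[int, int]  # (H, W)

    def __post_init__(self):
        H, W = self.slide_shape
        exp = (
            (H - self.tile_side_px) // self.stride_px + 1,
            (W - self.tile_side_px) // self.stride_px + 1,
        )
        if self.labels.shape != exp:
            raise ValueError(f"labels shape {self.labels.shape} != expected grid {exp}")

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=4)
        out = {c: int(counts[i]) for i, c in enumerate(CLASS_ORDER)}
        out["excluded"] = int(counts[EXCLUDED])
        return out


def classify_slide(
    image: np.ndarray,
    clf: TileClassifier,
    tile_side: int = TILE_MIN_SIDE,
    stride: int | None = None,
) -> ClassMatrix:
    """Sweep the classifier over a slide and build its class matrix.

    Tiles whose background fraction exceeds 30% are marked ``EXCLUDED``
    instead of being classified, mirroring the training-side filter.
    """
    if not clf.fitted:
        raise RuntimeError("classifier is not fitted")
    stride = tile_side if stride is None else stride
    H, W = image.shape[:2]
    if H < tile_side or W < tile_side:
        raise ValueError(
            f"image {H}x{W} is smaller than one {tile_side}x{tile_side} tile"
        )
    rows = (H - tile_side) // stride + 1
    cols = (W - tile_side) // stride + 1

    tiles = np.empty((rows * cols, tile_side, tile_side, 3), dtype=image.dtype)
    for i in range(rows):
        for j in range(cols):
            y, x = i * stride, j * stride
            tiles[i * cols + j] = image[y : y + tile_side, x : x + tile_side]

    bg = np.array([background_fraction(t) for t in tiles])
    keep = bg <= BACKGROUND_MAX_FRACTION
    labels = np.full(rows * cols, EXCLUDED, dtype=np.int64)
    if keep.any():
        proba = clf.predict_proba(tiles[keep])
        labels[keep] = proba.argmax(axis=1)
    return ClassMatrix(
        labels=labels.reshape(rows, cols),
        tile_side_px=tile_side,
        stride_px=stride,
        slide_shape=(H, W),
    )


def majority_filter(matrix: ClassMatrix, window: int = 3) -> ClassMatrix:
    """Replace each cell by the modal label of its window neighbors.

    The cell's own label does not vote, so an isolated cell whose
    neighbors all disagree with it is always absorbed — the filter's
    purpose.  Excluded cells neither vote nor change, and a cell with no
    voting neighbors keeps its label.  Ties keep the cell's original
    label when it is among the tied winners, otherwise the lowest class
    code wins (deterministic).  Borders use the truncated neighborhood.
    Single pass.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    lab = matrix.labels
    rows, cols = lab.shape
    half = window // 2
    out = lab.copy()
    changed = 0
    for i in range(rows):
        for j in range(cols):
            if lab[i, j] == EXCLUDED:
                continue
            win = lab[
                max(0, i - half) : i + half + 1, max(0, j - half) : j + half + 1
            ]
            votes = np.bincount(win.ravel(), minlength=4)[: len(CLASS_ORDER)]
            votes[lab[i, j]] -= 1  # the cell itself does not vote
            if votes.sum() == 0:
                continue
            best = votes.max()
            winners = np.flatnonzero(votes == best)
            if lab[i, j] in winners:
                new = lab[i, j]
            else:
                new = int(winners[0])
            if new != lab[i, j]:
                out[i, j] = new
                changed += 1
    if changed:
        logger.info("majority filter relabeled %d of %d cells", changed, lab.size)
    return ClassMatrix(
        labels=out,
        tile_side_px=matrix.tile_side_px,
        stride_px=matrix.stride_px,
        slide_shape=matrix.slide_shape,
    )


def matrix_to_mask(matrix: ClassMatrix) -> np.ndarray:
    """Expand the class matrix to a per-pixel label raster.

    Every pixel inherits its tile's label; pixels beyond the last full tile
    are ``EXCLUDED``.  Requires non-overlapping tiling (stride == side).
    """
    if matrix.stride_px != matrix.tile_side_px:
        raise NotImplementedError(
            "matrix_to_mask requires stride == tile side (non-overlapping grid)"
        )
    H, W = matrix.slide_shape
    side = matrix.tile_side_px
    mask = np.full((H, W), EXCLUDED, dtype=np.uint8)
    block = np.kron(matrix.labels, np.ones((side, side), dtype=np.uint8))
    mask[: block.shape[0], : block.shape[1]] = block
    return mask


def evaluate_classifier(clf: TileClassifier, test: TileDataset) -> dict:
    """Accuracy, per-class precision/recall/F1, macro F1 and confusion matrix."""
    if not clf.fitted:
        raise RuntimeError("classifier is not fitted")
    if len(test) == 0:
        raise ValueError("test dataset is empty")
    X, y = test.as_arrays()
    pred = clf.predict(X)
    labels = list(CLASS_ORDER)
    prec, rec, f1, _ = _skm.precision_recall_fscore_support(
        y, pred, labels=labels, zero_division=0
    )
    return {
        "accuracy": float(_skm.accuracy_score(y, pred)),
        "per_class": {
            c: {"precision": float(p), "recall": float(r), "f1": float(f)}
            for c, p, r, f in zip(labels, prec, rec, f1)
        },
        "macro_f1": float(f1.mean()),
        "confusion": _skm.confusion_matrix(y, pred, labels=labels).tolist(),
        "n": int(len(y)),
    }
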