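"""Contour-driven tile extraction for the tile classifier.

Annotated contours are turned into square training tiles: random side in
[48, 256] px, random position fully inside the contour, a per-contour tile
budget proportional to annotated area (twice the area divided by the area
of a reference 152 px tile, capped at 100), a near-white background filter
(tiles more than 30% background are dropped) and a final bilinear resize
to 48 x 48.  Train/validation/test splits are patient-disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from skimage.transform import resize as _sk_resize

from ._rng import substream

logger = logging.getLogger(__name__)

__all__ = [
    "TILE_MIN_SIDE",
    "TILE_MAX_SIDE",
    "TILE_REF_SIDE",
    "TILE_CAP",
    "BACKGROUND_WHITE_THRESHOLD",
    "BACKGROUND_MAX_FRACTION",
    "Contour",
    "Tile",
    "TileDataset",
    "tile_budget",
    "background_fraction",
    "sample_tiles",
    "filter_and_resize",
    "split_by_patient",
]

TILE_MIN_SIDE = 48
TILE_MAX_SIDE = 256
#: Reference side for the tile budget: the mean of the min and max sides.
TILE_REF_SIDE = 152
#: Hard cap on tiles minted from a single annotation.
TILE_CAP = 100
#: A pixel is background when all three channels reach this value (uint8).
BACKGROUND_WHITE_THRESHOLD = 220
#: Tiles with more than this background fraction are dropped (0.30 kept).
BACKGROUND_MAX_FRACTION = 0.30
#: Rejection-sampling attempts per requested tile before giving up.
SAMPLE_ATTEMPTS_PER_TILE = 50


@dataclass
class Contour:
    """A single-class annotation polygon in pixel coordinates.

    Vertices use a top-left origin with x rightward and y downward.
    """

    polygon: list[tuple[float, float]]
    class_label: str
    patient_id: str

    def __post_init__(self):
        if len(self.polygon) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        shp = Polygon(self.polygon)
        if not shp.is_valid:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        if shp.area <= 0:
            raise ValueError("polygon area must be > 0")

    @property
    def shape(self) -> Polygon:
        return Polygon(self.polygon)

    @property
    def area_px(self) -> float:
        return self.shape.area


@dataclass
class Tile:
    """A square crop from a slide, tagged with its annotation's class."""

    origin: tuple[int, int]  # (x, y) of the top-left corner
    side_px: int
    pixels: np.ndarray  # (side, side, 3) uint8 (48 x 48 after resize)
    class_label: str
    patient_id: str
    background_fraction: float = float("nan")

    def __post_init__(self):
        if np.isnan(self.background_fraction):
            self.background_fraction = background_fraction(self.pixels)


@dataclass
class TileDataset:
    split: str  # train | validation | test
    tiles: list[Tile] = field(default_factory=list)

    @property
    def patient_ids(self) -> set[str]:
        return {t.patient_id for t in self.tiles}

    def __len__(self) -> int:
        return len(self.tiles)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.tiles:
            out[t.class_label] = out.get(t.class_label, 0) + 1
        return out

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack tile rasters into (n, side, side, 3) plus a label array."""
        X = np.stack([t.pixels for t in self.tiles])
        y = np.array([t.class_label for t in self.tiles])
        return X, y


def tile_budget(area_px: float) -> int:
    """Number of tiles to mint from an annotation of the given pixel area.

    Twice the annotated area divided by the area of a reference tile of
    side 152 (the midpoint of the 48-256 size range), floored, clamped to
    [1, 100]: min(100, max(1, floor(2 * area / 152^2))).
    """
    if area_px <= 0:
        raise ValueError(f"area_px must be > 0, got {area_px}")
    raw = int(np.floor(2.0 * area_px / (TILE_REF_SIDE * TILE_REF_SIDE)))
    return min(TILE_CAP, max(1, raw))


def background_fraction(tile_pixels: np.ndarray) -> float:
    """Fraction of pixels that are near-white background.

    A pixel counts as background when all three channels are at least
    ``BACKGROUND_WHITE_THRESHOLD`` (default 220) — the H&E convention that
    unstained glass is near-white while any tissue retains stain in at
    least one channel.
    """
    px = np.asarray(tile_pixels)
    if px.size == 0:
        raise ValueError("empty tile raster")
    white = np.all(px >= BACKGROUND_WHITE_THRESHOLD, axis=-1)
    return float(white.mean())


def sample_tiles(
    contour: Contour,
    image: np.ndarray,
    seed: int = 0,
    attempts_per_tile: int = SAMPLE_ATTEMPTS_PER_TILE,
) -> list[Tile]:
    """Randomly crop square tiles that lie entirely inside the contour.

    Tile sides are uniform random integers in [48, 256]; positions are
    uniform over the contour's bounding box, accepted when all four corners
    and the center fall inside the polygon (rejection sampling, at most
    ``attempts_per_tile`` attempts per budgeted tile).  Overlap between
    accepted tiles is allowed by design: a large part of the contour is
    covered with overlapping crops.  Deterministic given ``seed``.
    """
    shp = contour.shape
    budget = tile_budget(shp.area)
    rng = substream(seed, "tiles", contour.patient_id, contour.class_label)

    minx, miny, maxx, maxy = shp.bounds
    h, w = image.shape[:2]
    tiles: list[Tile] = []
    bbox_w, bbox_h = maxx - minx, maxy - miny
    if bbox_w < TILE_MIN_SIDE or bbox_h < TILE_MIN_SIDE:
        logger.warning(
            "contour (%s, %s) cannot host a %dx%d tile; returning no tiles",
            contour.patient_id,
            contour.class_label,
            TILE_MIN_SIDE,
            TILE_MIN_SIDE,
        )
        return tiles

    for _ in range(budget):
        for _a in range(attempts_per_tile):
            side = int(rng.integers(TILE_MIN_SIDE, TILE_MAX_SIDE + 1))
            if side > bbox_w or side > bbox_h:
                continue
            x = int(rng.integers(int(np.ceil(minx)), int(np.floor(maxx - side)) + 1))
            y = int(rng.integers(int(np.ceil(miny)), int(np.floor(maxy - side)) + 1))
            probes = [
                (x, y),
                (x + side, y),
                (x, y + side),
                (x + side, y + side),
                (x + side / 2.0, y + side / 2.0),
            ]
            if not all(shp.covers(Point(p)) for p in probes):
                continue
            if x < 0 or y < 0 or x + side > w or y + side > h:
                continue
            pixels = np.ascontiguousarray(image[y : y + side, x : x + side])
            tiles.append(
                Tile(
                    origin=(x, y),
                    side_px=side,
                    pixels=pixels,
                    class_label=contour.class_label,
                    patient_id=contour.patient_id,
                )
            )
            break
    if len(tiles) < budget:
        logger.info(
            "contour (%s, %s): sampled %d of %d budgeted tiles",
            contour.patient_id,
            contour.class_label,
            len(tiles),
            budget,
        )
    return tiles


def _resize48(pixels: np.ndarray) -> np.ndarray:
    if pixels.shape[:2] == (TILE_MIN_SIDE, TILE_MIN_SIDE):
        return pixels
    out = _sk_resize(
        pixels.astype(np.float64),
        (TILE_MIN_SIDE, TILE_MIN_SIDE),
        order=1,  # bilinear
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def filter_and_resize(tiles: list[Tile]) -> list[Tile]:
    """Drop background-heavy tiles, then resize survivors to 48 x 48.

    A tile is dropped when strictly more than 30% of its pixels are
    background; exactly 30% is kept.  The background fraction is recomputed
    on the resized raster, which makes the operation idempotent.
    """
    out: list[Tile] = []
    dropped = 0
    for t in tiles:
        if t.background_fraction > BACKGROUND_MAX_FRACTION:
            dropped += 1
            continue
        px = _resize48(t.pixels)
        out.append(
            Tile(
                origin=t.origin,
                side_px=TILE_MIN_SIDE,
                pixels=px,
                class_label=t.class_label,
                patient_id=t.patient_id,
            )
        )
    if dropped:
        logger.info("background filter dropped %d of %d tiles", dropped, len(tiles))
    return out


def split_by_patient(
    tiles: list[Tile],
    train_ids,
    val_ids,
) -> tuple[TileDataset, TileDataset]:
    """Route tiles into patient-disjoint train/validation datasets.

    Tiles from patients in neither id set are excluded (counted in the log);
    overlapping id sets are rejected.
    """
    train_ids, val_ids = set(train_ids), set(val_ids)
    overlap = train_ids & val_ids
    if overlap:
        raise ValueError(f"train and validation patient ids overlap: {sorted(overlap)}")
    train = TileDataset(split="train")
    val = TileDataset(split="validation")
    unrouted = 0
    for t in tiles:
        if t.patient_id in train_ids:
            train.tiles.append(t)
        elif t.patient_id in val_ids:
            val.tiles.append(t)
        else:
            unrouted += 1
    if unrouted:
        logger.info("split_by_patient: %d tiles from unlisted patients excluded", unrouted)
    return train, val
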