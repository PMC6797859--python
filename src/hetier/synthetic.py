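"""Synthetic H&E-like slide generator with ground-truth compartment masks.

Real tissue-microarray (TMA) sections are not redistributable, so every
downstream stage of the pipeline is developed and tested against generated
slides that emulate the salient structure of an H&E-stained breast-tissue
core:

* a roughly circular tissue core on a white slide background,
* a pink eosin-textured stroma field filling the core,
* purple hematoxylin-dominated epithelial nests (elliptical, simply
  connected) embedded in the stroma,
* at least one "others" blob (necrosis / secretion-like material),
* per-pixel i.i.d. Gaussian color noise whose standard deviation grows
  with disease state, so that within-compartment color dispersion — and
  therefore K-means inertia — is a monotone function of disease severity.

The scale convention is 250 px per millimetre (``PX_PER_MM``), so a 1 mm
TMA core fits a 256 px canvas; physical sizes quoted elsewhere in the
package follow this constant.

Geometry and color noise are drawn from split RNG streams: holding the
slide seed fixed while varying ``noise_seed`` keeps the label geometry
bit-identical while re-rolling the colors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk, ellipse

from ._rng import substream

logger = logging.getLogger(__name__)

__all__ = [
    "STATES",
    "STATE_NOISE_MULTIPLIERS",
    "CLASS_NAMES",
    "EPITHELIUM",
    "STROMA",
    "OTHERS",
    "BACKGROUND",
    "LABEL_CODES",
    "PX_PER_MM",
    "DEFAULT_COLOR_MEANS",
    "DEFAULT_COLOR_STDS",
    "SlideSpec",
    "SlideRecord",
    "generate_slide",
    "generate_cohort",
    "generate_annotations",
    "min_pairwise_separation",
]

#: Disease states, ordered from benign to malignant.
STATES = ("normal", "hyperplasia", "dysplasia", "malignant")

#: Multiplier applied to every class noise std, per disease state.  Strictly
#: increasing so within-compartment dispersion tracks severity.
STATE_NOISE_MULTIPLIERS = {
    "normal": 1.0,
    "hyperplasia": 1.5,
    "dysplasia": 2.0,
    "malignant": 3.0,
}

# Integer truth-mask codes (single-channel PNG palette indices).
EPITHELIUM, STROMA, OTHERS, BACKGROUND = 0, 1, 2, 3
CLASS_NAMES = ("epithelium", "stroma", "others", "background")
LABEL_CODES = {name: code for code, name in enumerate(CLASS_NAMES)}

#: Pixel scale convention: 1 mm = 250 px (a 1 mm TMA core ≈ 250 px across).
PX_PER_MM = 250

#: Default class mean colors (uint8 RGB).  Pairwise L-infinity separation of
#: at least 40 (e.g. pink stroma and white background differ mainly in G/B).
DEFAULT_COLOR_MEANS = {
    "epithelium": (120, 60, 160),  # hematoxylin purple
    "stroma": (230, 150, 200),  # eosin pink
    "others": (170, 110, 80),  # necrosis / secretion brown
    "background": (250, 250, 250),
}

#: Default per-class Gaussian noise std (uint8 scale), before the state
#: multiplier.  Background is kept nearly noise-free so the near-white
#: background rule stays reliable at every state.
DEFAULT_COLOR_STDS = {
    "epithelium": 10.0,
    "stroma": 10.0,
    "others": 10.0,
    "background": 2.0,
}


def min_pairwise_separation(means: dict[str, tuple]) -> float:
    """Smallest pairwise L-infinity distance between class mean colors."""
    names = list(means)
    best = np.inf
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = np.max(np.abs(np.asarray(means[a], float) - np.asarray(means[b], float)))
            best = min(best, float(d))
    return best


@dataclass
class SlideSpec:
    """Parameters for one synthetic slide.

    ``color_means``/``color_stds`` map class name -> RGB triple / scalar std.
    Arbitrary palettes are accepted (including deliberately identical class
    means, used as a negative control for the tile classifier); the default
    palette keeps classes separated by >= 40 in at least one channel.
    """

    width_px: int = 256
    height_px: int = 256
    n_epithelial_nests: int = 3
    nest_radius_px: tuple[int, int] = (40, 52)
    state: str = "normal"
    color_means: dict = field(default_factory=lambda: dict(DEFAULT_COLOR_MEANS))
    color_stds: dict = field(default_factory=lambda: dict(DEFAULT_COLOR_STDS))
    texture_scale_px: float = 12.0
    texture_strength: float = 5.0
    n_other_blobs: tuple[int, int] = (1, 2)
    other_blob_radius_px: tuple[int, int] = (40, 52)
    core_radius_frac: float = 0.48
    state_multipliers: dict = field(
        default_factory=lambda: dict(STATE_NOISE_MULTIPLIERS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.width_px < 256:
            raise ValueError(f"width_px must be >= 256, got {self.width_px}")
        if self.height_px < 256:
            raise ValueError(f"height_px must be >= 256, got {self.height_px}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        for name in CLASS_NAMES:
            if name not in self.color_means:
                raise ValueError(f"color_means missing class {name!r}")
            if name not in self.color_stds:
                raise ValueError(f"color_stds missing class {name!r}")
            if self.color_stds[name] < 0:
                raise ValueError(f"color_stds[{name!r}] must be >= 0")
        if self.n_epithelial_nests < 0:
            raise ValueError("n_epithelial_nests must be >= 0")
        lo, hi = self.nest_radius_px
        if not (0 < lo <= hi):
            raise ValueError(f"nest_radius_px must satisfy 0 < lo <= hi, got {(lo, hi)}")
        mults = [self.state_multipliers[s] for s in STATES]
        if not all(b > a for a, b in zip(mults, mults[1:])):
            raise ValueError(
                f"state_multipliers must be strictly increasing over {STATES}, got {mults}"
            )


@dataclass
class SlideRecord:
    """One patient's slide: RGB image + per-pixel ground-truth labels."""

    image: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) uint8, values in LABEL_CODES
    patient_id: str
    state: str

    def __post_init__(self):
        if self.image.shape[:2] != self.truth_mask.shape:
            raise ValueError(
                "image and truth_mask shapes differ: "
                f"{self.image.shape[:2]} vs {self.truth_mask.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth_mask.shape

    def class_pixel_counts(self) -> dict[str, int]:
        counts = np.bincount(self.truth_mask.ravel(), minlength=len(CLASS_NAMES))
        return {name: int(counts[code]) for name, code in LABEL_CODES.items()}


def _draw_geometry(spec: SlideSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    mask = np.full((h, w), BACKGROUND, dtype=np.uint8)

    core_r = spec.core_radius_frac * min(h, w)
    cy, cx = h / 2.0, w / 2.0
    rr, cc = disk((cy, cx), core_r, shape=(h, w))
    mask[rr, cc] = STROMA
    in_core = mask == STROMA

    # Epithelial nests: ellipses confined to the tissue core.
    lo, hi = spec.nest_radius_px
    for _ in range(spec.n_epithelial_nests):
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        theta = rng.uniform(0, np.pi)
        rad = rng.uniform(0, 0.7 * core_r)
        ang = rng.uniform(0, 2 * np.pi)
        ny, nx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        rr, cc = ellipse(ny, nx, a, b, shape=(h, w), rotation=theta)
        keep = in_core[rr, cc]
        mask[rr[keep], cc[keep]] = EPITHELIUM

    # "Others" blobs placed in remaining stroma; guarantee at least one.
    blo, bhi = spec.n_other_blobs
    n_blobs = int(rng.integers(blo, bhi + 1)) if bhi > blo else blo
    n_blobs = max(1, n_blobs)
    rlo, rhi = spec.other_blob_radius_px
    for _ in range(n_blobs):
        # Prefer compact placements (blob mostly intact in stroma) so the
        # "others" class, like the nests, can host annotation windows.
        placed = False
        for min_intact in (0.85, 0.25):
            for _attempt in range(30):
                a = rng.uniform(rlo, rhi)
                b = rng.uniform(rlo, rhi)
                theta = rng.uniform(0, np.pi)
                rad = rng.uniform(0, 0.7 * core_r)
                ang = rng.uniform(0, 2 * np.pi)
                ny, nx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
                rr, cc = ellipse(ny, nx, a, b, shape=(h, w), rotation=theta)
                keep = mask[rr, cc] == STROMA  # never overwrite epithelium
                if keep.sum() >= min_intact * np.pi * a * b:
                    mask[rr[keep], cc[keep]] = OTHERS
                    placed = True
                    break
            if placed:
                break
    if not np.any(mask == OTHERS):
        # Degenerate geometry (core almost fully covered by nests): convert
        # a small stroma patch so the "at least one blob" contract holds.
        ys, xs = np.nonzero(mask == STROMA)
        if ys.size:
            i = int(rng.integers(ys.size))
            rr, cc = disk((ys[i], xs[i]), rlo, shape=(h, w))
            keep = mask[rr, cc] == STROMA
            mask[rr[keep], cc[keep]] = OTHERS
    return mask


def generate_slide(
    spec: SlideSpec,
    patient_id: str | None = None,
    noise_seed: int | None = None,
) -> SlideRecord:
    """Render one synthetic slide from its spec, deterministically.

    Geometry is drawn from the ``(seed, "geometry")`` substream and color
    noise from ``(noise_seed or seed, "noise")``, so two calls with the same
    spec are bit-identical, and varying ``noise_seed`` alone re-rolls colors
    on a fixed label geometry.
    """
    spec.validate()
    geo = substream(spec.seed, "geometry")
    noise = substream(spec.seed if noise_seed is None else noise_seed, "noise")

    mask = _draw_geometry(spec, geo)
    h, w = mask.shape

    img = np.empty((h, w, 3), dtype=np.float64)
    std_map = np.empty((h, w), dtype=np.float64)
    for name, code in LABEL_CODES.items():
        sel = mask == code
        img[sel] = np.asarray(spec.color_means[name], dtype=np.float64)
        std_map[sel] = spec.color_stds[name]

    # Eosin-like low-frequency brightness texture on stroma only: constant
    # across disease states, so state ordering of dispersion comes solely
    # from the noise multiplier.
    if spec.texture_strength > 0:
        raw = noise.standard_normal((h, w))
        tex = ndimage.gaussian_filter(raw, sigma=spec.texture_scale_px)
        s = tex.std()
        if s > 0:
            tex = tex / s * spec.texture_strength
            img[mask == STROMA] += tex[mask == STROMA, None]

    mult = spec.state_multipliers[spec.state]
    img += noise.standard_normal((h, w, 3)) * (std_map[..., None] * mult)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    pid = patient_id if patient_id is not None else f"slide-{spec.seed}"
    return SlideRecord(image=img, truth_mask=mask, patient_id=pid, state=spec.state)


def generate_cohort(
    n_per_state: int,
    base_spec: SlideSpec | None = None,
    seed: int = 0,
) -> tuple[list[SlideRecord], pd.DataFrame]:
    """Generate a balanced cohort: ``n_per_state`` slides for each state.

    Returns the slides (unique patient ids ``P0001``...) and a cohort table
    with one row per slide.
    """
    if n_per_state < 1:
        raise ValueError(f"n_per_state must be >= 1, got {n_per_state}")
    if base_spec is None:
        base_spec = SlideSpec()
    slide_seeds = substream(seed, "cohort-slide-seeds").integers(
        0, 2**31 - 1, size=4 * n_per_state
    )
    records: list[SlideRecord] = []
    rows = []
    idx = 0
    for state in STATES:
        for _ in range(n_per_state):
            pid = f"P{idx + 1:04d}"
            spec = replace(base_spec, state=state, seed=int(slide_seeds[idx]))
            records.append(generate_slide(spec, patient_id=pid))
            rows.append(
                {
                    "patient_id": pid,
                    "state": state,
                    "slide_seed": int(slide_seeds[idx]),
                    "width_px": spec.width_px,
                    "height_px": spec.height_px,
                }
            )
            idx += 1
    return records, pd.DataFrame(rows)


def generate_annotations(
    record: SlideRecord,
    n_contours: int,
    area_bounds_px: tuple[float, float] = (3600.0, 16384.0),
    seed: int = 0,
):
    """Mint pathologist-style rectangular contour annotations from truth.

    Each contour is a rectangle placed entirely inside a single truth-class
    region (epithelium, stroma or others), with target area drawn uniformly
    from ``area_bounds_px``.  When a class region cannot host the requested
    area the rectangle is shrunk geometrically; contours that still cannot
    be placed are dropped with a log message, so fewer than ``n_contours``
    may be returned.
    """
    from .tiling import Contour  # local import to avoid a cycle

    if n_contours < 0:
        raise ValueError("n_contours must be >= 0")
    rng = substream(seed, "annotations", record.patient_id)
    mask = record.truth_mask
    h, w = mask.shape

    tissue_classes = [c for c in ("epithelium", "stroma", "others")]
    counts = record.class_pixel_counts()
    avail = [c for c in tissue_classes if counts[c] > 0]
    if not avail:
        return []

    contours = []
    lo, hi = area_bounds_px
    for i in range(n_contours):
        cls = str(rng.choice(avail))
        code = LABEL_CODES[cls]
        inside = mask == code
        area = float(rng.uniform(lo, hi))
        aspect = float(rng.uniform(0.75, 1.3333))
        placed = False
        for _shrink in range(7):
            rw = max(8, int(round(np.sqrt(area * aspect))))
            rh = max(8, int(round(area / rw)))
            if rw <= w and rh <= h:
                ok = ndimage.minimum_filter(
                    inside, size=(rh, rw), mode="constant", cval=False
                )
                # Exclude centers whose window would leave the image.
                valid = np.zeros_like(ok)
                y0, y1 = rh // 2, h - (rh - rh // 2) + 1
                x0, x1 = rw // 2, w - (rw - rw // 2) + 1
                valid[y0:y1, x0:x1] = ok[y0:y1, x0:x1]
                ys, xs = np.nonzero(valid)
                if ys.size:
                    j = int(rng.integers(ys.size))
                    top = ys[j] - rh // 2
                    left = xs[j] - rw // 2
                    poly = [
                        (float(left), float(top)),
                        (float(left + rw), float(top)),
                        (float(left + rw), float(top + rh)),
                        (float(left), float(top + rh)),
                    ]
                    contours.append(
                        Contour(
                            polygon=poly,
                            class_label=cls,
                            patient_id=record.patient_id,
                        )
                    )
                    placed = True
                    break
            if area <= lo:
                break
            area = max(0.7 * 0.7 * area, lo)  # shrink, clamped at the bound
        if not placed:
            logger.warning(
                "annotation %d: no %s region of ~%.0f px^2 on slide %s; dropped",
                i,
                cls,
                rng.uniform(lo, hi),
                record.patient_id,
            )
    return contours
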