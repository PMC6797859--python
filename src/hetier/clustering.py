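"""Two-stage K-means on RGB pixels within each tissue compartment.

Stage 1 (refinement): a K=2 clustering of a compartment's RGB pixels drops
the minority cluster — small regions the tile classifier misassigned tend
to form a color mode distinct from the compartment's bulk.  A guard keeps
the compartment intact when the "minority" exceeds 40% of pixels, so a
genuinely bimodal compartment is never halved.

Stage 2: Lloyd's K-means for k = 2..5 on the refined pixels, run for up to
300 iterations and restarted 10 times from random initial centroids, the
minimum-inertia solution kept.  Inertia — the within-cluster sum of squared
Euclidean RGB distances — is the dispersion statistic that feeds the
diagnosis stage.

Initial centroids are a uniform random choice of k distinct observed
pixel values; restart r of a run seeded s draws from the (s, "restart", r)
substream, so restart streams are nested prefixes across n_init values and
the best-of-n_init inertia is non-increasing in n_init by construction.
Pixels are first collapsed to (unique color, multiplicity) pairs — an
exact reformulation — and each restart's Lloyd iteration runs at C speed
through sklearn's KMeans with n_init=1.  kmeans_rgb defaults to strict
assignment-stable convergence (tol=0); slide-scale clustering uses the
standard relative centroid-shift tolerance SLIDE_KMEANS_TOL instead.
Centroids and inertia are finally recomputed as exact float64 cluster
means so the within/between variance decomposition holds to machine
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from sklearn.cluster import KMeans

from ._rng import substream
from .segmentation import CLASS_ORDER, ClassMatrix  # noqa: F401  (re-export convenience)
from .synthetic import EPITHELIUM, STROMA, SlideRecord

logger = logging.getLogger(__name__)

__all__ = [
    "KMEANS_MAX_ITER",
    "KMEANS_N_INIT",
    "DEFAULT_K_VALUES",
    "RETENTION_THRESHOLD",
    "OVERLAY_PALETTE",
    "CompartmentPixels",
    "ClusterResult",
    "SlideClustering",
    "kmeans_rgb",
    "refine_compartment",
    "cluster_compartments",
    "overlay_clusters",
]

KMEANS_MAX_ITER = 300
KMEANS_N_INIT = 10
DEFAULT_K_VALUES = (2, 3, 4, 5)
#: Relative centroid-shift tolerance used for slide-scale clustering
#: (sklearn's standard); kmeans_rgb itself defaults to strict (tol=0)
#: assignment-stable convergence.
SLIDE_KMEANS_TOL = 1e-4
#: Stage-1 guard: if the minority K=2 cluster holds more than this fraction
#: of pixels the compartment is returned unchanged.
RETENTION_THRESHOLD = 0.40

#: Default 5-color overlay palette (uint8 RGB).
OVERLAY_PALETTE = (
    (228, 26, 28),
    (55, 126, 184),
    (77, 175, 74),
    (152, 78, 163),
    (255, 127, 0),
)


@dataclass
class CompartmentPixels:
    """The RGB pixels of one compartment of one slide, with coordinates."""

    compartment: str  # "epithelium" or "stroma"
    coordinates: np.ndarray  # (n, 2) int, (row, col)
    rgb: np.ndarray  # (n, 3) uint8

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates)
        self.rgb = np.asarray(self.rgb)
        if len(self.coordinates) != len(self.rgb):
            raise ValueError("coordinates and rgb must have equal length")

    def __len__(self) -> int:
        return len(self.rgb)


@dataclass
class ClusterResult:
    """Outcome of one best-of-restarts K-means run on a pixel set."""

    k: int
    labels: np.ndarray  # (n,) int in [0, k)
    centroids: np.ndarray  # (k, 3) float
    inertia: float
    n_init: int
    max_iter: int
    seed: int

    def recompute_inertia(self, rgb: np.ndarray) -> float:
        """Recompute inertia from labels + centroids (consistency check)."""
        X = np.asarray(rgb, dtype=np.float64)
        d = X - self.centroids[self.labels]
        return float(np.einsum("ij,ij->", d, d))


def _compress(X: np.ndarray):
    """Collapse a pixel set to unique values + counts (weighted K-means).

    Clustering on (unique colors, multiplicities) is mathematically
    identical to clustering the raw pixels and much cheaper on low-noise
    slides where many pixels share a color.
    """
    uniq, inverse, counts = np.unique(
        X.reshape(-1, 3), axis=0, return_inverse=True, return_counts=True
    )
    return uniq.astype(np.float32), inverse, counts.astype(np.float32)


def _weighted_lloyd(U, w, centroids, max_iter, tol=0.0):
    """One Lloyd run on (unique values U, multiplicities w) from given centroids.

    Iterates until the assignment is strictly stable (tol=0) or ``max_iter``
    is reached; empty clusters are relocated to far points.  The C-level
    iteration is delegated to sklearn's KMeans with ``n_init=1`` and the
    caller-supplied initial centroids, so restart and initialisation
    semantics stay under this module's control; the returned centroids and
    inertia are exact float64 recomputations from the final assignment.
    """
    km = KMeans(
        n_clusters=len(centroids),
        init=centroids,
        n_init=1,
        max_iter=max_iter,
        tol=tol,
        algorithm="lloyd",
    ).fit(U, sample_weight=w)
    labels = km.labels_.astype(np.int64)
    # Exact float64 means + inertia from the final assignment, so inertia
    # identities (law of total variance) hold to machine precision.
    k = len(centroids)
    U64 = U.astype(np.float64)
    w64 = w.astype(np.float64)
    counts = np.bincount(labels, weights=w64, minlength=k)
    centers = np.empty((k, 3), dtype=np.float64)
    for c in range(3):
        centers[:, c] = np.bincount(labels, weights=w64 * U64[:, c], minlength=k)
    centers /= counts[:, None]
    d = U64 - centers[labels]
    inertia = float(np.einsum("i,ij,ij->", w64, d, d))
    return labels, centers, inertia


def _kmeans_unique(U, w, k, n_init, max_iter, seed, tol=0.0):
    """Best-of-restarts K-means on pre-compressed (U, w); returns the
    minimum-inertia (labels over U, centroids, inertia)."""
    if n_init < 1 or max_iter < 1:
        raise ValueError("n_init and max_iter must be >= 1")
    best = None
    for r in range(n_init):
        rng = substream(seed, "restart", r)
        init = U[rng.choice(len(U), size=k, replace=False)].copy()
        labels, centroids, inertia = _weighted_lloyd(U, w, init, max_iter, tol)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia)
    return best


def kmeans_rgb(
    pixels: CompartmentPixels | np.ndarray,
    k: int,
    n_init: int = KMEANS_N_INIT,
    max_iter: int = KMEANS_MAX_ITER,
    seed: int = 0,
    tol: float = 0.0,
) -> ClusterResult:
    """Best-of-restarts K-means on RGB values; deterministic given seed.

    Runs Lloyd's algorithm ``n_init`` times (up to ``max_iter`` iterations
    each, stopping early when assignments stabilise) from random initial
    centroids — a uniform choice of k distinct observed pixel values, drawn
    from the (seed, "restart", r) substream for restart r, so restart
    streams are nested prefixes across n_init values — and keeps the
    minimum-inertia solution.
    """
    rgb = pixels.rgb if isinstance(pixels, CompartmentPixels) else np.asarray(pixels)
    U, inverse, w = _compress(rgb)
    if len(U) < k:
        raise ValueError(f"need at least k={k} distinct pixel values, got {len(U)}")
    labels, centroids, inertia = _kmeans_unique(U, w, k, n_init, max_iter, seed, tol)
    return ClusterResult(
        k=k,
        labels=labels[inverse],
        centroids=centroids,
        inertia=inertia,
        n_init=n_init,
        max_iter=max_iter,
        seed=seed,
    )


def refine_compartment(
    pixels: CompartmentPixels,
    seed: int = 0,
    retention_threshold: float = RETENTION_THRESHOLD,
    n_init: int = KMEANS_N_INIT,
    max_iter: int = KMEANS_MAX_ITER,
) -> CompartmentPixels:
    """Stage-1 K=2 refinement: drop the minority color mode.

    Constant-color compartments (fewer than 2 distinct values) are returned
    unchanged, as are compartments whose minority cluster exceeds the
    retention threshold (default 40%) — splitting those would discard
    genuine tissue rather than misclassified specks.
    """
    U, inverse, w = _compress(pixels.rgb)
    keep_rows = _refine_rows(
        U, w, pixels.compartment, seed, retention_threshold, n_init, max_iter
    )
    if keep_rows is None:
        return pixels
    keep = keep_rows[inverse]
    return CompartmentPixels(
        compartment=pixels.compartment,
        coordinates=pixels.coordinates[keep],
        rgb=pixels.rgb[keep],
    )


def _refine_rows(U, w, compartment, seed, retention_threshold, n_init, max_iter, tol=0.0):
    """Stage-1 refinement on unique rows; returns a keep mask over U, or
    None when the compartment is left unchanged."""
    if len(U) < 2:
        logger.info("%s compartment is constant-color; refinement skipped", compartment)
        return None
    labels, _, _ = _kmeans_unique(U, w, 2, n_init, max_iter, seed, tol)
    counts = np.bincount(labels, weights=w.astype(np.float64), minlength=2)
    minority = int(counts.argmin())
    frac = counts[minority] / counts.sum()
    if frac > retention_threshold:
        return None
    logger.info(
        "%s refinement dropped %d of %d pixels (minority fraction %.3f)",
        compartment,
        int(counts[minority]),
        int(counts.sum()),
        frac,
    )
    return labels != minority


@dataclass
class SlideClustering:
    """Per-compartment, per-k clustering results for one slide."""

    results: dict  # (compartment, k) -> ClusterResult
    refined: dict  # compartment -> CompartmentPixels (after stage 1)
    flags: dict  # compartment -> status string ("ok", "absent", ...)
    slide_shape: tuple[int, int]


def _extract_compartment(
    image: np.ndarray, mask: np.ndarray, code: int, name: str
) -> CompartmentPixels:
    ys, xs = np.nonzero(mask == code)
    return CompartmentPixels(
        compartment=name,
        coordinates=np.column_stack([ys, xs]),
        rgb=image[ys, xs],
    )


def cluster_compartments(
    slide: SlideRecord | np.ndarray,
    mask: np.ndarray,
    k_values=DEFAULT_K_VALUES,
    seed: int = 0,
    n_init: int = KMEANS_N_INIT,
    max_iter: int = KMEANS_MAX_ITER,
    retention_threshold: float = RETENTION_THRESHOLD,
    tol: float = SLIDE_KMEANS_TOL,
) -> SlideClustering:
    """Refine then cluster the epithelial and stromal compartments.

    ``mask`` is a per-pixel label raster using the package's class codes
    (ground truth or the expanded class matrix).  Missing compartments are
    flagged, not fatal.
    """
    image = slide.image if isinstance(slide, SlideRecord) else np.asarray(slide)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    results: dict = {}
    refined: dict = {}
    flags: dict = {}
    for name, code in (("epithelium", EPITHELIUM), ("stroma", STROMA)):
        pix = _extract_compartment(image, mask, code, name)
        if len(pix) == 0:
            flags[name] = "absent"
            continue
        # Compress once; stage-1 refinement and every k reuse the same
        # unique-color table.
        U, inverse, w = _compress(pix.rgb)
        keep_rows = _refine_rows(
            U,
            w,
            name,
            int(substream(seed, "refine", name).integers(2**31)),
            retention_threshold,
            n_init,
            max_iter,
            tol,
        )
        if keep_rows is not None:
            keep = keep_rows[inverse]
            pix = CompartmentPixels(
                compartment=name,
                coordinates=pix.coordinates[keep],
                rgb=pix.rgb[keep],
            )
            U, w = U[keep_rows], w[keep_rows]
            remap = np.cumsum(keep_rows) - 1
            inverse = remap[inverse[keep]]
        refined[name] = pix
        flags[name] = "ok"
        for k in k_values:
            if len(U) < k:
                flags[name] = f"too-few-distinct-for-k>={k}"
                break
            labels, centroids, inertia = _kmeans_unique(
                U,
                w,
                k,
                n_init,
                max_iter,
                int(substream(seed, "kmeans", name, k).integers(2**31)),
                tol,
            )
            results[(name, k)] = ClusterResult(
                k=k,
                labels=labels[inverse],
                centroids=centroids,
                inertia=inertia,
                n_init=n_init,
                max_iter=max_iter,
                seed=seed,
            )
    return SlideClustering(
        results=results,
        refined=refined,
        flags=flags,
        slide_shape=mask.shape,
    )


def overlay_clusters(
    image: np.ndarray,
    pixels: CompartmentPixels,
    labels: np.ndarray,
    palette=OVERLAY_PALETTE,
) -> np.ndarray:
    """Render cluster labels over a grayscale version of the slide.

    Pixels outside the compartment show the grayscale H&E rendering;
    compartment pixels take their cluster's palette color.
    """
    labels = np.asarray(labels)
    if len(labels) != len(pixels):
        raise ValueError("labels must cover exactly the masked pixels")
    k = int(labels.max()) + 1 if len(labels) else 0
    if k > len(palette):
        raise ValueError(f"palette has {len(palette)} colors but {k} clusters")
    gray = (rgb2gray(image) * 255).astype(np.uint8)
    out = np.stack([gray] * 3, axis=-1)
    pal = np.asarray(palette, dtype=np.uint8)
    if len(labels):
        ys, xs = pixels.coordinates[:, 0], pixels.coordinates[:, 1]
        out[ys, xs] = pal[labels]
    return out
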