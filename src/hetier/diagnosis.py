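"""Inertia-based cancer detection from the clustered compartments.

Per patient, the within-cluster sum of squares (inertia) of the epithelial
and stromal K-means solutions is normalised by the image pixel area; slides
whose compartments yield too few pixels after refinement are excluded from
analysis.  A pair of thresholds — one per compartment — splits the
(epithelial, stromal) normalised-inertia plane into four quadrants: the
low-low quadrant is called normal-like and everything else cancer-like.
Sweeping both thresholds over the observed feature values traces out a 2D
receiver operating characteristic for malignant-vs-rest detection, whose
upper-left Pareto envelope and trapezoidal AUC summarise performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import SlideClustering
from .synthetic import SlideRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_K_FEATURE",
    "MIN_YIELD_FRACTION",
    "InertiaRecord",
    "RocCurve",
    "compute_inertia_features",
    "filter_sufficient",
    "quadrant_classify",
    "roc_2d",
    "single_feature_auc",
    "records_to_frame",
]

#: Which k's inertia feeds diagnosis (matches the 5-cluster overlays).
DEFAULT_K_FEATURE = 5

#: A compartment is sufficient when its refined pixel count is at least
#: this fraction of the slide's pixel area.
MIN_YIELD_FRACTION = 0.005


@dataclass
class InertiaRecord:
    """Per-patient inertia features, raw and area-normalised."""

    patient_id: str
    state: str
    epi_inertia: float
    str_inertia: float
    epi_norm: float
    str_norm: float
    epi_pixels: int
    str_pixels: int
    sufficient: bool


@dataclass
class RocCurve:
    """Pareto envelope of (FPR, TPR) operating points plus its AUC."""

    points: np.ndarray  # (m, 2) [fpr, tpr], sorted by fpr, starts (0,0) ends (1,1)
    auc: float
    positive_class: str = "malignant"


def compute_inertia_features(
    slide: SlideRecord,
    clustering: SlideClustering,
    k_feature: int = DEFAULT_K_FEATURE,
    min_yield_fraction: float = MIN_YIELD_FRACTION,
) -> InertiaRecord:
    """Extract the per-patient inertia feature pair for one slide.

    Normalised inertia divides the raw within-cluster sum of squares by the
    slide's total pixel count (height x width), making the feature
    comparable across image sizes.  A slide is sufficient only when both
    refined compartments contain at least ``min_yield_fraction`` of the
    slide's pixels and both clustering results exist.
    """
    H, W = clustering.slide_shape
    area = float(H * W)
    min_yield = min_yield_fraction * area

    vals = {}
    npix = {}
    for comp in ("epithelium", "stroma"):
        res = clustering.results.get((comp, k_feature))
        pix = clustering.refined.get(comp)
        npix[comp] = 0 if pix is None else len(pix)
        vals[comp] = np.nan if res is None else res.inertia

    sufficient = (
        npix["epithelium"] >= min_yield
        and npix["stroma"] >= min_yield
        and np.isfinite(vals["epithelium"])
        and np.isfinite(vals["stroma"])
    )
    epi = float(vals["epithelium"]) if np.isfinite(vals["epithelium"]) else np.nan
    stro = float(vals["stroma"]) if np.isfinite(vals["stroma"]) else np.nan
    return InertiaRecord(
        patient_id=slide.patient_id,
        state=slide.state,
        epi_inertia=epi,
        str_inertia=stro,
        epi_norm=epi / area,
        str_norm=stro / area,
        epi_pixels=int(npix["epithelium"]),
        str_pixels=int(npix["stroma"]),
        sufficient=bool(sufficient),
    )


def filter_sufficient(records: list[InertiaRecord]) -> list[InertiaRecord]:
    """Drop insufficient-yield patients; error if nothing remains."""
    kept = [r for r in records if r.sufficient]
    discarded = len(records) - len(kept)
    if discarded:
        logger.info(
            "discarded %d of %d patients for insufficient epithelial or "
            "stromal yield; %d analysed",
            discarded,
            len(records),
            len(kept),
        )
    if not kept:
        raise ValueError("all patient records were discarded; nothing to analyse")
    return kept


def quadrant_classify(
    records: list[InertiaRecord],
    t_epi: float,
    t_str: float,
) -> dict[str, str]:
    """Label each patient by the quadrant rule.

    The normal quadrant is low-low: ``epi_norm < t_epi and str_norm <
    t_str``; every other quadrant is cancer-like, and a feature exactly on
    its threshold falls on the cancer side.
    """
    if t_epi <= 0 or t_str <= 0:
        raise ValueError("thresholds must be > 0")
    out = {}
    for r in records:
        normal = (r.epi_norm < t_epi) and (r.str_norm < t_str)
        out[r.patient_id] = "normal-like" if normal else "cancer-like"
    return out


def _pareto_envelope(points: np.ndarray) -> np.ndarray:
    """Upper-left Pareto envelope of (fpr, tpr) operating points.

    For every distinct FPR keep the best TPR, enforce monotone TPR along
    increasing FPR (dominated points are interior to the hull of the
    achievable set), and anchor the curve at (0,0) and (1,1).
    """
    pts = np.vstack([points, [0.0, 0.0], [1.0, 1.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    fpr, tpr = pts[order, 0], pts[order, 1]
    uniq, starts = np.unique(fpr, return_index=True)
    last = np.r_[starts[1:], len(fpr)] - 1  # max tpr within each fpr group
    best = np.maximum.accumulate(tpr[last])
    env = np.column_stack([uniq, best])
    if env[0, 1] > 0.0:
        env = np.vstack([[0.0, 0.0], env])
    return env


def roc_2d(records: list[InertiaRecord], positive_class: str = "malignant") -> RocCurve:
    """Malignant-vs-rest ROC from the 2D threshold sweep.

    Threshold pairs (t_epi, t_str) range over the cross-product of each
    feature's observed values plus 0 and infinity sentinels; each pair
    yields one (FPR, TPR) point of the quadrant rule; the upper-left Pareto
    envelope of all points is kept and its AUC computed by the trapezoid
    rule.
    """
    e = np.array([r.epi_norm for r in records])
    s = np.array([r.str_norm for r in records])
    y = np.array([r.state == positive_class for r in records])
    if y.all() or not y.any():
        raise ValueError(
            f"need both {positive_class} and non-{positive_class} records"
        )
    te_grid = np.concatenate([[0.0], np.unique(e), [np.inf]])
    ts_grid = np.concatenate([[0.0], np.unique(s), [np.inf]])
    n_pos, n_neg = int(y.sum()), int((~y).sum())

    # A record is called cancer-like when e >= te or s >= ts, so the count
    # of calls at (te, ts) is n - #{e < te and s < ts}.  That joint count
    # over the whole grid is a 2-D cumulative histogram: O(n + |grid|)
    # instead of a triple loop.
    def _miss_counts(mask: np.ndarray) -> np.ndarray:
        ia = np.searchsorted(te_grid, e[mask], side="right")
        ib = np.searchsorted(ts_grid, s[mask], side="right")
        K = np.zeros((len(te_grid), len(ts_grid)))
        np.add.at(K, (ia, ib), 1.0)
        return K.cumsum(axis=0).cumsum(axis=1)

    tpr = (n_pos - _miss_counts(y)) / n_pos
    fpr = (n_neg - _miss_counts(~y)) / n_neg
    env = _pareto_envelope(
        np.column_stack([fpr.ravel(), tpr.ravel()])
    )
    auc = float(np.trapezoid(env[:, 1], env[:, 0]))
    return RocCurve(points=env, auc=auc, positive_class=positive_class)


def single_feature_auc(
    values: np.ndarray, is_positive: np.ndarray
) -> float:
    """Standard threshold-sweep AUC of a scalar score (higher = positive).

    Equivalent to the Mann-Whitney pairwise-concordance probability; used
    for the axis-degenerate comparisons against the 2D envelope.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(is_positive, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("need both positive and negative records")
    thresholds = np.concatenate([[-np.inf], np.unique(values), [np.inf]])
    fprs, tprs = [], []
    for t in thresholds:
        pred = values >= t
        tprs.append(np.sum(pred & y) / y.sum())
        fprs.append(np.sum(pred & ~y) / (~y).sum())
    fprs, tprs = np.asarray(fprs), np.asarray(tprs)
    order = np.lexsort((tprs, fprs))  # ties in FPR sorted by TPR
    return float(np.trapezoid(tprs[order], fprs[order]))


def records_to_frame(records: list[InertiaRecord]) -> pd.DataFrame:
    """Tabulate records (one row per patient) for CSV export."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "state": r.state,
                "epi_inertia": r.epi_inertia,
                "str_inertia": r.str_inertia,
                "epi_norm": r.epi_norm,
                "str_norm": r.str_norm,
                "epi_pixels": r.epi_pixels,
                "str_pixels": r.str_pixels,
                "sufficient": r.sufficient,
            }
            for r in records
        ]
    )
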