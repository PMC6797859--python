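"""End-to-end orchestration: tiles -> classifier -> clusters -> diagnosis.

``run_pipeline`` executes the full tiered analysis in order — training-tile
extraction, tile-classifier fitting, slide sweeping with majority-filter
smoothing, two-stage per-compartment K-means, inertia feature extraction,
and the quadrant-rule ROC — writing every intermediate as a plain-text or
PNG artifact under the configured output directory.  All randomness derives
from the single config seed through named substreams, so a run is fully
deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from ._rng import substream
from .clustering import SlideClustering, cluster_compartments, overlay_clusters
from .config import PipelineConfig
from .diagnosis import (
    InertiaRecord,
    RocCurve,
    compute_inertia_features,
    filter_sufficient,
    records_to_frame,
    roc_2d,
)
from .segmentation import (
    TileClassifier,
    classify_slide,
    majority_filter,
    matrix_to_mask,
    train_classifier,
)
from .synthetic import (
    STATES,
    SlideRecord,
    SlideSpec,
    generate_annotations,
    generate_cohort,
    generate_slide,
)
from .tiling import Contour, Tile, filter_and_resize, sample_tiles, split_by_patient

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "build_training_tiles", "make_figures"]


@dataclass
class PipelineResult:
    """In-memory handles to everything a pipeline run produced."""

    config: PipelineConfig
    classifier: TileClassifier
    classifier_metrics: dict
    cohort_table: pd.DataFrame
    records: list  # all InertiaRecords (pre-filter)
    analysed: list  # sufficient InertiaRecords
    roc: RocCurve | None
    clusterings: dict  # patient_id -> SlideClustering
    output_dir: Path


def _stage(name: str):
    logger.info("stage: %s", name)


def build_training_tiles(
    slides: list[SlideRecord],
    contours: list[Contour],
    train_ids,
    val_ids,
    seed: int = 0,
):
    """Sample, filter and resize tiles from contours; split by patient."""
    image_by_pid = {s.patient_id: s.image for s in slides}
    tiles: list[Tile] = []
    for i, c in enumerate(contours):
        img = image_by_pid.get(c.patient_id)
        if img is None:
            logger.warning("contour %d references unknown patient %s", i, c.patient_id)
            continue
        tile_seed = int(substream(seed, "contour", i).integers(2**31))
        tiles.extend(sample_tiles(c, img, seed=tile_seed))
    tiles = filter_and_resize(tiles)
    return split_by_patient(tiles, train_ids, val_ids)


def _analyse_slide(
    record: SlideRecord,
    clf: TileClassifier,
    cfg: PipelineConfig,
) -> tuple[SlideClustering, "np.ndarray", "np.ndarray"]:
    matrix = classify_slide(record.image, clf)
    matrix = majority_filter(matrix)
    mask = matrix_to_mask(matrix)
    clustering = cluster_compartments(
        record,
        mask,
        k_values=cfg.clustering.k_values,
        seed=int(substream(cfg.seed, "cluster", record.patient_id).integers(2**31)),
        n_init=cfg.clustering.n_init,
        max_iter=cfg.clustering.max_iter,
        retention_threshold=cfg.clustering.retention_threshold,
        tol=cfg.clustering.tol,
    )
    return clustering, matrix, mask


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full tiered analysis and write all artifacts.

    In synthetic mode a patient-disjoint training cohort (6 training + 5
    validation patients by default) is generated and annotated from ground
    truth; the analysis cohort is generated separately.  With synthetic
    mode off, slides and annotations are read from ``slides_dir`` (a cohort
    CSV plus PNGs as written by :func:`hetier.io.save_cohort`) and
    ``annotations_path`` (GeoJSON).
    """
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in ("cohort", "matrices", "masks", "overlays", "figures"):
        (out / sub).mkdir(exist_ok=True)

    # -- stage 1: training data -------------------------------------------
    _stage("training data")
    if cfg.synthetic.enabled:
        n_train = cfg.synthetic.n_train_patients
        n_val = cfg.synthetic.n_val_patients
        seeds = substream(cfg.seed, "train-slide-seeds").integers(
            0, 2**31 - 1, size=n_train + n_val
        )
        train_slides = []
        for i in range(n_train + n_val):
            spec = SlideSpec(state=STATES[i % len(STATES)], seed=int(seeds[i]))
            train_slides.append(generate_slide(spec, patient_id=f"T{i + 1:04d}"))
        contours = []
        for i, slide in enumerate(train_slides):
            contours.extend(
                generate_annotations(
                    slide,
                    n_contours=cfg.synthetic.n_contours_per_slide,
                    area_bounds_px=tuple(cfg.synthetic.annotation_area_bounds),
                    seed=int(substream(cfg.seed, "annot", i).integers(2**31)),
                )
            )
        train_ids = [s.patient_id for s in train_slides[:n_train]]
        val_ids = [s.patient_id for s in train_slides[n_train:]]
    else:
        if not cfg.slides_dir or not cfg.annotations_path:
            raise ValueError(
                "non-synthetic mode needs slides_dir and annotations_path"
            )
        train_slides, _ = _load_cohort(cfg.slides_dir)
        contours = hio.load_contours(cfg.annotations_path)
        pids = sorted({c.patient_id for c in contours})
        n_train = cfg.synthetic.n_train_patients
        train_ids, val_ids = pids[:n_train], pids[n_train:]
    hio.save_contours(contours, out / "annotations.geojson")

    # -- stage 2: tiles ----------------------------------------------------
    _stage("tiling")
    train_ds, val_ds = build_training_tiles(
        train_slides, contours, train_ids, val_ids, seed=cfg.seed
    )
    _write_tile_manifest(train_ds, val_ds, out / "tile_manifest.csv")
    logger.info(
        "tiles: %d train / %d validation (%s / %s)",
        len(train_ds),
        len(val_ds),
        train_ds.class_counts(),
        val_ds.class_counts(),
    )

    # -- stage 3: classifier ----------------------------------------------
    _stage("classifier training")
    clf_cfg = replace(cfg.classifier, seed=cfg.seed)
    clf, metrics = train_classifier(train_ds, val_ds, clf_cfg)
    (out / "classifier_metrics.json").write_text(json.dumps(metrics, indent=1))

    # -- stage 4: analysis cohort -----------------------------------------
    _stage("analysis cohort")
    if cfg.synthetic.enabled:
        records_slides, cohort_table = generate_cohort(
            cfg.synthetic.n_per_state,
            seed=int(substream(cfg.seed, "analysis-cohort").integers(2**31)),
        )
    else:
        records_slides, cohort_table = _load_cohort(cfg.slides_dir)
    hio.save_cohort(records_slides, cohort_table, out / "cohort")

    # -- stage 5: classify + cluster + features ---------------------------
    _stage("slide analysis")
    cluster_rows = []
    inertia_records: list[InertiaRecord] = []
    clusterings: dict[str, SlideClustering] = {}
    per_k_records: dict[int, list[InertiaRecord]] = {
        k: [] for k in cfg.clustering.k_values
    }
    for slide in records_slides:
        try:
            clustering, matrix, mask = _analyse_slide(slide, clf, cfg)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'slide analysis' failed on slide {slide.patient_id}: {exc}"
            ) from exc
        clusterings[slide.patient_id] = clustering
        hio.class_matrix_to_csv(matrix, out / "matrices" / f"{slide.patient_id}_matrix.csv")
        hio.save_mask_png(mask, out / "masks" / f"{slide.patient_id}_pred_mask.png")
        for (comp, k), res in sorted(clustering.results.items()):
            row = {
                "patient_id": slide.patient_id,
                "compartment": comp,
                "k": k,
                "inertia": res.inertia,
            }
            for j, c in enumerate(res.centroids):
                row[f"centroid{j}"] = "|".join(f"{v:.3f}" for v in c)
            cluster_rows.append(row)
        k_max = max(cfg.clustering.k_values)
        for comp in ("epithelium", "stroma"):
            res = clustering.results.get((comp, k_max))
            pix = clustering.refined.get(comp)
            if res is not None and pix is not None:
                overlay = overlay_clusters(slide.image, pix, res.labels)
                hio.save_image_png(
                    overlay,
                    out / "overlays" / f"slide_{slide.patient_id}_{comp}_k{k_max}.png",
                )
        rec = compute_inertia_features(
            slide,
            clustering,
            k_feature=cfg.diagnosis.k_feature,
            min_yield_fraction=cfg.diagnosis.min_yield_fraction,
        )
        inertia_records.append(rec)
        for k in cfg.clustering.k_values:
            per_k_records[k].append(
                compute_inertia_features(
                    slide,
                    clustering,
                    k_feature=k,
                    min_yield_fraction=cfg.diagnosis.min_yield_fraction,
                )
            )
    pd.DataFrame(cluster_rows).to_csv(out / "clusters.csv", index=False, float_format="%.10g")

    feat = records_to_frame(inertia_records)
    for k in cfg.clustering.k_values:
        fk = records_to_frame(per_k_records[k])
        feat[f"epi_norm_k{k}"] = fk["epi_norm"]
        feat[f"str_norm_k{k}"] = fk["str_norm"]
    feat.to_csv(out / "features.csv", index=False, float_format="%.10g")

    # -- stage 6: diagnosis ------------------------------------------------
    _stage("diagnosis")
    analysed = filter_sufficient(inertia_records)
    states = {r.state for r in analysed}
    roc = None
    if "malignant" in states and states - {"malignant"}:
        roc = roc_2d(analysed)
        hio.roc_to_csv(roc, out / "roc.csv")
        logger.info("malignant-vs-rest AUC %.4f on %d patients", roc.auc, len(analysed))
    else:
        logger.warning("ROC skipped: need malignant and non-malignant sufficient cases")

    hio.export_report(
        {"records": inertia_records, "roc": roc, "classifier_metrics": metrics},
        out / "report.md",
    )
    make_figures(analysed, roc, out / "figures")
    cfg.to_yaml(out / "config.yaml")

    return PipelineResult(
        config=cfg,
        classifier=clf,
        classifier_metrics=metrics,
        cohort_table=cohort_table,
        records=inertia_records,
        analysed=analysed,
        roc=roc,
        clusterings=clusterings,
        output_dir=out,
    )


def _write_tile_manifest(train_ds, val_ds, path) -> None:
    rows = []
    for ds in (train_ds, val_ds):
        for i, t in enumerate(ds.tiles):
            rows.append(
                {
                    "tile_id": f"{ds.split}-{i:05d}",
                    "patient_id": t.patient_id,
                    "class_label": t.class_label,
                    "origin_x": t.origin[0],
                    "origin_y": t.origin[1],
                    "side_px": t.side_px,
                    "background_fraction": t.background_fraction,
                    "split": ds.split,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def _load_cohort(slides_dir) -> tuple[list[SlideRecord], pd.DataFrame]:
    slides_dir = Path(slides_dir)
    table = pd.read_csv(slides_dir / "cohort.csv")
    records = []
    for _, row in table.iterrows():
        records.append(
            SlideRecord(
                image=hio.load_image(slides_dir / row["image_path"]),
                truth_mask=hio.load_mask_png(slides_dir / row["mask_path"]),
                patient_id=str(row["patient_id"]),
                state=str(row["state"]),
            )
        )
    return records, table


def make_figures(analysed: list, roc: RocCurve | None, fig_dir) -> None:
    """Box plots of normalised inertia by state, the 2D scatter, and the ROC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = Path(fig_dir)
    fig_dir.mkdir(parents=True, exist_ok=True)
    if not analysed:
        return
    df = records_to_frame(analysed)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    for ax, col, title in zip(axes, ("epi_norm", "str_norm"), ("Epithelium", "Stroma")):
        data = [df.loc[df["state"] == s, col] for s in STATES if (df["state"] == s).any()]
        labels = [s for s in STATES if (df["state"] == s).any()]
        ax.boxplot(data, tick_labels=labels)
        ax.set_title(title)
        ax.set_ylabel("normalised inertia")
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(fig_dir / "inertia_boxplots.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4.5))
    for s in STATES:
        sel = df["state"] == s
        if sel.any():
            ax.scatter(df.loc[sel, "epi_norm"], df.loc[sel, "str_norm"], label=s, s=18)
    ax.set_xlabel("epithelial normalised inertia")
    ax.set_ylabel("stromal normalised inertia")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(fig_dir / "inertia_scatter.png", dpi=120)
    plt.close(fig)

    if roc is not None:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(roc.points[:, 0], roc.points[:, 1], marker="o", ms=3)
        ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"malignant vs rest (AUC = {roc.auc:.3f})")
        fig.tight_layout()
        fig.savefig(fig_dir / "roc.png", dpi=120)
        plt.close(fig)
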