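"""File formats: GeoJSON contours, PNG slides/masks, CSV tables, reports.

Truth and predicted masks are written as single-channel palette PNGs with a
fixed integer palette (0 epithelium, 1 stroma, 2 others, 3 background /
excluded); contours travel as a GeoJSON FeatureCollection of polygons in
pixel units with ``class_label`` and ``patient_id`` properties.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .diagnosis import RocCurve, records_to_frame
from .segmentation import ClassMatrix
from .synthetic import CLASS_NAMES, SlideRecord
from .tiling import Contour

__all__ = [
    "MASK_PALETTE",
    "save_image_png",
    "load_image",
    "save_mask_png",
    "load_mask_png",
    "contours_to_geojson",
    "geojson_to_contours",
    "save_contours",
    "load_contours",
    "save_cohort",
    "class_matrix_to_csv",
    "roc_to_csv",
    "export_report",
]

#: Display palette for mask PNGs, indexed by class code (code 3 doubles as
#: background in truth masks and excluded in predicted masks).
MASK_PALETTE = {
    0: (128, 0, 128),  # epithelium: purple
    1: (255, 182, 193),  # stroma: pink
    2: (139, 90, 43),  # others: brown
    3: (240, 240, 240),  # background / excluded: light gray
}


def save_image_png(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_mask_png(mask: np.ndarray, path) -> None:
    img = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="P")
    palette = []
    for code in range(256):
        palette.extend(MASK_PALETTE.get(code, (0, 0, 0)))
    img.putpalette(palette)
    img.save(path)


def load_mask_png(path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "P":
        img = img.convert("P")
    return np.asarray(img, dtype=np.uint8)


# -- contours ----------------------------------------------------------------


def contours_to_geojson(contours: list[Contour]) -> dict:
    """Serialise contours to a GeoJSON FeatureCollection (pixel coords)."""
    features = []
    for c in contours:
        ring = [[float(x), float(y)] for x, y in c.polygon]
        if ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "class_label": c.class_label,
                    "patient_id": c.patient_id,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def geojson_to_contours(obj: dict) -> list[Contour]:
    """Parse a GeoJSON FeatureCollection into contours, with validation."""
    if obj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    out = []
    for i, feat in enumerate(obj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValueError(f"feature {i}: geometry must be a Polygon")
        props = feat.get("properties") or {}
        if "class_label" not in props:
            raise ValueError(f"feature {i}: missing property 'class_label'")
        ring = geom.get("coordinates", [[]])[0]
        if len(ring) >= 2 and ring[0] == ring[-1]:
            ring = ring[:-1]
        out.append(
            Contour(
                polygon=[(float(x), float(y)) for x, y in ring],
                class_label=str(props["class_label"]),
                patient_id=str(props.get("patient_id", "")),
            )
        )
    return out


def save_contours(contours: list[Contour], path) -> None:
    Path(path).write_text(json.dumps(contours_to_geojson(contours), indent=1))


def load_contours(path) -> list[Contour]:
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed GeoJSON at line {exc.lineno}: {exc.msg}") from exc
    return geojson_to_contours(obj)


# -- cohorts and result tables ----------------------------------------------


def save_cohort(
    records: list[SlideRecord], table: pd.DataFrame, out_dir
) -> pd.DataFrame:
    """Write slide + mask PNGs and the cohort CSV; returns the table with paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = table.copy()
    image_paths, mask_paths = [], []
    for rec in records:
        ipath = out_dir / f"{rec.patient_id}_he.png"
        mpath = out_dir / f"{rec.patient_id}_mask.png"
        save_image_png(rec.image, ipath)
        save_mask_png(rec.truth_mask, mpath)
        image_paths.append(ipath.name)
        mask_paths.append(mpath.name)
    table["image_path"] = image_paths
    table["mask_path"] = mask_paths
    table.to_csv(out_dir / "cohort.csv", index=False)
    return table


def class_matrix_to_csv(matrix: ClassMatrix, path) -> None:
    names = list(CLASS_NAMES[:3]) + ["excluded"]
    grid = np.vectorize(lambda c: names[c])(matrix.labels)
    pd.DataFrame(grid).to_csv(path, index=False, header=False)


def roc_to_csv(curve: RocCurve, path) -> None:
    df = pd.DataFrame(curve.points, columns=["fpr", "tpr"])
    df["auc"] = curve.auc
    df.to_csv(path, index=False, float_format="%.10g")


def export_report(outputs: dict, path=None) -> str:
    """Summarise a pipeline run as markdown.

    ``outputs`` carries ``records`` (all InertiaRecords, pre-filter),
    optional ``roc`` (RocCurve) and optional ``classifier_metrics``.
    The report tabulates per-state mean/median normalised inertia over the
    analysed patients, states the exclusion count, and repeats the AUC.
    """
    records = outputs["records"]
    df = records_to_frame(records)
    kept = df[df["sufficient"]]
    discarded = int((~df["sufficient"]).sum())

    lines = ["# Pipeline report", ""]
    lines.append(f"Patients: {len(df)} total, {discarded} discarded "
                 f"(insufficient epithelial or stromal yield), {len(kept)} analysed.")
    lines.append("")
    lines.append("## Normalised inertia by disease state")
    lines.append("")
    lines.append("| state | n | epi mean | epi median | str mean | str median |")
    lines.append("|---|---|---|---|---|---|")
    for state, grp in kept.groupby("state", sort=False):
        lines.append(
            f"| {state} | {len(grp)} | {grp['epi_norm'].mean():.4f} | "
            f"{grp['epi_norm'].median():.4f} | {grp['str_norm'].mean():.4f} | "
            f"{grp['str_norm'].median():.4f} |"
        )
    lines.append("")
    roc = outputs.get("roc")
    if roc is not None:
        lines.append(f"Malignant-vs-rest 2D-threshold ROC AUC: {roc.auc:.4f}")
        lines.append("")
    cm = outputs.get("classifier_metrics")
    if cm is not None:
        lines.append(
            f"Tile classifier validation accuracy {cm['accuracy']:.4f}, "
            f"macro F1 {cm['macro_f1']:.4f} (n={cm['n']})."
        )
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
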