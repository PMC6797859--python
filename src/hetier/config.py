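"""Pipeline configuration: a single YAML-serialisable object.

Every constant of the method lives here as a default rather than being
hard-coded at a call site: tile sides 48-256 with the 152 px reference and
the 100-tile cap, the 30% background limit, the classifier's 12 trainable
end layers / 1024 dense units / dropout 0.2 / Adam lr 1e-7 / batch 32, the
K-means 300 iterations x 10 restarts over k = 2..5, and the diagnosis
defaults (k = 5 feature, 0.5% minimum compartment yield).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .clustering import (
    DEFAULT_K_VALUES,
    KMEANS_MAX_ITER,
    KMEANS_N_INIT,
    RETENTION_THRESHOLD,
    SLIDE_KMEANS_TOL,
)
from .diagnosis import DEFAULT_K_FEATURE, MIN_YIELD_FRACTION
from .segmentation import ClassifierConfig
from .tiling import (
    BACKGROUND_MAX_FRACTION,
    BACKGROUND_WHITE_THRESHOLD,
    TILE_CAP,
    TILE_MAX_SIDE,
    TILE_MIN_SIDE,
)

__all__ = [
    "TilingParams",
    "ClusteringParams",
    "DiagnosisParams",
    "SyntheticParams",
    "PipelineConfig",
]


@dataclass
class TilingParams:
    min_side: int = TILE_MIN_SIDE
    max_side: int = TILE_MAX_SIDE
    tile_cap: int = TILE_CAP
    background_threshold: int = BACKGROUND_WHITE_THRESHOLD
    background_max_fraction: float = BACKGROUND_MAX_FRACTION


@dataclass
class ClusteringParams:
    n_init: int = KMEANS_N_INIT
    max_iter: int = KMEANS_MAX_ITER
    k_values: tuple = DEFAULT_K_VALUES
    retention_threshold: float = RETENTION_THRESHOLD
    tol: float = SLIDE_KMEANS_TOL


@dataclass
class DiagnosisParams:
    k_feature: int = DEFAULT_K_FEATURE
    min_yield_fraction: float = MIN_YIELD_FRACTION
    t_epi: float | None = None  # optional fixed quadrant thresholds
    t_str: float | None = None


@dataclass
class SyntheticParams:
    enabled: bool = True
    n_per_state: int = 1
    n_train_patients: int = 6
    n_val_patients: int = 5
    n_contours_per_slide: int = 20
    annotation_area_bounds: tuple = (3600.0, 16384.0)


@dataclass
class PipelineConfig:
    seed: int = 0
    slides_dir: str | None = None
    annotations_path: str | None = None
    output_dir: str = "hetier_output"
    tiling: TilingParams = field(default_factory=TilingParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    diagnosis: DiagnosisParams = field(default_factory=DiagnosisParams)
    synthetic: SyntheticParams = field(default_factory=SyntheticParams)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "tiling": TilingParams,
            "classifier": ClassifierConfig,
            "clustering": ClusteringParams,
            "diagnosis": DiagnosisParams,
            "synthetic": SyntheticParams,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sub and isinstance(val, dict):
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        cfg = cls(**kwargs)
        # YAML has no tuple type; normalise list-valued fields back.
        cfg.clustering.k_values = tuple(cfg.clustering.k_values)
        cfg.synthetic.annotation_area_bounds = tuple(
            cfg.synthetic.annotation_area_bounds
        )
        return cfg

    def to_yaml(self, path=None) -> str:
        d = self.to_dict()
        d["clustering"]["k_values"] = list(d["clustering"]["k_values"])
        d["synthetic"]["annotation_area_bounds"] = list(
            d["synthetic"]["annotation_area_bounds"]
        )
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))
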