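"""Shared fixtures: small synthetic slides and a cached pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from hetier import PipelineConfig, SlideSpec, generate_slide, run_pipeline
from hetier._rng import substream
from hetier.pipeline import build_training_tiles
from hetier.synthetic import STATES, generate_annotations


@pytest.fixture(scope="session")
def normal_slide():
    return generate_slide(SlideSpec(state="normal", seed=101), patient_id="FIX1")


@pytest.fixture(scope="session")
def malignant_slide():
    return generate_slide(SlideSpec(state="malignant", seed=202), patient_id="FIX2")


def make_training_cohort(seed, n_slides=11, n_contours=20, n_train=6, **spec_kw):
    """Generate a patient-disjoint annotated training cohort.

    Returns (slides, contours, train_ids, val_ids); states cycle through
    the four disease states so every compartment appearance is seen.
    """
    seeds = substream(seed, "train-slide-seeds").integers(0, 2**31 - 1, size=n_slides)
    slides, contours = [], []
    for i in range(n_slides):
        spec = SlideSpec(state=STATES[i % len(STATES)], seed=int(seeds[i]), **spec_kw)
        rec = generate_slide(spec, patient_id=f"T{i + 1:04d}")
        slides.append(rec)
        contours.extend(
            generate_annotations(
                rec, n_contours, seed=int(substream(seed, "annot", i).integers(2**31))
            )
        )
    ids = [s.patient_id for s in slides]
    return slides, contours, ids[:n_train], ids[n_train:]


@pytest.fixture(scope="session")
def trained_baseline():
    """A color-baseline classifier fitted on a small synthetic cohort."""
    from hetier import train_classifier

    slides, contours, train_ids, val_ids = make_training_cohort(7)
    train, val = build_training_tiles(slides, contours, train_ids, val_ids, seed=7)
    clf, metrics = train_classifier(train, val)
    return clf, metrics, val


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full 4-slide synthetic pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline_a")
    cfg = PipelineConfig(seed=11, output_dir=str(out))
    cfg.synthetic.n_per_state = 1
    result = run_pipeline(cfg)
    return result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
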