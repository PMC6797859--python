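# hetier — tiered H&E image analysis with inertia-based cancer detection

`hetier` is a Python package for quantitative analysis of hematoxylin &
eosin (H&E) stained breast-tissue images, aimed at computational
pathology researchers who want interpretable digital markers rather than
end-to-end black-box predictions.  It implements a three-tier pipeline:

1. **Compartment segmentation.**  A tile classifier labels 48 × 48 px
   tiles as *epithelium*, *stroma* or *others* (necrosis, secretions,
   blood), producing a per-slide class matrix that is denoised with a
   majority filter.  Training tiles are minted from single-class contour
   annotations: random sides in [48, 256] px, random positions inside the
   polygon, a per-contour budget of `min(100, max(1, ⌊2A/152²⌋))` tiles,
   a >30%-background filter, and a bilinear resize to 48 × 48.
2. **Two-stage K-means.**  Within each detected compartment, a K = 2
   clustering first drops the minority colour mode (misclassified
   specks); the refined pixels are then clustered for k = 2…5 (Lloyd's
   algorithm, 10 random restarts × up to 300 iterations, best solution
   kept).
3. **Inertia diagnosis.**  The within-cluster sum of squares
   ("inertia") of the epithelial and stromal solutions, divided by image
   area, gives each patient a 2-D feature
   `(I_epi / A, I_str / A)`.  One threshold per axis splits the plane
   into quadrants — low-low is called normal-like, everything else
   cancer-like — and sweeping both thresholds traces a 2-D ROC whose
   Pareto envelope and trapezoidal AUC quantify malignant-vs-rest
   detection.

Because the tissue-microarray data behind the method are not publicly
deposited, the package includes a seeded synthetic histology generator
(`hetier.synthetic`): H&E-like cores with ground-truth masks whose
within-compartment colour dispersion increases with disease state
(normal → hyperplasia → dysplasia → malignant), so every stage is
testable at desk scale.  See `docs/methods.md` for model details,
defaults and limitations.

## Worked example

Run the full pipeline on a synthetic cohort (2 patients per disease
state) from Python:

```python
from hetier import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=11, output_dir="demo_run")
cfg.synthetic.n_per_state = 2
result = run_pipeline(cfg)
print(f"classifier val accuracy: {result.classifier_metrics['accuracy']:.3f}")
for r in result.analysed:
    print(f"{r.patient_id}  {r.state:<12} epi={r.epi_norm:8.2f}  str={r.str_norm:8.2f}")
print(f"malignant-vs-rest AUC: {result.roc.auc:.3f}")
```

which prints (numbers from this exact seed):

```
classifier val accuracy: 1.000
P0001  normal       epi=   19.77  str=   54.63
P0002  normal       epi=   49.73  str=   25.79
P0003  hyperplasia  epi=   83.48  str=  216.21
P0004  hyperplasia  epi=  120.49  str=   47.90
P0005  dysplasia    epi=  118.11  str=  155.65
P0006  dysplasia    epi=  201.80  str=   40.36
P0007  malignant    epi=  276.38  str=  260.52
P0008  malignant    epi=   66.61  str=  344.63
malignant-vs-rest AUC: 1.000
```

Read: normalised inertia (colour dispersion per pixel of slide area)
tracks disease state — normals sit low on both axes, malignants high on
at least one — and the quadrant rule's 2-D sweep separates malignant
from the rest perfectly in this small cohort.  Individual slides
scatter: P0008's epithelial feature is modest because its *predicted*
epithelial mask (this is the full classifier path, not ground truth) is
small, while its stromal feature is the cohort's highest; using both
compartments is exactly what rescues such cases.  The run directory contains the cohort PNGs,
the class-matrix CSVs and predicted masks, 5-cluster overlay images, the
per-k cluster inertia table, `features.csv`, `roc.csv`, figures, and a
markdown report.

The same pipeline is scriptable from the shell:

```bash
hetier synth --seed 3 --out cohort --n-per-state 2      # slides + GeoJSON annotations
hetier run   --seed 11 --out demo_run --n-per-state 2   # end to end
hetier roc   --features demo_run/features.csv --out demo_roc
```

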