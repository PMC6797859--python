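# Methods

`hetier` implements a tiered analysis of hematoxylin-and-eosin (H&E)
histology images: (1) a tile classifier separates each slide into
epithelium, stroma and an "others" class (necrosis, secretions, blood);
(2) the RGB pixels of each detected compartment are clustered with
K-means; (3) the within-cluster sum of squares (inertia) of each
compartment, normalised by image area, is used as an interpretable
two-dimensional feature for separating malignant from non-malignant
patients via a quadrant decision rule and its associated ROC curve.

## 1. Tile datasets from contour annotations

Training data come from pathologist-style contour annotations, each
specific to one class.  From every contour, square tiles are cropped at
uniform-random integer side lengths in [48, 256] px and uniform-random
positions whose four corners and centre all lie inside the polygon
(rejection sampling, 50 attempts per tile; a contour that cannot host a
48 px square yields nothing).  The per-contour tile budget is

    n_tiles = min(100, max(1, floor(2 * A / 152^2)))

where `A` is the contour area in px² and 152 is the midpoint of the side
range; the doubling deliberately over-covers the contour with overlapping
crops.  The published description of this budget carries no rounding or
minimum rule; flooring with a minimum of one tile per positive-area
contour was chosen so no annotation is discarded outright.

A tile is background-filtered when **more than 30%** of its pixels are
near-white (all three channels ≥ 220; exactly 30% is kept).  "Background"
is never defined precisely in the source description; all-channels-≥-220
is the usual H&E convention for unstained glass.  Survivors are resized
to 48 × 48 with bilinear interpolation.  Train/validation/test splits are
patient-disjoint; tiles from unlisted patients are dropped and counted.

## 2. Tile classifier

Two backbones honour one contract (3-class softmax over fixed class
order, rows summing to 1):

* `vgg19_transfer` — pretrained VGG19 base with only the last 12 layers
  trainable, flatten → dense(1024, ReLU) → dropout(0.2) → softmax(3);
  Adam, learning rate 1e-7, no decay, batch 32, 48 × 48 input (the
  smallest input the pretrained base accepts, keeping the slide-level
  class matrix finely rasterised).  Alternative backbones (ResNet50 and
  InceptionResNetV2 at 197 × 197) are recorded as configuration constants
  only.  This path requires a Keras backend at run time and raises a
  clear error otherwise.
* `color_baseline` — 34 per-tile colour/texture summary features (per
  channel mean, std and 8-bin histogram; grayscale mean/std; mean
  absolute horizontal/vertical gradient) and a multinomial logistic
  regression.  It is deterministic, fits in seconds on one CPU, and is
  the backend the test suite exercises.  On the synthetic data the two
  tasks it must pass are (a) ≥95% validation accuracy when class mean
  colours are ≥40 apart in some channel at noise σ = 10, and (b)
  chance-level (1/3) accuracy on a class-balanced tile set when class
  colours are identical — i.e. it can only succeed through colour, which
  is exactly the signal the synthetic slides encode.

Slide inference sweeps a non-overlapping 48 px grid (stride = tile side;
"one matrix position per tile"), producing a class matrix.  Tiles whose
background fraction exceeds 30% are labelled `excluded` rather than
classified — the training-side filter has no stated inference-side
counterpart, so the same rule is applied symmetrically.  A single-pass
3 × 3 majority filter then replaces each cell by the modal label of its
*neighbours* — the cell's own label does not vote, which guarantees that
an isolated single-cell island is always absorbed, the filter's stated
purpose.  Excluded cells neither vote nor change, a cell with no voting
neighbours keeps its label, borders use the truncated window, and on
ties the original label is kept when it is among the tied winners
(e.g. a 4-vs-4 neighbour split involving the cell's own class),
otherwise the lowest class code wins for determinism.
The window size is a default (none is given in the source description)
and is configurable.

## 3. Two-stage K-means and inertia

Pixel-level clustering operates on raw RGB values promoted to float — no
colour-space transform.  Stage 1 applies K = 2 clustering to each
detected compartment and drops the minority cluster, removing small
colour modes contributed by misclassified tiles; if the minority exceeds
40% of pixels the compartment is returned unchanged, so a genuinely
bimodal compartment is never halved (which cluster to keep, and the
guard, are package choices; the source only states that a K = 2 pass
filters misclassified regions).  Stage 2 runs K-means for k = 2…5 with
10 random restarts and up to 300 iterations each, keeping the
minimum-inertia solution.

Numerical design of the K-means core:

* pixels are first collapsed to (unique colour, multiplicity) pairs — an
  exact reformulation that speeds up low-noise slides;
* initial centroids are a uniform random choice of k distinct observed
  pixel values; restart r of a run seeded s draws from the
  (s, "restart", r) substream, so restart streams are nested prefixes and
  best-of-n restarts inertia is non-increasing in n by construction;
* each restart's Lloyd iteration runs through scikit-learn's `KMeans`
  with `n_init=1` and the supplied initial centroids (empty clusters are
  relocated to far points);
* `kmeans_rgb` defaults to strict convergence (`tol=0`: iterate until the
  assignment is a fixpoint, equivalent to running the full 300
  iterations); slide-scale clustering (`cluster_compartments`, the
  pipeline) uses the standard relative centroid-shift tolerance 1e-4
  instead, which changes slide inertia by ≲ 5e-4 relative and halves
  runtime;
* final centroids and inertia are recomputed as exact float64 cluster
  means, so the within/between variance decomposition
  `total SSQ = inertia + Σ n_j‖c_j − c̄‖²` holds to machine precision.

Five-cluster results are rendered as overlays: the slide in grayscale
with compartment pixels replaced by a 5-colour palette.

## 4. Diagnosis

For each patient the feature pair is the epithelial and stromal inertia
at k = 5 (matching the 5-cluster overlays; the exact k behind the
published plots is not stated, so all four k are exported and the choice
is configurable), divided by the **total image pixel area**.  A patient
is excluded as insufficient-yield when either refined compartment holds
fewer than 0.5% of the slide's pixels — the source reports 8 of 100
patients excluded without a numeric criterion, so the threshold is a
documented default.

The quadrant rule calls a patient normal-like iff both normalised
inertias fall strictly below their thresholds (low-low), cancer-like
otherwise, with equality on the cancer side.  Published descriptions of
this rule number the normal quadrant without defining the axes; since
mean inertia is lowest for normals on both axes, low-low is the only
consistent reading and the quadrant number is treated as a plotting
convention.

The ROC sweeps threshold pairs over the cross-product of each feature's
observed values plus 0/∞ sentinels (so (0,0) and (1,1) are attainable),
computes (FPR, TPR) of the quadrant rule for every pair via a 2-D
cumulative histogram, keeps the upper-left Pareto envelope, and reports
the trapezoidal AUC.  Malignant is the positive class; normal,
hyperplasia and dysplasia form the rest.  Two properties are worth
remembering when reading the numbers:

* the envelope dominates both single-feature ROCs by construction;
* because the envelope maximises over threshold pairs in-sample, its AUC
  is optimistically biased under the null: with permuted labels the mean
  envelope AUC is ≈ 0.58 at 40 records and ≈ 0.53 at 200 records rather
  than exactly 0.5.  Null references should therefore be quoted at a
  stated record count (the test suite and the acceptance script use 200).

## 5. Synthetic histology generator

No public imaging data accompany the method, so the package ships a
seeded generator whose slides emulate a 1 mm tissue-microarray core at a
documented 250 px/mm scale convention (256 × 256 px canvas by default): a
white background, a circular stroma core with a low-frequency eosin-like
brightness texture (Gaussian-filtered noise, scale 12 px, amplitude 5),
3 elliptical hematoxylin-purple epithelial nests (radii 40–52 px), and
1–2 brownish "others" blobs placed in intact stroma.  Default class mean
colours are pairwise ≥ 40 apart in at least one channel; per-pixel
i.i.d. Gaussian colour noise (σ = 10 for tissue classes, 2 for
background) is scaled by a strictly increasing disease-state multiplier —
1.0 (normal), 1.5 (hyperplasia), 2.0 (dysplasia), 3.0 (malignant).  The
multipliers are a modelling choice: the source never quantifies
within-class colour dispersion on real slides, only that inertia rises
with disease state; since expected inertia scales with the squared
multiplier, the chosen spacing spreads state means over a nine-fold range
(1 : 2.25 : 4 : 9), comfortably separating them at 10 slides per state.  Geometry and
noise use split RNG streams so label geometry can be held fixed while
colours are re-rolled.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: stain variability and scanner
artefacts, nuclear morphology and texture at cellular scale, spatially
structured disease heterogeneity (state enters only through colour
dispersion), annotation error, and class imbalance.  Results on these
slides validate the machinery (tiling arithmetic, classifier contract,
clustering identities, feature/ROC construction), not clinical
performance; the published accuracies on real tissue microarrays are
explicitly out of scope.

## 6. Problem sizes and determinism

Slide-scale analyses in the test suite use 256 × 256 px slides (the
minimum the generator accepts, one TMA core at the scale convention);
the disease-trend and ROC-recovery checks use 20 cohorts of 40 slides
(10 per state, cohort seeds 0–19), clustered at the k = 5 feature on
ground-truth compartment masks — isolating the clustering→feature→
diagnosis chain, while classifier behaviour is checked separately and an
end-to-end run (tiles → classifier → majority filter → clustering →
features → ROC) covers the full chain at smaller cohort size.  Every
random draw in the package derives from a single seed through named
substreams, and a repeated pipeline run with the same seed reproduces
its feature and ROC CSVs byte for byte.

## Known limitations

* The deep-learning backbone is faithfully configured but cannot be
  exercised without a Keras backend; the colour baseline is not a claim
  of equivalence to the CNN on real tissue.
* Overlapping-stride slide inference (argmax of mean probability) is
  configurable in principle but the class-matrix-to-mask expansion
  requires the non-overlapping default.
* The 40% stage-1 retention guard and the 0.5% yield floor are package
  defaults standing in for unstated criteria; both are configurable.
* Quadrant thresholds for the decision rule (as opposed to the swept
  ROC) must be supplied by the user; no threshold-selection procedure is
  implemented.
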