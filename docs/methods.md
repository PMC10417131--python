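# Methods

This note documents the models and procedures implemented in `somscape`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Input scale and preprocessing

All analyses assume *centralized log₁₀ expression*: each gene's values are
deviations from its own mean log expression across the cohort, so positive
values read as over-expression. `preprocess` chains three steps, each
skippable for data that arrives partly processed (the common case for
public array data):

1. **log₁₀ transform** with a user offset (default 0; every shifted value
   must be positive, and the first offending gene/sample is named).
2. **Quantile normalization**: every column is forced onto the common
   distribution of cross-column rank means. Ties within a column receive
   the mean of the reference values at their tied ranks, so tied entries
   stay tied.
3. **Centralization**: subtract each gene's row mean (idempotent).

Missing values are rejected at load time rather than imputed; arrays are
complete in the intended use case, and silent imputation would blur the
portrait semantics.

## SOM portrayal

The map is a planar (non-toroidal) rectangular grid, default 50 × 50 =
2500 metagenes, batch-trained on the gene profiles:

* **Initialization**: prototypes are laid out on the plane spanned by the
  first two principal components of the gene cloud, spanning ±2 SD along
  each, which makes training deterministic given the data.
* **Training**: 30 batch sweeps (default). In each sweep every gene is
  assigned to its Euclidean best-matching unit (ties resolve to the lowest
  linear index) and prototypes are recomputed as Gaussian-neighborhood
  weighted means; the neighborhood radius anneals linearly from half the
  larger grid dimension down to 1. Computation uses float32 matrix
  products, which keeps a 6000 × 2500 × 120 training run under ~10 s on
  one CPU.
* **Quantization-error trace**: the mean best-matching distance is
  recorded after every batch update. The pre-training (initialization)
  error is not part of the trace: the first smoothing sweep pulls
  prototypes toward the data mean and may sit above the PCA-plane error,
  whereas the post-update trace is non-increasing over the annealing
  schedule (asserted in the tests to 1e-6).
* **Grid conventions**: pixel (col, row), origin top-left, linear index =
  row · width + col. These conventions are frozen because spot pixel sets,
  HR maps and gene lists all address pixels by linear index.

Portraits, group mean portraits and difference portraits are pixelwise
reads/means/differences of the prototype matrix. Supporting maps:
per-pixel variance across samples (ddof = 1), gene population counts,
group summary (pixelwise max over group means), and a personalized summary
(per-pixel q-quantile over individual portraits, default q = 0.9, which
surfaces patterns too rare to dominate any group mean).

Sample similarity diagnostics operate on metagene profiles: silhouette
scores on 1 − Pearson distance (singleton clusters score 0; the
nearest-other label is the foreign cluster with the smallest mean
distance), FastICA embeddings (zero-variance metagenes dropped), and a
correlation-threshold sample network.

Rendered portraits use a diverging palette with symmetric limits at
±max|value| per image; rendering is presentation only and carries no
reproducibility guarantee.

## Spot modules

Detection runs on a summary map: pixels above the per-map
`threshold_percentile` (default 86) are labeled into 8-connected
components; components smaller than `min_pixels` (default 4) are dropped;
survivors are labeled A, B, … by descending peak value. A spot's gene
list is the set of genes whose best-matching unit lies in its pixels, and
its expression profile is the per-sample mean over its pixels.

**Why 86, and why a watershed.** Co-expression modules occupy roughly
density-proportional map area (a 200-gene module among 6000 genes claims
~40–90 of 2500 pixels) and organize along the map border, so neighboring
modules can abut with no sub-threshold gap. A very high percentile (top
2%) captures only blob peaks; a lower one risks merging neighbors. The
default therefore thresholds low enough to cover whole blobs and then
splits any component containing two or more *h-maxima* — local maxima
whose prominence above the connecting valley exceeds
`split_depth` × (component peak − threshold), default 0.1 — by a watershed
seeded at those maxima. Flat plateaus yield a single h-maximum, so
compact single spots are never split. The relative depth makes the rule
invariant to adding a constant to the map, as is the percentile threshold
itself; the same rule drives per-portrait spot counting. `split_depth`
is deliberately relative to the component's own height so that a dim
module merged with a bright one is still recognized by its own prominence.

The wTO network between spots uses the signed variant
ω_ij = (Σ_k a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 − |a_ij|) with
a = Pearson correlation of spot profiles and k_i = Σ_{k≠i}|a_ik|; the
signed form keeps anticorrelation between programs visible. The
liver-contamination split is a complete-linkage hierarchical clustering of
the one-dimensional spot profile cut at two clusters ("high" = larger
mean); being rank-geometry based it is invariant to monotone affine
transforms of the profile.

## Gene-set scores

GSZ(s) = (mean over present set genes − mean over all genes) /
(SD over all genes / √n_set), computed per sample with the sample SD
(ddof = 1). Consequences used as test anchors: the all-gene set scores
exactly 0, and a singleton set reduces to the gene's within-sample
z-score. Set genes absent from the matrix are dropped with a logged
count; an entirely absent set is an error. Spot/set overrepresentation
uses the one-sided hypergeometric tail P(X ≥ overlap) with
Benjamini–Hochberg correction across the collection per spot. The
reported tail is by construction conservative (discrete); its
continuity-corrected version is exactly uniform under random draws, which
is how the null behavior is verified.

## Trajectory

The principal tree is deliberately simple and fully specified: PCA to
`n_components` (default 10) → k-means with `n_nodes` centroids (default
20, deterministic under the seed) → minimum spanning tree over centroids
with Euclidean weights → samples projected to their nearest node. Leaf
chains that attach at a branch node and carry fewer than `prune_min_frac`
(default 8%) of the samples are pruned and their samples re-projected;
without this, noise dimensions grow spurious twigs on what should be a
path. Segments are maximal branch-free node paths (split at nodes of
degree ≥ 3), labeled Seg1, Seg2, … by descending sample count; branch
nodes belong to their lowest-ranked incident segment so every sample has
exactly one segment. Pseudotime is geodesic distance from the root — an
explicit node ID, or the leaf whose samples maximize a named spot's mean
expression; the root is a user decision because the orientation of a
purely unsupervised axis is not identifiable from expression alone. This
component is not a port of any single-cell trajectory package, and makes
no claim of fidelity to one.

## Prognostic maps and the ΔHR score

Per metagene pixel, the "high" group is samples with centralized metagene
expression > 0 (`gt-mean`) or > +1 within-pixel SD (`gt-1sd`; the SD is
pixel-wise across samples, flag-switchable because a global-SD reading is
also defensible). The pixel's HR is exp(β) from a univariate Cox
proportional-hazards fit of the indicator with Efron tie handling. Pixels
where either arm has fewer than `min_group_size` (default 5) samples, or
where the likelihood is monotone (no events in one arm), are masked. Cox
was chosen as the standard operationalization of a per-pixel hazard ratio;
it also supplies a standard error for masking decisions.

Because an HR map needs thousands of structurally identical univariate
fits, the solver is a vectorized Newton iteration on the Efron partial
likelihood specialized to a single binary covariate, sharing the risk-set
bookkeeping across pixels; it is validated against lifelines'
`CoxPHFitter` to ~1e-4 in the tests, and lifelines provides the
Kaplan–Meier estimates and log-rank test directly.

The ΔHR score is the mean centralized expression over the maxHR pixel's
genes minus the mean over the minHR pixel's genes (extreme pixels among
unmasked ones; ties resolve to the lower linear index). Each extreme gene
list is padded gene-by-gene from growing 8-neighborhood rings until
`min_genes` (default 20) genes — single pixels of a 50 × 50 map on a
6000-gene input hold only ~2–3 genes, too few for a stable mean. The
score is exactly antisymmetric under swapping the lists; a spot-based
variant substitutes spot gene lists. Risk groups are the top/bottom p%
(p ∈ (0, 50], default 25) with sample-ID tie-breaking; per-patient
aggregation reports the mean and SD of lesion scores (SD undefined for
single-lesion patients) and the contrast between the range of patient
means (inter-patient) and the mean within-patient SD (intra-patient).

## The synthetic cohort generator

`default_design()` (shipped as `data/default_design.yaml`) defines the
study conditions used throughout the tests: 6000 genes × 120 samples;
five subtypes LMS1–LMS5 (25/20/17.5/17.5/15%) plus a 5% liver-like LIV
group; six planted modules of 150–250 genes — five subtype markers (A–E,
+1.2 log₁₀ units in their subtype) and a liver module F (+1.2 in LIV)
additionally activated (+0.8) in 35% of samples of every subtype;
patient-level Gaussian noise (SD 0.25) plus lesion-level intra-patient
noise (SD 0.05); 1–3 lesions per patient (60/25/15%); exponential
survival with log-hazard 0.7·act_A − 0.7·act_E and ~30% independent
exponential censoring (baseline median ~24 time units). Module levels and
sizes were calibrated once so that the recovery analyses are comfortably
identifiable (a marker shift of 1.2 log₁₀ units ≈ 4.8× the noise SD);
the survival design pairs a risk with a protective module because a
prognostic score built from a maxHR *and* a minHR region presupposes both
tails exist — a power calculation shows a single binary HR≈2 module
cannot support a top-vs-bottom-quartile log-rank at α = 0.01 with ≥90%
power at n = 200, while the paired design (quartile contrast ≈ e^1.4)
can.

What the generator deliberately does *not* emulate: probe-level
microarray signal, batch effects, library-size artifacts, copy-number
dosage, single-cell data, non-proportional hazards, and correlated noise
between genes outside the planted modules. Passing tests therefore
demonstrate that the pipeline recovers planted structure of realistic
effect size under clean Gaussian noise — not that it is robust to every
real-data pathology; on real cohorts the preprocessing stage carries more
weight, and spot thresholds may need adjustment via the exposed
parameters.

## Problem sizes in the test and acceptance runs

Unit tests run a structurally identical scaled cohort (1200 genes × 60
samples, 20 × 20 grid). The full-scale analyses use: five
6000 × 120 cohorts at 50 × 50 for module recovery; one 200-sample cohort
at 40 × 40 for the survival layer (50 survival re-simulations); twenty
200-sample cohorts at 20 × 20 for null HR calibration; ten 1500 × 100
gradient cohorts at 20 × 20 for trajectory recovery; one 120-sample
cohort at 30 × 30 for the heterogeneity contrast. These sizes keep the
whole suite in the minutes range on a single CPU while leaving every
recovery margin wide (observed minima: Jaccard ≥ 0.88 over 18 probe
seeds, marker AUC ≥ 0.98, log-rank power ≥ 98%).

## Known limitations

* Spot labels are positional per run; no attempt is made to match labels
  across datasets or runs.
* The HR map cannot detect a survival-time unit mismatch between tables;
  times must share one unit.
* The principal tree is a heuristic ordering device: it has no branch
  confidence measure, and pseudotime direction is user-chosen.
* Quantile normalization assumes comparable global distributions across
  samples; strong composition shifts (e.g., heavy contamination) violate
  that assumption — which is precisely what the contamination split is
  for, downstream.
* The batch SOM is deterministic given data and configuration, but its
  layout is only identified up to grid symmetries; all derived statistics
  are layout-invariant.
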