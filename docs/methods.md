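# Methods

## Problem and model

Flow cytometry sorts cell populations by thresholding a handful of surface
markers, but populations defined this way are often impure: cells whose
molecular state (ground-truth label, e.g. a multi-omics annotation) differs
from the gate's target leak in. `citegate` quantifies that impurity on
CITE-seq ADT data — where the same gating logic can be applied *in silico*
and compared against per-cell ground truth — and then improves the gate in
two data-driven steps: rank additional markers by how well they separate
true from false positives, and replace rectangular cut-offs with non-linear
highest-density-region (HDR) gates.

## Normalization

ADT counts are compositional and heavy-tailed. The default transform is the
centred log-ratio across markers within each cell,

    clr(x)_m = ln((x_m + c) / g),   g = geometric mean of (x + c) over markers,

with pseudocount c = 1. Per-cell CLR values sum to zero, which the test
suite asserts to 1e-9. `arcsinh(x/5)` is offered as an alternative. The
normalization is recorded in a tag so the DE filter can tell counts from
transformed values and refuse double transforms.

## Gates and thresholds

A gate is a conjunction of atoms: 1-D intervals and 2-D polygons (even-odd
rule, boundary inclusive — hand-implemented because these semantics are part
of the gate contract). Panels are rooted trees; a cell gets the deepest leaf
whose root-to-leaf conjunction it satisfies, siblings are expected to be
mutually exclusive (empirical overlaps are counted and reported; first
declared wins).

Negativity thresholds are density-driven, mirroring how cytometrists place
cut-offs on the negative peak:

- **quantile mode**: the q-th quantile (default q = 0.995) of the marker
  within a negative reference — cells known not to express the marker;
- **valley mode**: the minimum of a Gaussian KDE (512-point grid, 5% range
  padding) between the two largest density modes of the full distribution.
  A unimodal density raises an error directing the caller to quantile mode.

The pipeline default tries valley mode and, for unimodal markers without a
supplied reference, falls back to the 0.995-quantile of the cells at or
below the marker's median ("lower-half" fallback) — a pragmatic stand-in
that is reasonable for mostly-negative markers and conservative otherwise.

The built-in classical panel is: CD19+ root; a plasmablast branch (CD27+
AND CD38 above the positive-population median) split by IgM; and a mature
branch (CD38 at or below that cut, CD10−) quadranted on IgD × CD27 into
naïve (IgD+ CD27−), unswitched memory (IgD+ CD27+), switched memory
(IgD− CD27+ IgM−) and IgD− CD27− (double-negative) B cells. The CD10− atom
on the mature branch is this package's design choice: transitional B cells
are IgD+ CD27− but CD10+/CD38-high, and without the atom they contaminate
the naïve gate even under ideal separation. "mid/low" and "lo" atoms in the
literature gate library span (negative threshold, median of the positive
population] — a declared convention, configurable through `ThresholdSet`.

## Purity and overlap

Gate membership is cross-tabulated against truth labels (unlabelled cells
are excluded and counted). For a gate/target pair: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), purity TP/(TP+FP), and accuracy (TP+TN)/(all
labelled cells) — the denominator choice is documented because alternatives
exist. Overlap between gated sets is the Jaccard index; compositional
similarity between populations is the Jensen–Shannon divergence, base 2
(so values lie in [0, 1]), computed between truth-label composition
vectors, with 0·log 0 = 0.

## Marker selection

Within a gate, cells are labelled TP (truth equals the target) or FP.
Three evidence streams are combined cheap-to-expensive:

1. **DE filter** — difference of mean log2(x+1) between classes on raw
   counts (plain mean difference, with a warning, on pre-normalized input);
   two-sided Wilcoxon rank-sum p-values, Benjamini–Hochberg adjusted across
   markers; survivors need |log2FC| ≥ 2 and adjusted p ≤ 0.05. If nothing
   survives, all markers are scored, with a warning.
2. **Per-marker sigmoid SVM** — single standardized feature; SVC with
   sigmoid kernel, scale-γ, r = 0, C = 1, balanced class weights; metrics
   (precision, accuracy, sensitivity/recall, F1, FP, FN; TP positive) from
   pooled out-of-fold predictions of a seeded stratified 5-fold CV (folds
   reduced with a warning when a class is smaller than 5). Cross-validated
   rather than in-sample metrics are a deliberate choice.
3. **MMD²** — the unbiased estimator

       MMD²_u = Σ_{i≠j}k(x_i,x_j)/(m(m−1)) + Σ_{i≠j}k(y_i,y_j)/(n(n−1))
                − 2Σ_{i,j}k(x_i,y_j)/(mn),

   default RBF kernel with the median heuristic (σ = median pooled pairwise
   absolute difference; σ = 1 with a warning if zero). The estimator is
   unbiased and may be negative.

Candidates are ranked by MMD² descending (F1 breaks ties, then name); up to
k = 2 markers are selected — the number of extra channels a practical
sorting panel can absorb — and markers already in the base gate remain
eligible (they are annotated, not dropped). The MMD-primary composite key
is a declared design decision; the evidence streams could be combined in
other ways.

For large gates the SVM and MMD stages subsample to a class-stratified,
seeded cap (default 2000 cells) to bound the quadratic kernel cost; the
standalone `svm_marker_score` and `mmd2_unbiased` functions are exact on
whatever they are given.

## HDR gate refinement

A Gaussian KDE (Scott's rule) of the TP cells over the selected marker pair
is evaluated on a 128 × 128 grid (data range + 5% padding). The density
level whose super-level set holds fraction α (default 0.9) of the total
grid mass is found by bisection (tolerance 1e-3 of the peak), and its
contours are extracted by marching squares (grid zero-padded so border
contours close) as one or more polygons — disconnected high-density areas
yield disjoint polygons. Fitting on TP density only (not a TP/FP ratio) is
the default; refinement therefore asks "where do the true cells live",
not "where do true cells outnumber false ones".

Refined membership is base-gate membership AND the HDR region, so a refined
gate is always a subset of its base gate. With two selected markers a
single stage over their joint plane is fitted; with one, the runner-up by
|log2FC| supplies the second axis. The evaluation reports purity
before/after, the gain in percentage points, TP yield, and per
contaminating class the fraction of its cells removed. Refined gates
serialize as polygon atoms in the standard gate config schema and round-trip
through the gating module.

## Group statistics

Per (sample, gate), the proportions of each truth label are computed;
samples where the gate is empty contribute no rows and are recorded.
Association of a (gate, label) frequency with group membership uses one-way
ANOVA on raw proportions (an empirical-logit transform is available behind
a flag) plus all pairwise two-sided Wilcoxon rank-sum tests with Holm
step-down adjustment. Tests run only when every group has more than 3
(i.e. at least 4) samples with non-zero frequency; ineligible combinations
are flagged and skipped. Samples where the gate is present but the label is
absent enter as explicit zeros.

## Synthetic data

The generator emulates a ten-marker B-cell ADT panel (CD19, CD20, CD21,
CD24, CD27, CD38, CD10, CD11c, IgD, IgM). Per population p and marker m,
counts are NegBin(mean μ[p,m], size φ_p) plus Poisson(λ) ambient background
(λ = 0.5); negative markers sit at a few counts, positives at 1–4 hundred,
matching the usual ADT dynamic range. Per-sample compositions are
Dirichlet(α₀ · π ⊙ group multiplier) with α₀ = 60, giving realistic
between-individual variation; one seed fixes the full output byte-for-byte.

Presets:

- **clean** — seven populations (naïve, unswitched/switched memory,
  IgD−CD27− B cells, plasmablasts, transitional, CD19− non-B), 12 samples ×
  500 cells; the classical panel gates the naïve population at ≥ 0.95
  purity by construction.
- **contaminated-naive** — adds an "atypical memory" population (12% of
  cells) that is IgD+ CD27− CD38-mid — indistinguishable from naïve on the
  classical axes — but CD21-low / CD20-high / CD24-high, pulling naïve-gate
  purity to ≈ 0.7–0.77. This is the substrate for marker selection (CD21
  ranks first) and HDR refinement.
- **group-shift** — two groups of 10 samples × 400 cells; the disease group
  doubles the contaminant proportion, for cross-group association tests.
- **planted-marker** (`planted_marker_config`) — two populations identical
  on every marker except a 2^Δ mean shift on one; the recovery benchmark
  for the selection pipeline. Note that for Δ = 2 the difference of mean
  log2(x+1) sits slightly below 2 (concavity of the log), so the DE filter's
  no-survivor fallback path is the one exercised — the planted marker is
  still ranked first by MMD².

What the generator does **not** emulate: per-cell capture-efficiency
(library size) variation, batch effects, doublets, antibody aggregates and
isotype-control background structure, marker-marker correlations within a
population, or gene expression/BCR modalities. Passing tests therefore
demonstrate correctness of the algorithms under a faithful count-level
model, not robustness to every artefact of real CITE-seq data.

## Problem sizes and numerical choices

Calibration experiments use sizes chosen to keep Monte-Carlo error well
below the tolerances they check: 50 random instances per metric oracle;
200 replicates at n = 500 for MMD null unbiasedness; 20 seeded runs at
n = 5000 cells for planted-marker recovery; 20 seeded runs of the
contaminated preset (6000 cells) for refinement efficacy; n = 2000 for HDR
mass calibration (|observed − α| ≤ 0.05); 1000 null simulations for ANOVA
type-I error (0.05 ± 0.02). Ties in sibling gates break by declaration
order; degenerate inputs (constant markers, collinear TP clouds, zero
median bandwidth, empty refined gates) raise or warn explicitly rather
than returning silent zeros.

## Known limitations

- Valley thresholding assumes a visible negative mode; markers that are
  uniformly positive in the data need an explicit negative reference.
- HDR polygons are grid-resolution approximations (128² default); enclosed
  mass is calibrated on the density grid, so very small α or very spiky
  densities deserve a finer grid.
- The per-marker SVM is univariate by design (the selection question is
  "which single extra channels help"); joint marker-subset optimization is
  out of scope.
- Purity metrics exclude unlabelled cells; with sparse labelling the
  reported counts say so rather than extrapolating.
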