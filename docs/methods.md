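# Methods

This note records the models, numerical choices and defaults behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Recurrence scoring (REC)

**Statistic.** For compound *c*, gene *g*, timepoint *t*, over the measured
cell lines, `rec = (#{z ≥ z_thr} − #{z ≤ −z_thr}) / n_measured` with
`z_thr = 2.0`. The statistic is bounded in [−1, 1], antisymmetric under
z → −z, and its denominator counts only measured cell lines (absent cells
are stored as missing, never zero). The threshold-count form is a
deliberately simple, interpretable concretization of "recurrent
up/downregulation across cell types"; z_thr = 2 marks the conventional
two-sigma tail of a z-scored signature.

**Null model.** The gene label is resampled independently within each cell
line's signature for the same compound, preserving each cell line's
signature distribution. Because the per-line draws are independent, the
null of the summed ±1/0 direction indicators is the convolution of L
three-point distributions (support −n…n), which this package computes in
closed form — mathematically identical to exhaustive enumeration over all
G^L per-line gene assignments, at O(L·n) cost. A Monte-Carlo estimator with
the add-one correction `p = (1 + #{|rec*| ≥ |rec|}) / (B + 1)` (B = 999
default) is provided as well; tensors with < 20 genes always take the exact
path. The exact method is the pipeline default because the screening rule
FDR ≤ 10⁻³ (Benjamini–Hochberg across hundreds of compounds within a
(gene, timepoint) slice) can only be met by p-values orders of magnitude
below any realistic Monte-Carlo floor of 1/(B+1). A compound-label
resampling null is available as a configuration alternative.

**Discreteness and calibration.** REC at n cell lines has 2n+1 support
points, so conservative p-values are necessarily non-uniform under the
null. For calibration diagnostics the package offers randomized (smoothed)
p-values, `p = P(|rec*| > |obs|) + U·P(|rec*| = |obs|)`, the standard
device that is uniformly distributed under the null for discrete
statistics. Screening always uses the conservative estimator; the
randomized one exists only to *check* calibration.

**Multiplicity and ranking.** BH FDR (statsmodels) across compounds within
each (gene, timepoint) slice — the context in which compounds compete.
Negative-REC ranks break ties by smaller p, then compound identifier, so
output order is deterministic. Ranking is within (gene, timepoint), not
pooled across timepoints.

## Nomination

Filters combine by conjunction: for every target gene and every timepoint,
REC < 0, FDR ≤ `rec_fdr_max` (10⁻³) and membership in the `rec_top_k` (30)
most negative REC scores; plus, per target gene, a negative
expression-vs-AUC correlation at p ≤ `corr_p_max` (0.05). Sensitivity is an
AUC with *lower = more sensitive* (the CTRP convention), so "high basal
expression predicts sensitivity" is r < 0 against AUC. Pearson correlation
is the default (Spearman available); p from the t-distribution on n − 2 df.
Nomination is monotone: relaxing any threshold can only add candidates.
Ragged cell-line coverage across timepoints is handled by the presence
mask; pairs with fewer than 3 shared finite cell lines are skipped with a
log entry.

## Preranked GSEA

Classic weighted Kolmogorov–Smirnov running sum (weight 1 by default; hit
increments ∝ |score|^weight normalized over hits, miss decrements
1/(N−N_h)); ES is the signed maximum deviation and the leading edge the
hits up to (ES > 0) or after (ES < 0) the extremum. If all hit scores are
zero the increments fall back to equal weights. The null permutes gene
labels — placing the set members at random list positions — because a
sample-level permutation is undefined for a preranked list that carries no
samples. Null ES are evaluated only at hit positions (the running sum's
extrema are attained there), cached per set size. NES divides ES by the
mean same-sign null ES; p is the same-sign null tail with add-one; FDR q is
the standard GSEA pooled-null NES tail ratio clipped to [0, 1]. Defaults
follow common practice: 1000 permutations, set sizes 10–500 after
intersection with the list, significance q < 0.25. Which timepoint slice
(6 h, 24 h, or their per-gene mean) feeds the ranked list is an explicit
argument.

## Survival cutoff scan

Kaplan–Meier estimation and the standalone two-group log-rank test wrap
lifelines. The scan tests every distinct expression value leaving both
groups at least `min_group` patients (default max(8, 5% of cohort); ties at
the cutoff go to the low group, high means strictly greater), evaluating
the 1-df log-rank chi-square for all cutoffs in one vectorized
O(n·n_cutoffs) sweep using the hypergeometric variance
`d·(n₁/n)(1−n₁/n)(n−d)/(n−1)` per distinct event time. The sweep is
cross-checked against lifelines per cutoff in the test suite. The reported
p is the minimum over cutoffs, with `bonf_p = min(1, raw_p ×
n_cutoffs_tested)` counting all cutoffs actually tested; since cutoffs are
correlated this Bonferroni factor is conservative, which the null
calibration tests confirm. The scan depends on expression only through
ranks, hence is invariant to monotone transforms. Stage-wise expression
summaries (group means + one-way ANOVA) are a thin descriptive helper, not
a scored stage.

## Mitochondrial morphometry

Gaussian blur (`mito_blur_sigma_px`, default 1.0) → two-class K-means on
intensities (Lloyd's algorithm in 1-D, centers initialized evenly spaced
between the min and max intensity, so segmentation is deterministic and
invariant to positive rescaling) → mask = brighter cluster, optionally
restricted to a polygon ROI; a k = 3 variant merges the two brightest
clusters for images with a diffuse haze class. Objects are 8-connected
components of at least `mito_min_object_px` (3) pixels; area is pixel count
× pixel size², perimeter the Crofton 4-direction estimator, circularity
4π·area/perimeter² (can exceed 1 slightly through discretization).
Condition comparison uses Welch's unequal-variance two-sided t-test on
per-object area and perimeter (a pooled-variance test would assume equal
spread between a few large and many small objects, which is exactly what
differs between fusion states); degenerate zero-variance comparisons return
t = 0, p = 1 when means agree. Note the Crofton 4-direction estimator is
calibrated for isotropic boundary orientation: it is within ~3% on discs
but ~6% short on axis-aligned rectangles — per-object *areas* are the
robust quantity. Z-stacks are expected max-projected before analysis.

## Dose–response

Four-parameter logistic `v = bottom + (top − bottom)/(1 + (d/IC50)^h)` fit
by least squares on log dose with free asymptotes, three fixed multi-starts
(IC50 at the geometric mean, minimum and maximum positive dose; hill 1),
tight tolerances (1e−15), best residual wins — deterministic given the
data. The dose-0 control is excluded from the fit and used only to
normalize viability to percent of control (if absent, viability is taken as
already normalized). The reported IC50 is the fitted transition midpoint;
fits are flagged extrapolated outside [min positive dose/10, max dose×10],
and a fitted curve that never crosses 50% raises "IC50 not identifiable".
A log-linear interpolation between the doses bracketing 50% mean viability
is available as a second method. Literature IC50 values for specific
compound/cell-line pairs (e.g. 28.23 and 17.30 nM for a PLK-1 inhibitor in
two neuroblastoma lines) depend on unpublished raw viability readings and
are context, not targets, for this package.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed); all randomness flows
from the run seed through named substreams, so equal config + inputs give
byte-identical outputs.

* **Signatures** — Gaussian z-score background (sd 1), a planted z-shift of
  −4 for each (reversal compound, target gene) in a chosen fraction of cell
  lines (default all 10) at both timepoints. This emulates the *shape* of
  L1000-style signatures, not bead-level intensities, batch structure, or
  correlated gene modules; passing tests show the statistics behave as
  designed, not that real signatures are this clean.
* **Sensitivity panel** — per target gene and reversal compound, expression
  and AUC share a per-cell-line latent factor giving population correlation
  exactly −|corr_r| (0.9 default; the exact degenerate line at |corr_r| = 1);
  other pairs independent. With several target genes an exact pairwise
  bivariate construction is impossible without correlating the genes; the
  latent factor is the minimal structure achieving every target pair's
  correlation simultaneously.
* **Survival cohorts** — LogNormal expression; exponential event times with
  the hazard multiplied by `hr` above the `cutoff_q` expression quantile
  (baseline hazard 0.1 per time unit); independent exponential censoring.
  No covariates, no time-varying effects.
* **Micrographs** — tubes as smooth constant-width random curves (heading
  noise sd 0.08 rad/px), placed without contact by rejection sampling,
  Gaussian PSF blur, Poisson shot noise over a flat background; fused vs
  fission pairs hold total curve length constant (default 480 px split into
  6 × 80 px vs 24 × 20 px, width 4 px, PSF 1.2 px, 30 photons/px) so
  morphology, not intensity, separates conditions. Ground truth (area,
  perimeter, label mask) is recorded pre-blur. No 3-D stacks, no
  out-of-focus light, no cell-to-cell variation.
* **Dose–response** — the logistic model itself plus Gaussian noise on the
  0/1/3/10/30/100 nM grid, 3 replicates.

## Simulation sizes

The validation suite uses: the planted screen at its stated condition
(1 reversal compound among 200 inert, 200 genes, 10 cell lines, 2
timepoints; 50 seeds), null calibration at 500 compounds × 200 genes with
B = 999 (uniformity pooled over 8 seeds, FDR screen over 20 seeds),
survival null/power at n = 200 over 100 seeds each, GSEA planted-set
recovery over 20 seeds (list of 300, 25 random background sets), image
pairs over 20 seeds, and IC50 recovery over 100 seeds at 5% noise. The
acceptance script reports the same quantities at moderately smaller seed
counts (20/5/10/50) and prints the problem size next to each value.

## Known limitations

* The REC formula and its null are this package's own concretization of
  "recurrence across cell types"; other recurrence statistics (e.g.
  rank-based or magnitude-weighted) would need their own calibration.
* GSEA FDR q uses the pooled-null ratio estimator; with very few sets it is
  coarse (q = 0 can occur when no pooled null NES exceeds the observed).
* The Bonferroni scan correction counts all tested cutoffs and is
  conservative; a permutation-based min-p null would be sharper.
* Segmentation assumes a bimodal intensity histogram; heavily vignetted or
  haze-dominated images need the k = 3 variant or an ROI.
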