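# recscreen

Expression-reversal drug nomination for target genes, with the downstream
functional analyses that typically accompany such a screen.

Given a tensor of perturbation-induced differential-expression z-scores over
(compound × gene × cell line × timepoint) — the shape of LINCS-L1000-style
signatures — the package asks: *which compounds recurrently push a target
gene down across cell types, and are cell lines with high basal expression
of that gene preferentially sensitive to those compounds?* Compounds passing
both filters for every target gene at every timepoint are nominated as
repositioning candidates. The package also provides the stages used to
characterize a nominated compound: preranked GSEA on its recurrence profile,
cutoff-scan Kaplan–Meier survival stratification of tumor cohorts,
mitochondrial fission/fusion morphometry from fluorescence micrographs, and
IC50 estimation from viability–dose tables.

## The REC score

For compound *c*, gene *g* and timepoint *t*, with z-scores *z<sub>ℓ</sub>*
over the measured cell lines ℓ = 1…n:

```
REC(c,g,t) = ( #{ℓ : z_ℓ ≥ z_thr} − #{ℓ : z_ℓ ≤ −z_thr} ) / n
```

with z_thr = 2 by default. REC ∈ [−1, 1]; −1 means the compound
downregulates the gene beyond threshold in every measured cell line.
Significance comes from a resampling null that redraws the gene label
independently within each cell line's signature; because the per-line draws
are independent, the null distribution is computed **exactly** by convolving
per-line three-point distributions (identical to exhaustive enumeration over
all gene assignments). Two-sided p-values on |REC| are corrected by
Benjamini–Hochberg across compounds within each (gene, timepoint) slice.

A compound is **nominated** when, for every target gene and timepoint,
REC < 0, FDR ≤ 10⁻³ and the compound ranks in the top 30 most negative REC
scores, *and* for every target gene the basal expression–sensitivity
correlation is negative (sensitivity is an AUC; lower = more sensitive) with
p ≤ 0.05.

All inputs are plain text (tall TSV signatures, TSV matrices, CSV cohorts,
GMT gene sets, 16-bit TIFF micrographs), and a synthetic-data module
generates every input with planted ground truth.

## Worked example

Run the full synthetic demo (201 compounds × 200 genes over 10 cell lines
at 6 h and 24 h, one planted reversal compound hitting MCM2 and MCM10 with a
z-shift of −4 in all lines, planted expression–sensitivity correlation 0.9):

```
$ recscreen --seed 7 all --outdir demo_run
demo dataset written to demo_run
wrote demo_run/rec_scores.tsv (804 rows)
nominated 1 compound(s): RVRSL-001
wrote demo_run/gsea_results.tsv: 25 sets, 1 at q < 0.25
```

The screen recovers exactly the planted compound `RVRSL-001`: its REC is
−1.0 for both target genes at both timepoints with exact permutation
p ≈ 10⁻¹⁶, far below the FDR ≤ 10⁻³ screening threshold, while all 200
inert compounds fail. The GSEA stage runs on the nominated compound's
genome-wide REC list against 25 random demo sets (the planted effect touches
only two genes, so enrichment here is a null demonstration).

The survival and dose-response stages on the same demo data:

```
$ recscreen survival --cohort demo_run/survival.csv --gene MCM2
MCM2: best cutoff 0.93 (high n=104, low n=96), raw p=4.82e-14, Bonferroni p=8.91e-12 over 185 cutoffs
$ recscreen ic50 --table demo_run/dose_response.csv
IC50 = 10.22 nM (hill 1.02, 4pl)
```

The demo cohort plants a hazard ratio of 4 above the median expression of
MCM2: the cutoff scan tests every admissible split (both groups ≥ 8
patients), reports the minimal log-rank p and multiplies it by the number of
cutoffs tested (Bonferroni). The dose–response table is generated at a true
IC50 of 10 nM with 3% viability noise on the 0/1/3/10/30/100 nM grid; the
four-parameter logistic fit recovers it within ~2%.

```
$ recscreen mito --image-a demo_run/fused_mito.tif --image-b demo_run/fission_mito.tif
   metric  n_A  n_B     mean_A     mean_B  median_A   median_B          t            p
     area    6   24 458.833333 123.750000  458.0000 125.000000  90.957791 4.404228e-10
perimeter    6   24 172.953336  52.387991  173.1253  52.345399 200.370336 1.970483e-14
```

Fused and fission micrographs carry equal total mitochondrial mass; the
segmentation (Gaussian blur → two-class K-means threshold → 8-connected
components ≥ 3 px) recovers the larger per-object area and perimeter of the
fused condition.

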