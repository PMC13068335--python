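# Methods

This note documents the models implemented in `larconnect`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Responder classification

A subject's late-phase status is decided from the FEV1 percent-change
trajectory (hours 0–7 post-challenge) and the pre/post methacholine PC20
pair. The late window is the closed interval [3, 7] h. The primary rule
is inclusive: a maximum late fall of exactly 15% (`max_late_drop <= -15`)
is a dual responder. The rescue rule uses the measurement nearest 7 h
(within ±15 min): a fall still greater than 10% (`< -10`, strict) with an
allergen-induced shift AIS = PC20_pre/PC20_post ≥ 2 also gives DR — such
subjects are presumed to develop the LAR after the last spirometry
measurement, because the LAR is accompanied by an approximately two-fold
PC20 drop. The rule is monotone in the late fall (making the fall deeper
never converts DR to ER), which is enforced by a property test.

## Bulk preprocessing

* `log2_clip`: transform first, then replace negative results and missing
  values with zero. The alternative order (clip before log) would map
  sub-unity intensities differently; transform-first matches the rule
  "log2-transformed and values below 0 or NA replaced with zeros".
* `log_cpm`: value = log2((count + c) / (libsize + 2c) × 1e6) with prior
  count c = 0.5 by default. The 2c in the denominator keeps the transform
  exactly invariant to per-sample count scaling at c = 0 and reduces to
  the familiar libsize + 1 at the default prior.
* `filter_low_abundance`: NanoString-style background threshold — a gene
  is kept if its mean count exceeds mean + k·SD of the pooled
  negative-control counts (k = 2 by default); housekeeping genes and the
  control probes themselves are always removed. On the default synthetic
  challenge cohort this retains 600 of 770 genes.
* `collapse_probes_mean` / `sum_transcripts`: probe-level values are
  averaged per symbol within sample (microarray), transcript counts are
  summed (RNA-seq); summing is refused on log-scale input.
* Gene identifiers are matched case-sensitively after whitespace
  trimming.

### ComBat batch correction

`combat_adjust` performs parametric empirical-Bayes location/scale
adjustment (backed by scanpy's ComBat): per-gene standardization with
batch in the design, batch effects shrunk toward a normal prior
(locations) and inverse-gamma prior (scales) fit across genes by method
of moments, then back-transformation. Biological group labels, when
supplied, are protected in the standardization design (passed as
drop-first numeric dummies; a categorical covariate would make the
one-hot design singular).

A property worth understanding: EB shrinkage deliberately does **not**
zero out per-gene batch-mean differences when batch effects vary across
genes — each gene's estimated effect is pulled toward the prior mean, so
a residual proportional to its deviation remains (the same behavior as
the reference R implementation). Removal is exact (to machine precision)
when the standardized batch effect is constant across genes, e.g. a
uniform planted location shift; the test suite asserts exactness in that
regime and strong (> 85%) shrinkage for gene-varying shifts. For the same
reason the adjustment is not exactly idempotent.

Batches must have at least two samples; genes with zero variance overall
or within a batch are passed through unchanged with a warning.

### Sex imputation

Y-chromosome genes only (≥ 2 required): center, PCA to two components,
k-means with k = 2 and 10 seeded restarts; the cluster with the higher
mean Y expression is labelled male. The returned diagnostic is the
centroid separation in PC space divided by the pooled within-cluster
spread. The procedure is invariant to sample order and to the presence of
autosomal genes. With a 5-SD planted Y-gene elevation the imputation is
exact; real cohorts (mixed platforms, partial Y coverage) will do worse.

## Sparse PLS-DA

Two-class, two components by default. Columns of X are centered and
scaled to unit SD (ddof 1); Y is a two-column class indicator, centered
and scaled — for two classes this is rank-1, so component 1 coincides
with classical PLS1 (used as an independent cross-check against sklearn's
`PLSRegression`). Per component, the NIPALS weight vector is
soft-thresholded by the largest excluded |weight| so exactly `keepX`
entries stay nonzero, then renormalized; scores t = Xw; X is deflated by
t·pᵀ (Y is not deflated). Ties in |weight| at the threshold could reduce
the nonzero count below `keepX`; with continuous expression data this has
measure zero.

Prediction applies the stored scaling, walks the deflation sequence, and
returns T·q for the positive-class column of the centered dummy — zero at
the training mean, positive toward the positive class. VIP is
VIP_j = sqrt(p · Σ_h SS_h w_jh² / Σ_h SS_h) with SS_h = (Σ_k q_hk²)·t_hᵀt_h,
so mean(VIP²) = 1.

**Tuning** is 20×5-fold stratified CV: per repeat, test-fold scores are
pooled before computing one AUC; repeat r derives its fold assignment
from seed + r, making the whole table reproducible. `tune_keepx` tunes
components sequentially (component 1 first, later components with earlier
ones fixed), which scans 6 + 6 configurations instead of 36. The panel
rule takes, among configurations with mean AUC strictly above the
threshold (0.70), the one with the fewest total transcripts; ties break
by higher mean AUC, then lower SD. When nothing qualifies the result is
an explicit "no panel", not an exception.

Panel merging unions symbols in first-appearance order and reports total
slots and the pairwise overlap matrix. The fixed reference panels (sizes
40, 33, 35, 34, 14) are constructed so the slot total is 156 and the
union is 109.

## Cohort evaluation

The grid is the Cartesian product of declared axes in declared order.
Each cell subsets samples to its two comparison groups and sex stratum
("combined" uses everyone; imputed sex can stand in where sex is
unobserved), drops panel genes missing from the dataset (error if more
than half are missing), and runs the same pooled-scores repeated CV with
either a dense PLS-DA (keepX = p) or a random forest (500 trees,
sqrt(p) features per split, seeded; smaller forests are used in the
scaled-down test configurations). Cells whose classes cannot fill the
folds are skipped with a logged reason rather than failing the grid.

Importances come from a full-data refit — VIP for PLS-DA, impurity
importance for the forest — converted to percentage ranks
(highest → 1, lowest → 0, ties averaged) and averaged per biomarker over
models with mean AUC > 0.70; a biomarker only enters the averages of
models whose panel contains it.

## Pseudobulk differential expression

Counts are normalized per cell to a common scale factor (median library
size by default; 10⁴ optionally), log2(x+1) transformed (zeros stay
zero), and averaged per (cell type, sample); strata under `min_cells`
(10) are dropped with a log entry. Per cell type, an OLS fit of the
condition contrast runs on **all** genes, and empirical-Bayes moderation
shrinks residual variances: with e = log s² − ψ(d/2) + log(d/2), the
prior df d₀ solves ψ′(d₀/2) = var(e) − ψ′(d/2) (trigamma inversion by
Newton iteration) and the prior variance follows a lowess trend in
average expression when `trend=True`. The moderated
t = β / sqrt(s̃²·v) has d + d₀ degrees of freedom; d₀ = 0 recovers the
ordinary t and d₀ = ∞ the fully pooled t, with monotone interpolation in
between (tested). With the trend off, results agree with the R reference
implementation to machine precision on a frozen fixture; the trend mode
uses statsmodels' lowess, which differs from the R smoother in detail
(agreement r ≈ 0.9999 on the same fixture).

Results are then restricted to the biomarker list and BH-adjusted within
each cell type (restriction before adjustment — the FDR is controlled
over the hypotheses actually reported); flags at q < 0.20. The contrast
is unpaired (condition as fixed effect; subjects are not modeled) to
match the pseudobulk design; cell types observed in only one condition,
or with too few strata for residual df, are skipped and logged.

Note one compositional effect that tests must anticipate: library-size
normalization means a strong planted **up**-shift in a cell type deflates
all other genes' normalized values there, producing genuine down-flags
outside the planted set. Null datasets (no planted effect) stay at the
nominal flag rate.

## Drug connectivity

Per cell type, one linear model over pseudobulk samples (compound ×
donor) with an indicator per compound and DMSO as reference (optional
donor blocking), with the same EB moderation. Genes are ranked by
s = log2FC × (−log10 p). The enrichment score walks the list sorted by
descending s (ties broken by gene id): hits add |s|^α normalized over the
set (α = 1), misses subtract 1/(N − m); ES is the running-sum value of
largest magnitude. This makes ES antisymmetric under score negation and
invariant to positive rescaling of s. An empty intersection yields a
flagged NaN, not an exception.

The raw ES is bounded in [−1, 1], so the connectivity score
CS = ES_up − ES_down is bounded by ±2. Because reported connectivity
magnitudes above 3 are meaningful only on a normalized scale, the default
scoring mode divides each ES by the mean |ES| of same-sign random
same-size gene sets (seeded, vectorized permutations; NES), with raw-ES
mode available. Reversers are compounds with CS < 0 in every scored cell
type (mimics: CS > 0 everywhere); positive controls are scored but
excluded from those calls. Biopsy cell types map onto screen cell types
via a user-overridable table (CD4/CD8 T subtypes to their parents, MNP to
Myeloid); sets of biopsy types sharing a target are unioned.

## Over-representation analysis

One-sided Fisher exact p per gene set from the 2×2 overlap table of the
query list and the set, both intersected with a caller-supplied universe
(default in the pipeline: all genes on the analyzed platform after
filtering). BH adjustment across the library; significant at q < 0.01.
`frequent_genes` tallies each list gene's occurrences across significant
sets.

## Synthetic data

The generators emit the four data tiers with planted truth sufficient to
score every recovery metric; all are deterministic under a fixed seed.

* **Challenge cohort** (defaults: 15 ER / 20 DR, 770 genes of which 40
  housekeeping, 8 negative-control probes): negative-binomial counts
  (dispersion size 10). 130 genes are drawn below the control background
  so default filtering retains 600. Informative genes (25) are shifted in
  DRs by `effect` SDs of the log2 count noise. FEV1 trajectories give
  every subject an early fall ≥ 20%; DRs fall ≥ 15% late except a
  configurable borderline fraction (10%) who stay in (−15, −10) at 7 h
  with AIS ≥ 2, so the classification rules recover the planted classes
  exactly, exercising both DR rules.
* **Bulk cohorts**: Gaussian log-intensities (or NB counts for the
  RNA-seq-like dataset) for the 109 panel genes plus background and six
  Y genes; group effects scale with severity level; each dataset is its
  own batch (additive per-gene shift); males get a 5-SD Y-gene elevation;
  optional male-only effect genes reproduce a sex-specific signal
  qualitatively. Default group sizes mirror the seven public cohorts'
  structure.
* **Single-cell biopsy** (4 + 4 subjects, pre/post condition, six cell
  types): NB counts (size 2) around lognormal gene means; in the asthma
  group's allergen condition only, planted per-cell-type sets are
  multiplied by 2^±effect. Defaults plant 55 up-regulated biomarkers in
  CD8 T and 42 in CD4 T (plus small down sets).
* **Perturbation screen** (defaults: 144 compounds + DMSO + dabrafenib/
  belinostat × 3 donors × 5 cell types): the planted reverser inverts the
  target sets in every cell type, the mimic reinforces them, other
  compounds perturb a few random non-target genes, and positive controls
  perturb many genes strongly.

What the generators do **not** emulate: gene–gene correlation, cell-type
marker structure, doublets/ambient RNA, platform-specific intensity
distributions, or missing-at-random annotations. Passing recovery tests
therefore demonstrates the estimators' correctness and calibration under
the stated noise models, not performance on real cohorts.

### Problem sizes in tests and the acceptance script

The generator defaults are the study-scale conditions. The test suite and
`scripts/acceptance.py` run scaled-down designs chosen once for speed:
perturbation screens of 12 compounds × 2 donors × 3 cell types × 10
cells; biopsies with 20 cells per stratum and 40 background genes; grids
with few panels and 100-tree forests; the null-CV calibration uses
n = 80, p = 60 and averages five independent null datasets, because
repeated-CV AUCs on a single dataset are strongly correlated across
repeats and a single draw retains ~0.1 spread around 0.5.

## Known limitations

* Two classes only; multiclass sPLS-DA and keepY sparsity are out of
  scope, as are component counts beyond the configured `ncomp`.
* The moderated fit assumes a common design across genes and at least one
  residual df; single-replicate conditions are rejected.
* NES permutations draw uniform gene sets, ignoring gene–gene
  correlation, so NES calibration is optimistic on correlated data.
* The ComBat surface exposes only the parametric prior variant.
* ORA's default universe (analyzed platform) is a choice, not a given;
  enrichment counts depend on it and on the supplied GMT libraries.
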