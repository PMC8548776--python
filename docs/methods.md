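# Methods

`nafld_meta` re-implements, as a tested and reusable pipeline, a cross-study
meta-analysis workflow for gut shotgun-metagenomic profiles over the ordered
NAFLD spectrum (healthy controls, NAFL, NASH, fibrosis, cirrhosis). This note
records the models, the defaults and why they were chosen, the numerical
details, and what the synthetic verification battery does and does not show.

## Data model

Profiles are feature-by-sample matrices (species, genus, pathway or
gene-family level) with a declared unit (`counts`, `relative`, `cpm`,
`log_cpm`, `normalized`). Metadata carries, per sample: study of origin,
stage as an ordered five-level factor (HC < NAFL < NASH < fibrosis <
cirrhosis, coded 0–4), BMI (kg/m²), age and sex. Metadata joins are strict
one-to-one on sample ID; an unmatched sample is an error rather than a silent
drop, because a desynchronized label column is the most dangerous failure
mode of a merged-cohort analysis.

## Filtering

Counts (or relative abundances) are rescaled per sample to counts-per-million
(cpm). The prevalence filter keeps a feature only if its cpm *strictly
exceeds* 1 in at least 3 samples; the boundary is read literally from the
rule "exceed", and both threshold and count are configurable. Cross-study
consistency is the same rule applied within every study separately — a
feature must be reliably detectable in each cohort, not merely in the pooled
table. Pooled-prevalence filtering and per-study consistency are deliberately
separate operations, since "detected" and "consistently detected" feature
sets differ and both are reported in the run manifest.

## Normalization and batch correction

`log_cpm` is log2(cpm + 1); the unit pseudocount maps absent features to
exactly zero and is exposed in configuration.

Batch correction follows the supervised-normalization idea: per feature, a
linear model contains the biological design **B** (stage, 5-level factor by
default; a binary control/case coding is available by flag) and the
adjustment design **A** (study factor), and only the fitted adjustment
component is subtracted, centred so grand means are preserved. Because a
partially confounded design can absorb disease signal into the batch
estimate, the fit is iterated (default 5 iterations, tolerance 1e-4 on the
adjustment coefficients): each round (1) regresses batch-cleaned data on
**B**, (2) turns the per-feature biological F statistics into association
weights via Benjamini–Hochberg-adjusted tail probabilities (weight = 1 − q),
and (3) re-estimates **A**'s coefficients from the data minus the *weighted*
biological component. Null features therefore contribute their full profile
to the batch estimate while associated features contribute only their
non-biological part. Intensity-dependent (array-style) adjustment terms are
omitted: after log-cpm, sequencing profiles have no analogue of probe
intensity, and study is the only removed effect. A study containing a single
stage makes the joint design rank-deficient; this triggers a warning and a
fall back to estimable contrasts (least-squares pseudoinverse) rather than a
hard failure.

The confounder ANOVA replaces each feature's values by midranks across
samples, then computes type-II sums of squares for stage, BMI, age, sex and
study (each covariate's increment over the model containing all others),
divided by the total rank sum of squares. BMI and age enter linearly (single
degree of freedom, the smallest model for a continuous covariate). The
computation is projection-based and vectorized over features; a test checks
it against statsmodels' `anova_lm(typ=2)` on ranks. Constant features are
flagged and given zero fractions.

## Association statistics

**Blocked Wilcoxon.** The meta-analysis is one stratified rank-sum test over
the pooled samples — not a per-study p-value combination — with blocks
defined as study × BMI-tertile (bins from global quantiles of the analyzed
samples; both bin count and the inclusion of study are configurable, and a
missing BMI goes to its own bin). Within each informative block (≥2 samples,
both groups present) midranks are formed; the deviations of the case
rank-sum from its null mean are summed over blocks and divided by the root
of the summed tie-corrected null variances, giving a Z statistic with a
two-sided normal p-value. Blocks containing a single group are dropped from
the statistic, standard stratified-test practice. When the number of
within-block group assignments is at most 1e5 (configurable), the exact
permutation distribution is built by enumerating per-block rank-sum
distributions and convolving them; `mode="auto"` switches automatically,
`"exact"`/`"normal"` force a path. With a single block the test reduces
exactly to the classic two-sided Wilcoxon rank-sum test.

**Generalized fold change** is the mean of case-minus-control differences at
the nine quantiles 0.1–0.9 (linear-interpolation quantiles), computed on the
same log-scale matrix that is tested, so p-value and effect direction always
refer to the same quantity. It is location-equivariant and antisymmetric
under group swap.

**AUROC** is the midrank Mann–Whitney statistic, P(case > control) +
P(tie)/2; its confidence interval uses the DeLong placement-value variance
with a normal quantile, clipped to [0, 1].

**FDR** is Benjamini–Hochberg, one family per contrast across features
(the progressive contrast is its own family). Contrasts: all patients vs HC
("meta"), each stage vs HC, and progressive (NASH+fibrosis+cirrhosis) vs
(HC+NAFL). Thresholds: significance at q < 0.05, core set at meta q < 1e-3,
both configurable. Direction is the sign of the generalized fold change.
Blocking is applied in every contrast by default; the per-stage tests can be
run unblocked by passing a single-block scheme.

**Progression (pSRC).** Partial Spearman correlation between abundance and
stage rank given BMI: midranks of the feature and of stage rank are each
regressed on midranks of BMI, and the Pearson correlation of the residuals
is tested with a t approximation on n − 3 degrees of freedom. HC enters at
rank 0 by default (patient-only coding is a flag). A feature is called
progression-consistent when its stage-vs-HC q-value is below 0.05 in NASH,
fibrosis and cirrhosis with the same fold-change sign in all three.

## Diversity, ordination, network

Alpha diversity is the Gini–Simpson index 1 − Σp², computed on cpm within
the filtered feature set (the batch-corrected matrix is not
abundance-interpretable); inverse Simpson is available. Pairwise stage
comparisons use the unstratified two-sided rank-sum test (the single-block
case of the blocked test). Bray–Curtis dissimilarity is computed on
per-sample proportions, making it library-size invariant. PCoA is classical
scaling (eigendecomposition of the double-centred Gower matrix); axes with
negative eigenvalues are dropped without correction, their count is
reported, and the proportion explained is taken over the positive
eigenvalues only. The PCA view is feature-centred PCA of samples, used to
compare study structure before and after batch correction.

The co-occurrence network is built over the core feature set from midrank
Spearman correlations across all samples; an edge exists where |rho|
*strictly* exceeds 0.8 (configurable), signed positive/negative, with
isolated nodes retained and constant features recorded as missing.
Correlation is computed on one pooled network, not per group.

## Machine learning

The classifier protocol: stratified 70/30 train/test split; per-feature
standardization (mean 0, sd 1) fitted on the training portion only; grid
search over interaction depth {1,2,3} × trees {50,100,150} with shrinkage
0.1, minimum node size 5 and stochastic subsampling 0.5, by stratified
4-fold cross-validation maximizing ROC area (first maximum wins ties);
final refit at the winning point. The learner is scikit-learn's gradient
boosting; a 500-tree random forest is the verification learner. The quoted
protocol's "centered and scaled" step is implemented per feature — per-sample
standardization of library-normalized data is incoherent for tree models —
with a per-sample mode retained behind a flag for fidelity experiments. All
randomness flows from one seed. Fewer than `cv_folds` training samples in a
class is a hard error with an actionable message.

Validation designs:

- **Stage-vs-control transfer matrix.** Controls are split once into 70%
  train-eligible / 30% holdout, reused by every model for comparability.
  Model *i* trains on stage-*i* patients (70%) plus eligible controls;
  the diagonal cell tests on stage *i*'s holdout plus the control holdout;
  cell (i, j) tests on *all* stage-*j* patients plus the same control
  holdout. Controls seen in training are never re-used at test time, the
  conservative resolution of an ambiguity in transfer evaluation (the
  optimistic alternative — testing on all controls — is easy to enable but
  not default).
- **One-vs-rest** among patients only: each stage against the other three
  pooled, with its own 70/30 split.
- **Split-half replication**: samples are halved stratified by study and
  stage; each half independently runs filter → normalize → train
  (patients-vs-controls); each model is tested on its own holdout and on the
  entire other half. Feature filtering and normalization are recomputed per
  half, so no preprocessing information crosses the halves.

AUROC is the trapezoid over the empirical ROC (equal to pair counting);
AUPR is the step integral of the precision–recall curve. Variable importance
is split-gain relative influence normalized to sum 100.

## Synthetic cohorts

The generator emulates a merged multi-study design: per-feature baseline
log2 abundances ~ N(0, 2.5) (a wide spread, so rare taxa drop below
detection realistically); per-study × per-feature batch shifts ~ N(0,
batch_sd, default 1 log2 unit); stage effects either uniform over patient
stages or growing linearly with stage rank (rank/4 of the full effect,
default 2 log2 units); BMI drawn per stage (means 24/28/30/31/32, sd 3,
mirroring the obesity gradient of fatty-liver cohorts) with optional
BMI-linked features (slope 0.15 log2 per BMI unit above the control mean);
library sizes log-normal (median ≈ 2M reads, log-sd 0.35); counts
gamma-Poisson with Var = μ + 0.3μ². Differential features are drawn from
the lower half of baseline abundance: spiking a dominant taxon would shift
every other feature's relative abundance through compositional closure,
silently invalidating the null labels, and disease-associated species are
in any case rarely the community's dominant members. A `stage_specific`
class (off by default) gives each patient stage a private signature for
transfer-heterogeneity experiments. Presets: three balanced studies
(20/stage/study, 300 features), and an unbalanced design with stage totals
120/39/39/15/14 across three studies.

What the generator does **not** emulate: taxon–taxon correlation beyond the
induced stage/batch structure, zero-inflation beyond what the count model
produces, per-study differences in sequencing depth distributions or
taxonomic bias, longitudinal structure, and functional-profile scale
(millions of gene families). Passing recovery tests therefore demonstrates
the statistical machinery is correct under the stated model, not that any
particular real-data finding would replicate.

## Verification battery and problem sizes

The acceptance battery (also re-runnable via `scripts/acceptance.py`) uses
these frozen designs, all chosen by power analysis before the battery was
first run:

- Oracle equivalence: exact blocked test vs exhaustive enumeration on ≤10
  samples; AUROC vs pair counting; BH vs the step-up definition.
- Confounded null: 1,000 features, 100 samples/group, case BMI shifted by
  one sd (3 units), feature–BMI slope 0.05 per unit. Tertile blocking leaves
  ≈21% of the raw confounding (measured by Monte-Carlo), so the naive test
  rejects at ≈0.16 while the blocked test stays near 0.05.
- Batch recovery: 200 features, 15/stage/study, deterministic +2/0/−2 log2
  study shifts injected into a batch-free cohort; residual study rank
  variance and the spiked-feature AUROC change against the same draw.
- Differential-abundance recovery: 10 seeds × (3 studies × 40 controls/40
  patients), effect 2 log2 units, sensitivity on stage-uniform features and
  false-discovery proportion on nulls.
- gFC calibration: shifts {0.5, 1, 2}, 100/arm, within-group log-sd 0.5,
  200 replicates per shift.
- pSRC: 4,000 null replicates at n=150 (the mean |rho| of a *perfect* null
  is √(2/π)/√(n−3), ≈0.066 at n=150, which bounds what the confounding-
  removal check can show) against the 95% binomial band for 1,000 trials.
- Transfer: 300 features, 20/stage/study, shared (stage-uniform, 15%) vs
  disjoint (stage-specific, 20%) signatures.
- End-to-end: the balanced preset, run twice, byte-identical output
  checksums.

These sizes keep any single experiment under a few minutes on one CPU while
leaving the conclusions clearly powered.

## Known limitations

- The normal approximation of the blocked test is used for cohort-scale
  data; exact p-values are only available for small strata.
- SNM here is per-feature location adjustment by study; it does not model
  study-specific dispersion or taxonomic bias.
- The DeLong interval degenerates to a point under complete separation.
- Compositionality is handled by design choices (robust rank tests,
  low-abundance spiking in simulation), not by log-ratio modelling; ALR/CLR
  approaches are out of scope.
- Transfer AUROCs share one control holdout across cells, so cells are
  correlated; they are comparable to each other, not independent estimates.
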