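# Methods

This note records the statistical conventions the package implements, the
choices made where more than one convention is defensible, and what the
synthetic data can and cannot establish.

## Cohort model

A cohort is a per-subject table: demographics (age in years, sex),
diagnosis stratum (SCD / MCI / dementia), MMSE at baseline and follow-up
(0–30), a 4-level clinician disease-course label at ~12 months
(progression / stable / fluctuation / improvement), 8 unilateral lobe
volumes (mm³), 8 unilateral lobe FDG-PET SUVRs (unitless, reference-region
normalized upstream), total ventricular volume (mm³), total
grey+white-matter SUVR, and optionally CSF total tau (ng/L), disease
duration and education (years). The pipeline starts from these quantified
values; image acquisition, segmentation and SUVR computation are out of
scope.

The binary outcome collapses fluctuation, improvement and stable into
**stable** — those courses are individually too rare for separate
analysis — against **progressed**. Subjects with MMSE below the study
inclusion floor of 18 trigger a validator warning, not a rejection: the
library must accept externally assembled tables.

## Standardization and dichotomization

- **Intracohort z-scores** use the cohort's own mean and *sample* SD
  (n − 1 denominator, the default of standard statistical software). Each
  column is standardized over its non-missing subjects, so CSF tau —
  measured in roughly half the cohort — is standardized against the
  tau-measured subset, exactly the subjects eligible for models that use it.
- **Direction conventions**: lobe volumes, lobe SUVRs and the total SUVR
  are abnormal *below* the threshold; ventricular volume and CSF tau
  *above* it.
- **Boundary**: a z-score exactly at the threshold is *not* abnormal
  (strict inequalities).
- **Thresholds** are magnitudes t ∈ {0, 0.1, 0.5}; the low-direction
  threshold is −t and the high-direction one +t, varied jointly in the
  sensitivity grid.
- Lobe pattern counts use the 8 *unilateral* lobes, so each of the counts
  n(+A/−H), n(−A/+H), n(+A/+H) lies in 0..8 and the four patterns
  (including −A/−H) partition the 8 lobes. Counts are dichotomized at
  ≥ 2 lobes (sensitivity: 1 and 3).
- The **anatomical variable** per bilateral lobe takes A = atrophy in
  either hemisphere, H = hypometabolism in either hemisphere: neither →
  no abnormality (reference); A only → isolated atrophy; H only → isolated
  hypometabolism; both → congruent or non-isolated abnormality. The last
  level deliberately merges same-hemisphere congruence with
  cross-hemisphere co-occurrence: at lobe level the available definition
  distinguishes only "both modalities somewhere in the lobe" from isolated
  findings, and a finer split is not identifiable from lobewise flags.
- **Abnormal-marker counts**: set M1 = {ventricular volume, total SUVR,
  CSF tau} (0–3, complete-case ⇒ tau subset only), set M2 drops tau (0–2,
  full cohort). Missing tau is a first-class state, never imputed as 0.

## Effect estimation

- Univariable binary-exposure effects use the **Woolf** 2×2 estimator:
  OR = ad/bc, SE(log OR) = √(1/a+1/b+1/c+1/d), normal-approximation
  (Wald) 95% CI and two-sided p. No continuity correction by default — a
  zero cell is an error unless the Haldane–Anscombe +0.5 mode is requested
  explicitly, and corrected results carry a flag.
- Multivariable models are plain (unpenalized) **logistic regression** via
  Newton maximum likelihood (statsmodels), convergence tolerance 1e-8,
  ≤ 100 iterations, Wald CIs from the inverse observed information. Wald
  rather than profile-likelihood intervals were chosen because the
  univariable closed form is Wald, and the two routes then agree exactly
  for a single binary predictor — the test suite uses this as a dual-route
  oracle on every published 2×2. Categorical terms are dummy-coded against
  the first level (female; unexposed / count 0 / no abnormality).
- Possible separation (any |β| > 15) attaches a warning but still returns
  estimates; a singular Hessian falls back to BFGS. Terms constant within
  the complete-case set are reported with counts but excluded from
  estimation (recorded in the table's metadata) — degenerate grid cells and
  single-pattern fixtures produce these legitimately.
- p-values render as three decimals, "<0.001" below that.

## Internal validation and collinearity

- **Repeated stratified k-fold CV** (default k = 10, 1000 repeats, seeded):
  per fold an unpenalized logistic model is fit on the training part and
  held-out subjects are classified at probability ≥ 0.5 (a tie counts as
  progressed — arbitrary, documented). Overall accuracy is the mean over
  all folds and repeats; balanced accuracy = (sensitivity + specificity)/2
  on the pooled held-out predictions. Stratification on outcome matches
  common resampling defaults; a non-stratified mode exists.
- **Condition number**: Belsley convention by default — columns of the
  design (intercept appended) scaled to unit Euclidean length,
  κ = √(λ_max/λ_min) of the scaled cross-product. A correlation-matrix
  convention (no intercept) is available; exactly singular designs return
  infinity.

## Descriptives

Group comparisons dispatch the named test per variable: Pearson chi-squared
**without** continuity correction (this choice reproduces the published
baseline sex comparison exactly, and many software defaults differ), Fisher's
exact test for sparse tables (r×c by full enumeration under fixed margins;
a seeded conditional Monte-Carlo permutation fallback guards against
combinatorial blow-up), one-way ANOVA, Kruskal–Wallis. Spearman correlations
are pairwise-complete (tau pairs use the tau subset), with t-approximation
p-values and a significance flag for correlogram masking. MMSE-change
regressions model follow-up minus baseline (decline is negative) on a
biomarker z-score by OLS, exporting residuals and fitted values for Q-Q and
residual diagnostics.

## Sensitivity grid

`run_sensitivity` crosses thresholds × lobe cut-offs × outcome definitions
× adjustment sets × cohort filters. Every requested cell holds either a
full model table with provenance (threshold, cut-off, n, exclusions) or a
structured failure reason; the grid never aborts on a degenerate cell. The
base cell (first entry of every axis) is bit-identical to the standalone
primary analysis. Each successful cell records whether its +A/+H point
estimate lies on the same side of 1 as the base cell — the directionality
robustness criterion. The MMSE-decline outcome marks subjects as progressed
when baseline − follow-up ≥ 3 (boundary included) and excludes subjects
missing either score. By default subgroup cells inherit the full-cohort
z-scores (the subgroup analyses are the same model on fewer patients);
`rescore_subgroups=True` re-standardizes within the subgroup.

## Synthetic data

`generate_cohort` draws a latent severity s ~ N(0,1) per subject; lobewise
volume and SUVR signals are −λ·s plus equicorrelated noise (loadings 0.6,
within-modality residual correlation 0.5 — stated assumptions, the source
cohort reports no inter-lobe correlations), affinely mapped to physical
scales (e.g. frontal volume 180,000 ± 18,000 mm³ — arbitrary constants that
intracohort z-scoring cancels exactly). Ventricular volume grows
lognormally with age and severity; tau grows with severity and is missing
completely at random for ~49% of subjects (76/149 measured, no missingness
mechanism is reported). Progression is sampled from a logistic model whose
predictor is the *dichotomized* +A/+H lobe count computed from the
generating signals — the analysis model is therefore correctly specified
and parameter recovery is clean; `risk_from="severity"` provides a
deliberately mis-specified mode for robustness experiments. Defaults:
n = 149, age 70.3 (SD 9.8), intercept −1.4 (≈ one-third progressors at the
default effect), effect log OR = ln 4.46 (the primary published effect
size).

What a green synthetic test establishes: the pipeline recovers generating
effects without bias attributable to the code, preserves determinism under
seeds, and behaves correctly under null and degenerate conditions. What it
does not establish: agreement with the original cohort's multivariable
estimates, CV accuracies, condition number or correlation structure — those
depend on the raw data's joint distribution, which the generator only
sketches. Quantities reproducible from printed contingency counts are
instead checked exactly via the fixture cohorts, which encode each printed
table's exposure/outcome structure in raw values (two well-separated
clusters per column with sub-cluster jitter) and verify themselves by
re-deriving the feature end to end after construction. Fixtures are
per-table; no single subject-level dataset can reproduce all printed tables
jointly without the original raw data.

## Known limitations

- The Woolf/Wald machinery assumes large-ish cells; sparse tables (the
  3-abnormal-markers level, occipital multivariable contrasts) produce wide
  intervals and are sensitive to separation.
- Fisher's exact enumeration is exponential in principle; the MC fallback
  is accurate but stochastic (seeded).
- The generator's diagnosis strata, MMSE trajectories and follow-up times
  are plausible but not calibrated beyond their published margins.
- Repeated CV refits ~k·repeats models; with the published 1000 repeats the
  default cohort takes a few minutes on one CPU (tests and the acceptance
  script scale repeats down, which only narrows the Monte-Carlo error of a
  mean).
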