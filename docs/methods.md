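# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the known limitations of the package. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and preprocessing

The unit of analysis is a dense log2 genes x samples matrix with a sample
metadata table (patient, timepoint 0-3, sex, age, initial and
re-irradiation WHO grade, total dose in GyRBE, survival). Matrix/metadata
consistency is a hard error unless the caller opts into intersecting.

**Virtual-pool normalization.** The reference is the per-gene median over
samples, r_g = median_s(x_gs); each sample is shifted by
o_s = median_g(x_gs - r_g). One pass is applied, exactly as defined. Two
properties deserve care: on matrices of the form x_gs = b_g + c_s
(a common profile plus per-sample offsets) one pass removes the offsets
*exactly* and is exactly idempotent; on unstructured data the median
reference moves slightly between passes, so idempotence and shift
invariance hold only approximately (residual per-sample offsets are
~1e-2 log2 at 1000 genes and shrink with gene count; the tests assert
both the exact structured case and the approximate general case). A
mean-based pool would be exactly invariant but was rejected for
robustness.

**Scale summaries.** The MAD is the raw median absolute deviation without
the 1.4826 Gaussian consistency constant: every use here is a
quantile-threshold selection, which is invariant to the constant.
Quantiles are linear-interpolation (type 7) throughout. The top-variant
gene set is the top ceil(0.10 G) genes by MAD across all samples, ties at
the cutoff broken lexicographically so selections are reproducible.

**Covariate coding.** Sex enters as a female indicator; initial grade
numerically (II/III/IV -> 2/3/4), the grade at re-irradiation as a
III-vs-IV indicator. Residualization is gene-wise OLS on the named
covariates with the gene mean added back; rank-deficient designs are
rejected with the collinear columns named.

## Inferential kernels

**BH / Bonferroni.** Step-up BH (statsmodels) behind a thin validated
surface; tested against a hand-rolled step-up oracle.

**TOST equivalence.** Two one-sided Welch t-tests of H0: d <= -m and
H0: d >= +m; the reported p is the larger of the two one-sided p-values
and equivalence requires p < alpha. The margin is expressed in pooled-SD
units (default 1.0 SD) because no absolute margin is reported for the
analysis being reproduced; it is a configuration field recorded in output
headers. Zero-variance degeneracies are decided by the raw mean
difference and flagged. Note an arithmetic consequence of the default:
with arms of 5/6/3 patients, declaring equivalence needs
m > |d| + t_crit * se, i.e. a margin of roughly 1.2 pooled SDs even at a
zero observed difference — the default-margin prescreen is therefore
*highly* selective by construction (often empty at n = 14), which the
dose stage reports rather than hides.

**ANOVA-type statistic (ATS).** One-group repeated-measures rank test:
joint mid-ranks, relative effects per timepoint, centering contrast T,
statistic F = p'Tp / tr(T V) with V the (pairwise-complete) covariance of
subject rank vectors scaled to Cov(p). The reference distribution is the
Box approximation chi-square(f)/f with f = tr(TV)^2 / tr((TV)^2). An
earlier denominator-df variant taken from the independent-groups setting
proved badly conservative on correlated repeated measures (size 0.015 at
nominal 0.05 in 2000-replicate null simulation) and was replaced by this
standard form, which calibrates at 0.04-0.06 across the designs used
here. Subjects observed at fewer than two levels are dropped; remaining
missingness enters through pairwise-complete covariance. If the contrast
variance estimate is zero, the test returns p = 1 for no rank variation
and p = 0 for a perfectly consistent within-subject shift.

**Wald-type statistic (WTS).** Two-way factorial rank interaction test:
cell-wise relative effects, interaction contrast C = P_a ⊗ P_b, quadratic
form with a diagonal covariance estimate (observations treated as
independent) inverted by Moore-Penrose pseudo-inverse, chi-square
reference on (a-1)(b-1) df. Applying a between-subject factorial test to
longitudinal data is a deliberate, documented convention of the analysis
being reproduced; its consequences are measurable and reported by the
acceptance machinery: on the cohort's longitudinal null the test is
conservative at alpha = 0.05 (the independence assumption overestimates
the interaction-contrast variance), while 3-observation cells make its
far tail liberal. Both effects are inherent to the design, not tuned
away.

**Mixed models.** Gene-wise linear mixed models with a random patient
intercept, fitted by REML (statsmodels MixedLM, lbfgs with a bfgs retry),
Wald z per fixed effect; when the random-effect variance estimate
collapses to zero or the fit fails the model falls back to OLS with a
logged warning. Null calibration on 500 generator null genes is asserted
to lie in (0.03, 0.08) at alpha = 0.05.

**Survival.** Cox proportional hazards (Efron ties) and Weibull
accelerated-failure-time models via lifelines on patient-level data;
AIC = -2 log L + 2k with k counting all estimated parameters (for the
Weibull AFT: covariates + intercept + shape); likelihood-ratio tests are
against the intercept-only model of the same family. Marker covariates
use the pre-treatment sample's expression.

## Synthetic cohort generator

The generator emulates the study conditions: 14 patients whose sex, age,
grade and dose composition reproduce the published cohort table
(9 male / 5 female; ages 2/6/6 across <40 / 40-49 / >=50; initial grade
5 II / 2 III / 7 IV; re-irradiation grade 5 III / 9 IV; doses
5/6/3 at 30/33/36 GyRBE), four timepoints with at most one missing
non-baseline draw per patient (never the baseline — every screen
conditions on it), and 5000 genes.

Expression for gene g, patient p, timepoint t is

    x = mu_g + b_gp + covariate terms + class profile + dose term
        + marker terms + hub regression + noise,

with baseline means uniform on 6-12 log2, gene noise SD uniform on
0.1-0.5, and random intercepts b_gp ~ N(0, 0.3^2) drawn per
(gene, patient). Drawing the intercept per gene-patient pair (rather
than one scalar per patient) is exactly the random-intercept structure
every downstream gene-wise mixed model assumes, and it is what makes
serial samples of one patient genuinely more correlated than samples of
two patients — the property the fingerprint clustering detects.

Planted effects (disjoint gene sets): 20 housekeeping genes (SD 0.02,
means in the top 2% of the baseline range so that they can clear the
97.5% median quantile of the fingerprint rule); 10 sex genes (±2.0
log2); 2 age genes (±0.02 log2/yr); 10 initial-grade genes (±0.4 per
grade step); 15 genes per temporal class with profiles
(0,-1,-1,-1), (0,-1,0,+0.5), (0,0,-0.5,-1), (0,+1,+1,+1) at amplitude
1.0; 10 dose genes (amplitude 1.5 log2 at 36 GyRBE scaling linearly to 0
at 30, gated as a transient spike at the first post timepoint or
sustained from it); 3 hub genes (SD fixed at 0.5 so their satellites are
identifiable) each with 20 satellites at regression coefficient ±0.8;
one marker gene with a ±1.5 log2 patient-level offset defining two
balanced trajectory groups (applied at all timepoints — a stable
patient trait observable pre-treatment), and a 50-gene block with
group-specific slopes of ±0.5 log2 per timepoint. Survival is Weibull
AFT (shape 1.2, scale 12 months) with coefficients -0.8 for initial
grade IV and -0.7 for trajectory group B, administratively censored at
36 months.

What the generator does **not** emulate: probe-level noise, array batch
effects, correlated null genes (nulls are independent given the patient
intercept), cell-composition shifts, or non-Gaussian heavy tails.
Passing tests on this generator therefore demonstrate that the pipeline
detects the planted statistical structure at the study's sample sizes —
not that any specific gene-level finding on real data would replicate.

## Pipeline design choices

* **Screen tiers.** Strict tier: FDR < 0.05 on the top-variant set;
  liberal tier: FDR < 0.2 on all genes. BH families are per screen, never
  pooled across screens.
* **Dynamics classes** are assigned by thresholded contrasts
  (e1 = m1 - m0, e3 = m3 - m0 against tau = 0.5 z-units) on mean
  z-profiles of covariate-adjusted (sex, age, initial grade) data. The
  rule is deterministic and testable; a caveat: profiles whose early
  contrast sits inside the (-tau, tau) band can change class when scaled,
  so scale-stability is guaranteed only away from the band (all planted
  prototypes qualify).
* **Seed-gene screens** are plain OLS across all samples with Bonferroni
  adjustment (matching the "linear models" convention of the source
  analyses); a mixed-model variant exists behind a flag.
* **Embedding AIC.** The 2-D embedding backend is pluggable (t-SNE via
  scikit-learn by default, UMAP optionally) with a fixed seed; the AIC of
  I(grade IV) ~ d1 + d2 + d1:d2 is computed per timepoint on a joint
  embedding, so AIC comparisons share one model structure (k = 4) and
  differ only in fit. Perfect separation is flagged, with AIC -> 8.
* **Trajectories.** "Differences and correlations" is fixed as:
  consecutive-timepoint deltas over the top-variant gene set,
  concatenated per patient, Pearson-correlated between complete-series
  patients, Ward-clustered on 1 - r and cut at k = 2; incomplete-series
  patients are assigned to the cluster whose core members correlate best
  with them on shared segments and are flagged `nearest-centroid`.
  Cluster names are anchored to the smallest patient ID so labels are
  order-invariant. Known limitation (measured, documented in the
  acceptance output): planted dose-interaction deltas are shared among
  the three high-dose patients and can occasionally out-vote the
  marker-block group signal for one such patient.
* **Determinism.** A run is fully described by the YAML analysis config
  plus one integer seed; every output table carries the config hash and
  seed in a header comment, and identical (config, seed) produce
  byte-identical TSVs.

## Problem sizes

The default test and acceptance runs use the study-scale cohort
(14 patients x 5000 genes, ten replicate seeds for recovery rates), 2000
null genes for rank-test size, 500 for mixed-model size, and n = 200
patients for survival coefficient recovery — sizes chosen so each check
has adequate Monte-Carlo resolution while the whole suite stays
desk-scale.
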