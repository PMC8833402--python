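# cirblood

Longitudinal whole-blood transcriptome analysis for small re-irradiation
cohorts: patient/tumor fingerprinting, treatment time-course and
dose-interaction screens, trajectory clustering with baseline marker
discovery, and parametric survival model comparison.

## The problem

Recurrent high-grade glioma (rHGG, WHO grade III/IV) is rarely re-biopsied
before or during re-irradiation, so serial blood draws are an attractive
surrogate for monitoring tumor evolution under therapy. The setting this
package models is a cohort of 14 rHGG patients treated with carbon-ion
re-irradiation (30/33/36 GyRBE in 3 GyRBE fractions), with whole-blood
expression profiles drawn before treatment and 3, 6 and 9 weeks after it
(one timepoint missing for some patients). The analysis has to extract
several distinct kinds of signal from a single log2 genes x samples matrix
at n = 14:

* **stable patient/tumor fingerprints** — per patient, genes with
  within-patient median above its 97.5% quantile and raw median absolute
  deviation (MAD, no consistency constant) below its 2.5% quantile;
* **covariate associations** — gene-wise linear mixed models (random
  patient intercept, REML, Wald z) of the most-variant 10% of genes
  against sex, age and tumor grade, BH-adjusted (FDR < 0.05);
* **treatment time courses** — the rank-based ANOVA-type statistic (ATS)
  for repeated measures, globally over the four timepoints and pairwise
  (baseline vs each post-treatment timepoint), with genes assigned to four
  temporal classes: (1) sustained decrease, (2) decrease then
  return/overshoot, (3) steady or late decrease, (4) early sustained
  increase;
* **dose interactions** — the rank-based Wald-type statistic (WTS) for the
  dose x time interaction, plus a TOST equivalence prescreen of baseline
  expression across dose arms feeding a post-treatment-only mixed-model
  interaction;
* **trajectories and survival** — patients correlated on their
  consecutive-timepoint expression changes, clustered into two groups,
  screened for baseline marker genes, and compared in Cox /
  Weibull accelerated-failure-time survival models by AIC
  (AIC = -2 log L + 2k).

Real patient data are not distributable, so the package ships a
synthetic-data generator that plants every one of these effects with known
ground truth, and the whole pipeline is exercised and graded against that
ground truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/03_fingerprints.py
python analysis/07_trajectories_survival.py
```

prints (seed 1):

```
simulated 5000 genes x 51 samples (14 patients, seed 1)
planted effect genes: 226; trajectory groups: {'B': 7, 'A': 7}

stable genes per patient: median 8 (range 2-15); union of 48 genes
planted housekeeping genes recovered in union: 20/20
mean within-patient sample correlation 0.740 vs cross-patient 0.110

trajectory clustering: {'A': 7, 'B': 7} (ARI vs planted groups: 1.00)
top baseline marker: G00176 (effect -2.54 log2, FDR 4.45e-03; planted marker is G00176)
```

Reading this: the fingerprint rule recovers all 20 planted
high-abundance/low-variance genes and serial samples of the same patient
are far more correlated than samples of different patients (a preserved
per-patient fingerprint); the delta-correlation clustering reproduces the
two planted trajectory groups exactly (adjusted Rand index 1.0) and ranks
the planted bimodal pre-treatment marker first among 5000 genes. The
remaining drivers (`02`, `04`-`06`) produce the cohort characteristics
table, the covariate/seed-gene/signature/embedding screens and the
time-course and dose screens, writing every result table under
`results/`.

The same stages are available as CLI subcommands
(`cirblood simulate|preprocess|fingerprint|associate|dynamics|dose|trajectory|survival|summarize`).

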