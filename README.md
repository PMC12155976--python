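# epiaccel

Epigenetic age-acceleration analysis for small paired (pre/post-treatment)
cohorts — built around the question of whether growth-hormone replacement
in GH-deficient children slows or speeds biological ageing, as read from
blood DNA methylation.

## What it computes

**DNAm age.** Biological age is scored from bisulfite-pyrosequencing
methylation (percentage points, 0–100) at five CpG sites with a linear
clock:

```
Y = 3.26847784751817
  + 0.465445549010653 · meth(ELOVL2)
  − 0.355450171437202 · meth(C1orf132)
  + 0.306488541137007 · meth(TRIM59)
  + 0.832684435238792 · meth(KLF14)
  + 0.237081243617191 · meth(FHL2)
```

**Age acceleration.** The residual of DNAm age regressed (OLS) on
chronological age, pooled over both timepoints: positive values mean
"biologically older than expected". Residuals sum to zero and are
uncorrelated with chronological age by construction.

**Paired descriptives.** Per-variable T0 vs T6 comparisons routed by a
Shapiro–Wilk normality check: mean ± SD with the paired *t*-test, or
median [Q1;Q3] with an *exact* Wilcoxon signed-rank test (full null
distribution over all 2ⁿ sign assignments). Spearman correlations between
chronological and DNAm age per timepoint, with an exact permutation
*p*-value at n ≤ 10. HOMA-IR = insulin [µIU/mL] × glucose [mmol/L] / 22.5.

**Longitudinal mixed models.** Random-intercept (per subject) linear
models of age acceleration, REML via statsmodels, with Wald *t* inference
on between-within residual degrees of freedom:

* change model `accel ~ time` (univariate and covariate-adjusted) — the
  time coefficient is the T6 − T0 change;
* interaction model `accel ~ time * covariate` — covariate effect at each
  timepoint plus the treatment × covariate interaction *p*;
* adjusted model `accel ~ time + covariate` — covariate association
  controlling for treatment;
* marginal means of acceleration per timepoint at a fixed covariate value
  (e.g. IGF-1 = 120 µg/L).

**Synthetic cohorts.** Because individual-level study data are not
publicly deposited, a generator produces GHD-like cohorts with known
ground truth (treatment shift, IGF-1 slope, subject intercepts):
methylation profiles are back-solved from the intended DNAm age by a
minimum-norm shift along the clock coefficients, so the whole pipeline is
testable end to end, including estimator bias, CI coverage and type-I
error.

## Worked example

The numbered scripts under `analysis/` run the full study workflow on a
simulated 10-subject cohort (seed 17) and write their tables to
`results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_compute_dnam_age.py
python analysis/03_age_acceleration.py
python analysis/04_descriptives.py
python analysis/05_mixed_models.py
python analysis/06_recovery_experiment.py
```

Key lines of the output:

```
age regression (pooled, n=20): DNAm age = 1.040 + 0.961 x age
  acceleration at T0: -0.18 +/- 3.69 years
  acceleration at T6: +0.18 +/- 3.10 years
change in acceleration T6-T0, univariate: +0.367 years (95% CI -2.385 to 3.118, p=0.7698)
change in acceleration T6-T0, IGF-1 adjusted: -1.872 years (95% CI -6.390 to 2.646, p=0.3672)
marginal means at IGF-1=120 ug/L: T0 -0.03, T6 -1.91 years (comparison p=0.3672)
```

Read: with a pooled residual fit the two timepoint means are mirror
images by construction; the raw T6 − T0 change is masked by the
treatment-driven IGF-1 rise (IGF-1 carries a positive acceleration
slope), and only after adjusting for IGF-1 does the negative treatment
shift (truth −1.8 years in the generator) reappear, here −1.87. The
recovery script then quantifies the estimator over 200 replicates at
n = 100: bias +0.04 years, 95 % CI coverage 94.5 %, IGF-1 slope bias
−0.0001.

The same stages are available as a CLI (`epiaccel simulate | compute-age |
accel | report | analyze | run`) for external CSV data; see
`epiaccel --help`.

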