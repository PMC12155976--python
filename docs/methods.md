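# Methods

## The clock

DNAm age is an affine function of methylation (percentage points, 0–100)
at five CpG sites (ELOVL2, C1orf132/MIR29B2C, TRIM59, KLF14, FHL2). The
constants are stored as exact decimal strings in
`src/epiaccel/data/default_clock.json` and parsed at load time; they are
never retyped in code, so the 15-digit coefficients cannot drift through
transcription, and a clock round-trips through serialization
bit-identically. Methylation is taken to enter on the percent scale: the
intercept (~3.27 years) and coefficient magnitudes are only consistent
with a paediatric-to-adult age range if inputs are 0–100, not 0–1.
Out-of-range values are hard errors, never clamped — clamping would
silently corrupt the score. Gene symbols act as column aliases for the
formula's site keys, giving an unambiguous join between the clock and CSV
columns.

## Age acceleration

Acceleration is the residual from an OLS regression of DNAm age on
chronological age. The default fits the regression **pooled over both
timepoints**: with complete T0/T6 pairs this makes the two group means of
acceleration exactly equal in magnitude and opposite in sign (the sum of
residuals is zero and the pairs contribute equally), which is the
structure a paired pre/post analysis of this kind exhibits. A
`baseline_only` scope is provided for scoring follow-up observations
against a baseline-anchored line, and residuals are always computed
against the *stored* fit coefficients so new data can be scored without
refitting.

## Paired descriptives

Each variable is routed between the paired *t*-test (summary mean ± SD)
and the Wilcoxon signed-rank test (median [Q1;Q3]) by a Shapiro–Wilk
normality check on the pooled values at α = 0.05; a per-variable override
exists because the routing convention of any given published table cannot
be recovered from a normality rule alone. Conventions that differ across
software and are therefore fixed here explicitly:

* Wilcoxon zero differences are dropped before ranking (Wilcoxon's
  original procedure); ties in |d| get mid-ranks. The exact two-sided
  *p* doubles the smaller tail of W⁺ over all 2ⁿ sign assignments,
  computed by dynamic programming over integer-doubled ranks —
  algebraically identical to full enumeration, which the test suite
  verifies literally for n ≤ 10.
* Spearman rho is the Pearson correlation of mid-ranks. The *p*-value is
  exact (full n! permutation enumeration) when n ≤ 10 and there are no
  ties, else the *t* approximation on n − 2 df. At n = 10 the exact path
  enumerates 3.6 M pairings in vectorized chunks (~seconds).
* Quartiles use linear (type-7) interpolation.
* Glucose mg/dL → mmol/L conversion divides by 18.016 (the molar mass of
  glucose); rounded legend factors like "0.06" are not used for
  arithmetic.

## Mixed models

All inference models are linear mixed models with a per-subject random
intercept and a 0/1 time indicator (T0 reference), estimated by REML
(statsmodels `MixedLM`). On a balanced complete-pairs design the
univariate time coefficient equals the paired mean difference exactly,
which the suite checks numerically. The interaction model reports the
covariate effect at T0 (main coefficient) and at T6 (main + interaction,
SE from the covariance of the linear combination).

statsmodels reports asymptotic z inference; this package instead applies
Wald *t* intervals and *p*-values on **between-within residual degrees of
freedom**, df = n_obs − n_subjects − k (k = non-intercept fixed effects),
appropriate for effects that vary within subject — which all battery
terms do here. A plain residual df option (n_obs − rank X) is exposed.
Satterthwaite-type df are not implemented; at the simulated calibration
sizes the choice is immaterial, at n = 10 subjects it shifts CI width
slightly and is the main reason digit-level replication of any particular
software's output is not claimed.

Covariates enter raw and uncentered, so betas are per natural unit (e.g.
years of acceleration per µg/L IGF-1). No multiplicity correction is
applied across the covariate battery — a deliberate mirror of common
practice in small exploratory cohorts, and a documented caveat. Marginal
means evaluate the covariate-adjusted change model at a fixed covariate
value (default IGF-1 = 120 µg/L, a baseline-median-like value exposed as
a parameter); their difference is identically the adjusted time contrast,
and the comparison *p* is that contrast's *p*. Degenerate inputs are
handled explicitly: a singular design (constant covariate) raises a
singular-design error; data with zero residual variance fall back to the
exact OLS solution with zero variance components and undefined *p*
(flagged, not fabricated); a zero random-intercept variance estimate is
flagged as a singular fit but returned.

## Synthetic cohort generator

The generator emulates the design the inference battery assumes, with
defaults chosen as the study conditions: n = 10 subjects, baseline age
uniform on 6–15 years, second timepoint exactly 6 months later, subject
intercept SD 2 years and residual SD 2 years (acceleration SD ≈ 2.8 in
quadrature), treatment shift −1.8 years, IGF-1 slope 0.011 years per
µg/L, baseline IGF-1 log-normal with median 120.5 µg/L (log-SD 0.4)
multiplied by 2.8 (log-noise 0.25) under treatment. The IGF-1 effect is
centered at the configured baseline median so the treatment shift is
interpretable as the IGF-adjusted contrast. A clinical covariate panel
(auxology, glucose/insulin with derived HOMA-IR, lipids, CRP, HbA1c) is
drawn with within-subject correlation 0.7 around plausible paediatric GHD
values; sex alternates deterministically for a 5/5 balance.

Site-level methylation has no public reference data, so the default
trajectories are synthetic conventions: linear in age with slopes scaled
so the clock of the noise-free trajectory tracks chronological age
(≈ 1.022·age − 0.01 over 6–15 years), e.g. ELOVL2-like increasing at
1 %/year. Gaussian site noise is added, then the profile is shifted by
the **minimum-norm** solution along the clock coefficient vector so the
clock reproduces the intended DNAm age exactly (to 1e-9); infeasible
targets (a site forced outside 0–100) raise an error naming the binding
site, i.e. the first site to hit a bound along the shift direction.
Randomness uses one per-subject stream `default_rng([seed,
subject_index])`, so output is reproducible and independent of generation
order.

What the generator does **not** emulate: assay chemistry (bisulfite
conversion efficiency, pyrosequencing noise spectra), realistic
between-site correlation of methylation beyond the shared age trend,
measurement error in IGF-1, and any nonlinearity of covariate effects.
Passing recovery tests therefore demonstrate that the estimators are
correct for the assumed linear-Gaussian data-generating process, not that
the scientific conclusions transfer to real cohorts.

## Calibration checks and problem sizes

`recovery_experiment` runs the full pipeline (generate → clock →
acceleration → change model) per replicate and aggregates bias, RMSE,
CI coverage and rejection rates against the generative truth. The test
suite calibrates at 500 replicates of n = 200 subjects for bias/coverage
of the treatment shift (with the IGF-1 slope set to zero there, since the
univariate change model is only an unbiased estimator of the shift when
no covariate effect is present) and 1000 replicates for the null
covariate type-I error; the analysis driver uses 200 replicates at
n = 100 with the IGF-1-adjusted model as its standing example. A small
pooled-fit subtlety: because T6 observations are 0.5 years older, a
nonzero treatment shift leaks marginally into the age-regression slope,
biasing the recovered contrast by ≈ shift · 0.5 · cov(time, age)/var(age)
— about +0.017 years under the default conditions, well inside the
stated bias tolerance and invisible relative to the estimator SD.

## Known limitations

* Two timepoints only ({T0, T6}); the label map is configurable but the
  paired invariants assume exactly two complete waves.
* No missing-data handling: complete pairs are a hard requirement,
  matching the design the models assume.
* No cell-composition adjustment or alternative published clocks; the
  clock registry accepts user-supplied JSON definitions but ships only
  the five-CpG model.
* Exact Spearman enumeration is limited to n ≤ 10 without ties; beyond
  that the t approximation is used.
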