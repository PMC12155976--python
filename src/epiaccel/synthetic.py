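"""Synthetic longitudinal GHD-like cohorts with known ground truth.

The generator emulates the statistical structure of a paired
pre/post-treatment epigenetic-ageing study: ~10 short-statured children
measured at baseline (T0) and after six months of growth-hormone
replacement (T6), with

* chronological age drawn uniformly over a paediatric range, T6 exactly
  six months later;
* a per-subject random intercept on age acceleration (within-subject
  correlation across timepoints);
* a treatment effect on age acceleration (negative by default) plus a
  linear IGF-1 effect, IGF-1 itself log-normal at baseline and multiplied
  ~2.8x by treatment;
* methylation trajectories per CpG site that are linear in age, scaled so
  the clock's expected age tracks chronological age roughly 1:1, with
  Gaussian site noise;
* a clinical covariate panel (auxology, glucose/insulin with HOMA-IR,
  lipids, CRP, HbA1c) anchored to plausible paediatric GHD values.

Methylation is back-solved from the intended DNAm age by a minimum-norm
shift along the clock coefficient vector, so applying the clock to the
generated profiles reproduces the intended DNAm age exactly. Each subject
draws from its own counter-based random stream ``(seed, subject_index)``,
making output independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import dataset as ds
from .acceleration import add_age_acceleration
from .clock import ClockModel, MethylationProfile, batch_compute, compute_dnam_age, default_clock
from .dataset import LongitudinalDataset
from .descriptives import homa_ir
from .errors import EstimationError, InfeasibleTargetError, ValidationError
from .mixed_models import fit_change_model


@dataclass(frozen=True)
class SiteTrajectory:
    """Linear age model of one CpG site: base % at age 0, slope %/year, noise SD %."""

    base: float
    slope_per_year: float
    noise_sd: float


#: default site trajectories: monotone age trends scaled so the clock's
#: expected age ~ 1.02 x chronological age - 0.01 over the paediatric range
DEFAULT_TRAJECTORIES: dict[str, SiteTrajectory] = {
    "methC7-ELOVL2": SiteTrajectory(10.0, 1.0, 1.0),
    "methC1-C1orf132": SiteTrajectory(60.0, -0.6, 1.0),
    "methC7-TRIM59": SiteTrajectory(8.0, 0.5, 0.8),
    "methC1-KLF14": SiteTrajectory(12.0, 0.2, 0.5),
    "methC2-FHL2": SiteTrajectory(4.0, 0.1, 0.5),
}

# clinical covariates: name -> (mean_t0, sd_t0, mean_t6, sd_t6, floor)
_COVARIATE_PANEL: dict[str, tuple[float, float, float, float, float | None]] = {
    "height_cm": (130.0, 12.0, 135.0, 12.5, 50.0),
    "height_sds": (-2.5, 0.3, -2.2, 0.4, None),
    "weight_kg": (31.0, 10.0, 34.0, 11.0, 10.0),
    "weight_sds": (-1.9, 0.7, -1.7, 0.8, None),
    "bmi": (17.5, 2.8, 18.2, 3.2, 10.0),
    "bmi_sds": (-0.8, 0.8, -0.7, 0.9, None),
    "fm_pct": (23.0, 7.0, 22.0, 6.5, 2.0),
    "ffm_kg": (23.0, 5.0, 27.0, 6.0, 5.0),
    "hv_cmyr": (3.9, 1.4, 8.7, 2.6, 0.5),
    "hv_sds": (-2.8, 1.2, 1.9, 1.8, None),
    "glucose_mgdl": (81.8, 5.9, 92.5, 6.1, 50.0),
    "insulin_mUl": (5.0, 3.0, 10.8, 4.7, 0.5),
    "tc_mgdl": (153.0, 21.0, 177.0, 23.0, 60.0),
    "hdl_mgdl": (52.0, 14.0, 65.0, 19.0, 15.0),
    "ldl_mgdl": (90.0, 16.0, 103.0, 22.0, 30.0),
    "tg_mgdl": (55.0, 15.0, 62.0, 20.0, 15.0),
    "crp_mgdl": (0.10, 0.12, 0.08, 0.10, 0.0),
    "hba1c_pct": (5.0, 0.2, 5.3, 0.2, 3.5),
}
_WITHIN_SUBJECT_R = 0.7  # T0-T6 correlation of each covariate


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of the synthetic cohort.

    Defaults emulate the reference study conditions: n=10 subjects aged
    6-15, timepoints six months apart, age-acceleration SD split evenly
    between subject and residual levels (2 + 2 in quadrature ~ 2.8 years),
    a -1.8-year treatment shift, a 0.011 year per ug/L IGF-1 slope,
    baseline IGF-1 median 120.5 ug/L raised ~2.8x by treatment.
    """

    n_subjects: int = 10
    seed: int = 0
    age_range_t0: tuple[float, float] = (6.0, 15.0)
    months_between: float = 6.0
    sigma_subject: float = 2.0
    sigma_resid: float = 2.0
    treatment_shift: float = -1.8
    igf_slope: float = 0.011
    igf_baseline_median: float = 120.5
    igf_log_sd: float = 0.4
    igf_treatment_multiplier: float = 2.8
    igf_multiplier_log_sd: float = 0.25
    igf_reference: float | None = None  # default: igf_baseline_median
    site_trajectories: Mapping[str, SiteTrajectory] = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES)
    )

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ValidationError("need at least 3 subjects")
        for name in ("sigma_subject", "sigma_resid", "igf_log_sd", "igf_multiplier_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.age_range_t0
        if not lo < hi or lo <= 0:
            raise ValidationError("age_range_t0 must be a positive increasing interval")

    @property
    def igf_ref(self) -> float:
        return self.igf_baseline_median if self.igf_reference is None else self.igf_reference


@dataclass(frozen=True)
class TrueParams:
    """Realized generative ground truth for parameter-recovery tests."""

    treatment_shift: float
    igf_slope: float
    sigma_subject: float
    sigma_resid: float
    igf_reference: float
    seed: int
    subject_intercepts: dict[str, float]
    #: intended DNAm age per observation, keyed "<subject>_<timepoint>";
    #: the clock applied to the generated methylation must reproduce these
    intended_dnam_age: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class SyntheticCohort:
    dataset: LongitudinalDataset
    truth: TrueParams


def expected_clock_age(age_years: float, params: CohortParams, clock: ClockModel) -> float:
    """Clock value of the deterministic (noise-free) site trajectories."""
    y = clock.intercept
    for site in clock.sites:
        tr = params.site_trajectories[site.site_key]
        y += site.coefficient * (tr.base + tr.slope_per_year * age_years)
    return y


def _validate_trajectories(params: CohortParams, clock: ClockModel) -> None:
    lo, hi = params.age_range_t0
    hi += params.months_between / 12.0
    for site in clock.sites:
        if site.site_key not in params.site_trajectories:
            raise ValidationError(f"no trajectory configured for site {site.site_key!r}")
        tr = params.site_trajectories[site.site_key]
        for a in (lo, hi):
            v = tr.base + tr.slope_per_year * a
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"trajectory for {site.site_key!r} leaves [0, 100] at age {a:g} "
                    f"(value {v:g})"
                )


def invert_clock(
    target_age: float,
    reference_profile: MethylationProfile,
    clock: ClockModel | None = None,
) -> MethylationProfile:
    """Minimum-norm methylation profile achieving a target DNAm age.

    Shifts the reference profile along the clock's coefficient vector
    (the least-norm solution of the affine constraint), so all five sites
    move proportionally to their coefficients and
    ``compute_dnam_age(result) == target_age`` to floating precision.

    Raises
    ------
    InfeasibleTargetError
        If any site would leave [0, 100], naming the binding site.
    """
    if clock is None:
        clock = default_clock()
    current = compute_dnam_age(reference_profile, clock)
    coefs = clock.coefficients
    step = (target_age - current) / float(coefs @ coefs)
    values = dict(reference_profile.values)
    new_values = {}
    binding = None  # (max feasible |step|, site, value it would need)
    for site in clock.sites:
        ref_key = site.site_key if site.site_key in values else site.gene
        v = float(values[ref_key]) + site.coefficient * step
        if not 0.0 <= v <= 100.0:
            # step at which this site exits [0, 100]: the binding site is
            # the one reached first along the shift direction
            bound = 100.0 if site.coefficient * step > 0 else 0.0
            exit_step = (bound - float(values[ref_key])) / site.coefficient
            if binding is None or abs(exit_step) < binding[0]:
                binding = (abs(exit_step), site.site_key, v)
        new_values[ref_key] = v
    if binding is not None:
        raise InfeasibleTargetError(binding[1], binding[2], target_age)
    values.update(new_values)
    return MethylationProfile(sample_id=reference_profile.sample_id, values=values)


def _draw_covariates(rng: np.random.Generator) -> dict[str, tuple[float, float]]:
    """One subject's covariate panel at (T0, T6), within-subject correlated."""
    out = {}
    r = _WITHIN_SUBJECT_R
    for name, (m0, s0, m6, s6, floor) in _COVARIATE_PANEL.items():
        z0 = rng.normal()
        z6 = r * z0 + np.sqrt(1 - r**2) * rng.normal()
        v0 = m0 + s0 * z0
        v6 = m6 + s6 * z6
        if floor is not None:
            v0, v6 = max(v0, floor), max(v6, floor)
        out[name] = (v0, v6)
    return out


def generate_cohort(params: CohortParams, clock: ClockModel | None = None) -> SyntheticCohort:
    """Generate a complete-pairs cohort with methylation, IGF-1 and covariates.

    Fully reproducible from ``params.seed``; each subject uses the
    counter-based stream ``default_rng([seed, subject_index])``.
    """
    if clock is None:
        clock = default_clock()
    _validate_trajectories(params, clock)
    lo, hi = params.age_range_t0
    mu_igf = np.log(params.igf_baseline_median)
    rows = []
    intercepts: dict[str, float] = {}
    intended: dict[str, float] = {}
    for i in range(params.n_subjects):
        rng = np.random.default_rng([int(params.seed), i])
        sid = f"S{i + 1:03d}"
        age0 = rng.uniform(lo, hi)
        u = rng.normal(0.0, params.sigma_subject)
        intercepts[sid] = float(u)
        igf0 = float(np.exp(mu_igf + params.igf_log_sd * rng.normal()))
        igf6 = float(
            igf0
            * params.igf_treatment_multiplier
            * np.exp(params.igf_multiplier_log_sd * rng.normal())
        )
        eps = rng.normal(0.0, params.sigma_resid, size=2)
        covs = _draw_covariates(rng)
        sex = "F" if i % 2 == 0 else "M"
        for j, (tp, igf) in enumerate((("T0", igf0), ("T6", igf6))):
            age = age0 + (params.months_between / 12.0) * (tp == "T6")
            accel = (
                u
                + params.treatment_shift * (tp == "T6")
                + params.igf_slope * (igf - params.igf_ref)
                + eps[j]
            )
            target_dnam = expected_clock_age(age, params, clock) + accel
            intended[f"{sid}_{tp}"] = float(target_dnam)
            noisy = {}
            for site in clock.sites:
                tr = params.site_trajectories[site.site_key]
                v = tr.base + tr.slope_per_year * age + rng.normal(0.0, tr.noise_sd)
                noisy[site.site_key] = float(np.clip(v, 0.0, 100.0))
            ref = MethylationProfile(sample_id=f"{sid}_{tp}", values=noisy)
            profile = invert_clock(target_dnam, ref, clock)
            row = {
                ds.SUBJECT: sid,
                ds.TIMEPOINT: tp,
                ds.AGE: float(age),
                "sex": sex,
                "igf1": igf,
            }
            for site in clock.sites:
                row[site.gene] = profile.values[site.site_key]
            for name, pair in covs.items():
                row[name] = float(pair[j])
            row["homa_ir"] = homa_ir(row["insulin_mUl"], row["glucose_mgdl"])
            rows.append(row)
    data = pd.DataFrame(rows)
    truth = TrueParams(
        treatment_shift=params.treatment_shift,
        igf_slope=params.igf_slope,
        sigma_subject=params.sigma_subject,
        sigma_resid=params.sigma_resid,
        igf_reference=params.igf_ref,
        seed=int(params.seed),
        subject_intercepts=intercepts,
        intended_dnam_age=intended,
    )
    return SyntheticCohort(dataset=LongitudinalDataset(data), truth=truth)


@dataclass(frozen=True)
class RecoveryReport:
    """Aggregated estimator behaviour over simulation replicates."""

    n_reps: int
    n_failed: int
    estimates: pd.DataFrame  # one row per successful replicate
    shift_truth: float
    shift_mean: float
    shift_bias: float
    shift_rmse: float
    shift_coverage: float | None
    shift_rejection_rate: float
    covariate: str | None = None
    covariate_truth: float | None = None
    covariate_bias: float | None = None
    covariate_coverage: float | None = None
    covariate_rejection_rate: float | None = None


def recovery_experiment(
    params: CohortParams,
    n_reps: int,
    seed: int,
    covariate: str | None = None,
    alpha: float = 0.05,
) -> RecoveryReport:
    """Run generate -> clock -> acceleration -> change model per replicate.

    Aggregates bias, RMSE, CI coverage and rejection rates against the
    generator's ground truth. Individual replicate failures are recorded;
    more than 5% failures aborts the experiment.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    recs = []
    n_failed = 0
    for r in range(n_reps):
        p = replace(params, seed=int(rep_seeds[r]))
        try:
            cohort = generate_cohort(p)
            lds = cohort.dataset.with_columns(dnam_age=batch_compute(cohort.dataset.data))
            lds, _ = add_age_acceleration(lds, scope="pooled")
            res = fit_change_model(lds, covariate=covariate)
        except (EstimationError, InfeasibleTargetError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        tc = res.time_contrast
        rec = {
            "rep": r,
            "shift_est": tc.beta,
            "shift_se": tc.se,
            "shift_lo": tc.ci_low,
            "shift_hi": tc.ci_high,
            "shift_p": tc.p_value,
        }
        if covariate is not None:
            ce = res.covariate_effect
            rec.update(
                cov_est=ce.beta, cov_se=ce.se, cov_lo=ce.ci_low,
                cov_hi=ce.ci_high, cov_p=ce.p_value,
            )
        recs.append(rec)
    if n_failed > 0.05 * n_reps:
        raise EstimationError(
            f"{n_failed}/{n_reps} replicates failed (> 5%); experiment aborted"
        )
    est = pd.DataFrame(recs)
    truth_shift = params.treatment_shift
    coverage = None
    if len(est) > 1:
        coverage = float(
            ((est["shift_lo"] <= truth_shift) & (truth_shift <= est["shift_hi"])).mean()
        )
    report = {
        "n_reps": n_reps,
        "n_failed": n_failed,
        "estimates": est,
        "shift_truth": truth_shift,
        "shift_mean": float(est["shift_est"].mean()),
        "shift_bias": float(est["shift_est"].mean() - truth_shift),
        "shift_rmse": float(np.sqrt(((est["shift_est"] - truth_shift) ** 2).mean())),
        "shift_coverage": coverage,
        "shift_rejection_rate": float((est["shift_p"] < alpha).mean()),
    }
    if covariate is not None:
        truth_cov = params.igf_slope if covariate == "igf1" else 0.0
        report.update(
            covariate=covariate,
            covariate_truth=truth_cov,
            covariate_bias=float(est["cov_est"].mean() - truth_cov),
            covariate_coverage=(
                float(((est["cov_lo"] <= truth_cov) & (truth_cov <= est["cov_hi"])).mean())
                if len(est) > 1
                else None
            ),
            covariate_rejection_rate=float((est["cov_p"] < alpha).mean()),
        )
    return RecoveryReport(**report)
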