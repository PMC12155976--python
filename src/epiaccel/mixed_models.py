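"""Random-intercept mixed models for paired pre/post cohorts.

The response is age acceleration; every model carries a per-subject random
intercept that absorbs within-subject correlation across the two
timepoints, and a 0/1 treatment-time indicator (T0 reference, so the time
coefficient is directly the T6 - T0 change). Three fixed-effect layouts
cover the whole battery:

* change model:        accel ~ time                    (+ covariate, optional)
* adjusted model:      accel ~ time + covariate
* interaction model:   accel ~ time * covariate

Estimation is REML via statsmodels ``MixedLM``. Wald t intervals and
p-values use between-within residual degrees of freedom by default (a
"residual" option, n_obs - rank(X), is exposed); covariates enter raw and
uncentered, so betas are per natural unit of the covariate. Marginal means
evaluate the covariate-adjusted model at a fixed covariate value with CIs
from the fixed-effects covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from . import dataset as ds
from .dataset import LongitudinalDataset
from .errors import EstimationError, SingularFitError, ValidationError

DfMethod = Literal["between-within", "residual"]

_ZERO_RESID_TOL = 1e-10


@dataclass(frozen=True)
class FixedEffect:
    """One fixed-effect estimate with its Wald t interval."""

    term: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValidationError(f"CI [{self.ci_low}, {self.ci_high}] excludes beta {self.beta}")


@dataclass(frozen=True)
class MixedFit:
    """Internal REML fit: coefficients, fixed-effects covariance, bookkeeping."""

    terms: tuple[str, ...]
    params: np.ndarray
    cov_fe: np.ndarray
    n_obs: int
    n_subjects: int
    sigma_subject2: float
    sigma_resid2: float
    df_method: DfMethod
    ci_level: float
    converged: bool
    singular: bool
    degenerate: bool  # zero residual variance; SEs are not meaningful

    def df_for(self, term: str) -> float:
        k = len(self.terms) - 1  # non-intercept fixed effects
        if self.df_method == "residual":
            return max(self.n_obs - len(self.terms), 1)
        # between-within: all battery terms vary within subject
        return max(self.n_obs - self.n_subjects - k, 1)

    def effect(self, term: str) -> FixedEffect:
        i = self.terms.index(term)
        return self.linear_combination(
            term, np.eye(len(self.terms))[i]
        )

    def linear_combination(self, label: str, weights) -> FixedEffect:
        """Wald t inference for a linear combination of fixed effects."""
        w = np.asarray(weights, dtype=float)
        beta = float(w @ self.params)
        var = float(w @ self.cov_fe @ w)
        se = float(np.sqrt(max(var, 0.0)))
        df = self.df_for(label)
        if self.degenerate or se == 0.0:
            return FixedEffect(label, beta, 0.0, beta, beta, float("nan"), df)
        tcrit = stats.t.ppf(0.5 + self.ci_level / 2.0, df)
        t = beta / se
        p = float(min(1.0, 2.0 * stats.t.sf(abs(t), df)))
        return FixedEffect(label, beta, se, beta - tcrit * se, beta + tcrit * se, p, df)


@dataclass(frozen=True)
class ChangeModelResult:
    """T6 - T0 change in age acceleration (Table-2-style)."""

    time_contrast: FixedEffect
    covariate: str | None
    covariate_effect: FixedEffect | None
    fit: MixedFit


@dataclass(frozen=True)
class CovariateEffectByTime:
    """Per-timepoint covariate effect with the interaction p (Table-3-style)."""

    covariate: str
    effect_at_t0: FixedEffect
    effect_at_t6: FixedEffect
    interaction: FixedEffect
    fit: MixedFit

    @property
    def interaction_p(self) -> float:
        return self.interaction.p_value


@dataclass(frozen=True)
class AdjustedModelResult:
    """Covariate effect adjusted for treatment time (Table-4-style)."""

    covariate: str
    covariate_effect: FixedEffect
    time_contrast: FixedEffect
    fit: MixedFit


@dataclass(frozen=True)
class MarginalMeansResult:
    """Model means of age acceleration per timepoint at a fixed covariate value."""

    covariate: str
    fixed_value: float
    mean_t0: FixedEffect
    mean_t6: FixedEffect
    comparison: FixedEffect  # the adjusted T6 - T0 contrast

    @property
    def p_value(self) -> float:
        return self.comparison.p_value


def _design(
    data: pd.DataFrame,
    response: str,
    covariate: str | None,
    interaction: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    if response not in data.columns:
        raise ValidationError(f"response column {response!r} missing")
    y = data[response].to_numpy(dtype=float)
    time = (data[ds.TIMEPOINT] == "T6").to_numpy(dtype=float)
    cols = [np.ones_like(y), time]
    terms = ["intercept", "time"]
    if covariate is not None:
        if covariate not in data.columns:
            raise ValidationError(f"covariate {covariate!r} missing from dataset")
        c = data[covariate].to_numpy(dtype=float)
        if np.any(~np.isfinite(c)):
            raise ValidationError(f"covariate {covariate!r} has missing values")
        cols.append(c)
        terms.append(covariate)
        if interaction:
            cols.append(time * c)
            terms.append(f"time:{covariate}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError(
            f"design matrix is singular (constant covariate {covariate!r} "
            "or collinear terms)"
        )
    groups = data[ds.SUBJECT].to_numpy()
    return y, X, groups, tuple(terms)


def _fit_lmm(
    cohort: LongitudinalDataset | pd.DataFrame,
    covariate: str | None = None,
    interaction: bool = False,
    response: str = ds.ACCEL,
    df_method: DfMethod = "between-within",
    ci_level: float = 0.95,
) -> MixedFit:
    data = cohort.data if isinstance(cohort, LongitudinalDataset) else cohort
    y, X, groups, terms = _design(data, response, covariate, interaction)
    n_obs = len(y)
    n_subjects = len(np.unique(groups))

    # Exact-fit degenerate data (no residual noise) breaks the REML
    # likelihood; fall back to the exact OLS solution with zero variances.
    beta_ols, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted_ss = float(((X @ beta_ols - y) ** 2).sum())
    if fitted_ss / max(n_obs, 1) < _ZERO_RESID_TOL:
        return MixedFit(
            terms=terms,
            params=beta_ols,
            cov_fe=np.zeros((X.shape[1], X.shape[1])),
            n_obs=n_obs,
            n_subjects=n_subjects,
            sigma_subject2=0.0,
            sigma_resid2=0.0,
            df_method=df_method,
            ci_level=ci_level,
            converged=True,
            singular=True,
            degenerate=True,
        )

    singular = False
    result = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = MixedLM(y, X, groups=groups)
        last_exc: Exception | None = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                result = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if result.converged:
                break
        if result is None:
            raise EstimationError(f"mixed model failed to converge: {last_exc}")
    if not result.converged:
        raise EstimationError("mixed model failed to converge (all optimizers)")
    for w in caught:
        if "singular" in str(w.message).lower():
            singular = True

    k = X.shape[1]
    cov_fe = np.asarray(result.cov_params())[:k, :k]
    sigma_subject2 = float(np.asarray(result.cov_re).ravel()[0])
    if sigma_subject2 <= 1e-10:
        singular = True
    return MixedFit(
        terms=terms,
        params=np.asarray(result.fe_params, dtype=float),
        cov_fe=cov_fe,
        n_obs=n_obs,
        n_subjects=n_subjects,
        sigma_subject2=sigma_subject2,
        sigma_resid2=float(result.scale),
        df_method=df_method,
        ci_level=ci_level,
        converged=True,
        singular=singular,
        degenerate=False,
    )


def fit_change_model(
    cohort: LongitudinalDataset | pd.DataFrame,
    covariate: str | None = None,
    **kwargs,
) -> ChangeModelResult:
    """T6 - T0 change in age acceleration, optionally covariate-adjusted.

    On a complete-pairs design the univariate time contrast reproduces the
    paired mean difference mean(x_t6 - x_t0) exactly.
    """
    fit = _fit_lmm(cohort, covariate=covariate, interaction=False, **kwargs)
    return ChangeModelResult(
        time_contrast=fit.effect("time"),
        covariate=covariate,
        covariate_effect=fit.effect(covariate) if covariate else None,
        fit=fit,
    )


def fit_interaction_model(
    cohort: LongitudinalDataset | pd.DataFrame,
    covariate: str,
    **kwargs,
) -> CovariateEffectByTime:
    """Effect modification: covariate slope at each timepoint.

    The T0 effect is the covariate main coefficient; the T6 effect is the
    main + interaction coefficient with its SE from the covariance of the
    linear combination.
    """
    fit = _fit_lmm(cohort, covariate=covariate, interaction=True, **kwargs)
    k = len(fit.terms)
    i_cov = fit.terms.index(covariate)
    i_int = fit.terms.index(f"time:{covariate}")
    w6 = np.zeros(k)
    w6[i_cov] = 1.0
    w6[i_int] = 1.0
    return CovariateEffectByTime(
        covariate=covariate,
        effect_at_t0=fit.effect(covariate),
        effect_at_t6=fit.linear_combination(f"{covariate}@T6", w6),
        interaction=fit.effect(f"time:{covariate}"),
        fit=fit,
    )


def fit_adjusted_model(
    cohort: LongitudinalDataset | pd.DataFrame,
    covariate: str,
    **kwargs,
) -> AdjustedModelResult:
    """Covariate association with age acceleration, adjusted for treatment time."""
    fit = _fit_lmm(cohort, covariate=covariate, interaction=False, **kwargs)
    return AdjustedModelResult(
        covariate=covariate,
        covariate_effect=fit.effect(covariate),
        time_contrast=fit.effect("time"),
        fit=fit,
    )


def marginal_means(
    cohort: LongitudinalDataset | pd.DataFrame,
    covariate: str,
    fixed_value: float,
    **kwargs,
) -> MarginalMeansResult:
    """Model means of age acceleration per timepoint at a fixed covariate value.

    mean(t) = intercept + time_beta * 1[t=T6] + covariate_beta * fixed_value,
    with CIs from the fixed-effects covariance; the comparison p-value is
    the covariate-adjusted time-contrast p. Warns (does not fail) when
    ``fixed_value`` lies outside the observed covariate range.
    """
    data = cohort.data if isinstance(cohort, LongitudinalDataset) else cohort
    cvals = data[covariate].to_numpy(dtype=float)
    if not (cvals.min() <= fixed_value <= cvals.max()):
        warnings.warn(
            f"fixed value {fixed_value:g} outside observed {covariate} range "
            f"[{cvals.min():g}, {cvals.max():g}]; marginal means extrapolate",
            stacklevel=2,
        )
    fit = _fit_lmm(cohort, covariate=covariate, interaction=False, **kwargs)
    k = len(fit.terms)
    i_cov = fit.terms.index(covariate)
    w0 = np.zeros(k)
    w0[0] = 1.0
    w0[i_cov] = fixed_value
    w6 = w0.copy()
    w6[fit.terms.index("time")] = 1.0
    return MarginalMeansResult(
        covariate=covariate,
        fixed_value=float(fixed_value),
        mean_t0=fit.linear_combination("mean@T0", w0),
        mean_t6=fit.linear_combination("mean@T6", w6),
        comparison=fit.effect("time"),
    )
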