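"""Epigenetic age acceleration.

Age acceleration is the residual from an ordinary least-squares regression
of DNAm age on chronological age. By construction the residuals sum to
zero over the fitted observations and are uncorrelated with chronological
age; positive values mean the sample looks epigenetically older than its
chronological age predicts.

The regression can be fitted pooled over both timepoints (the default) or
on baseline observations only; a stored fit can then score new
observations without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import dataset as ds
from .dataset import LongitudinalDataset
from .errors import SingularFitError, ValidationError

Scope = Literal["pooled", "baseline_only"]


@dataclass(frozen=True)
class AgeRegressionFit:
    """OLS fit of DNAm age on chronological age (both in years)."""

    slope: float
    intercept: float
    n_obs: int
    scope: Scope

    def predict(self, chronological_age) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(chronological_age, dtype=float)


def fit_age_regression(
    cohort: LongitudinalDataset | pd.DataFrame,
    scope: Scope = "pooled",
) -> AgeRegressionFit:
    """Regress DNAm age on chronological age over the scoped observations.

    Parameters
    ----------
    cohort
        Long-format cohort with ``dnam_age`` already computed.
    scope
        ``"pooled"`` uses both timepoints in a single regression;
        ``"baseline_only"`` fits on T0 rows only.
    """
    data = cohort.data if isinstance(cohort, LongitudinalDataset) else cohort
    if ds.DNAM_AGE not in data.columns:
        raise ValidationError(f"column {ds.DNAM_AGE!r} missing; run the clock first")
    if scope == "baseline_only":
        data = data[data[ds.TIMEPOINT] == "T0"]
    elif scope != "pooled":
        raise ValidationError(f"unknown scope {scope!r}")

    y = data[ds.DNAM_AGE].to_numpy(dtype=float)
    x = data[ds.AGE].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValidationError(f"need >= 3 observations to fit, got {len(y)}")
    bad = ~np.isfinite(y)
    if bad.any():
        raise ValidationError(f"missing dnam_age at rows {data.index[bad].tolist()[:10]}")
    if np.ptp(x) == 0:
        raise SingularFitError("chronological age has zero variance; regression is singular")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    return AgeRegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        n_obs=len(y),
        scope=scope,
    )


def compute_age_acceleration(
    cohort: LongitudinalDataset | pd.DataFrame,
    fit: AgeRegressionFit,
) -> pd.Series:
    """Residual of each observation from the stored age regression.

    Residuals are computed against ``fit``'s frozen coefficients, so new
    observations can be scored against a previously fitted line. Returns a
    Series ``age_acceleration`` aligned with the cohort rows.
    """
    data = cohort.data if isinstance(cohort, LongitudinalDataset) else cohort
    if ds.DNAM_AGE not in data.columns:
        raise ValidationError(f"column {ds.DNAM_AGE!r} missing; run the clock first")
    y = data[ds.DNAM_AGE].to_numpy(dtype=float)
    bad = ~np.isfinite(y)
    if bad.any():
        raise ValidationError(f"missing dnam_age at rows {data.index[bad].tolist()[:10]}")
    resid = y - fit.predict(data[ds.AGE])
    return pd.Series(resid, index=data.index, name=ds.ACCEL)


def add_age_acceleration(
    cohort: LongitudinalDataset,
    scope: Scope = "pooled",
) -> tuple[LongitudinalDataset, AgeRegressionFit]:
    """Fit the age regression and attach the residuals as a column."""
    fit = fit_age_regression(cohort, scope=scope)
    accel = compute_age_acceleration(cohort, fit)
    return cohort.with_columns(**{ds.ACCEL: accel}), fit
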