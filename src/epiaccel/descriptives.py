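"""Paired descriptive statistics and derived clinical indices.

Implements the pre/post comparison battery for a paired two-timepoint
cohort: paired t-test, exact Wilcoxon signed-rank test (full null
distribution over all sign assignments), Spearman rank correlation with an
exact permutation p-value at small n, a Shapiro-Wilk-driven routing policy
between the parametric and nonparametric tests, and the HOMA-IR insulin
resistance index.

Conventions, since software packages differ subtly:

* Wilcoxon zero differences are dropped before ranking (Wilcoxon's
  original procedure); tied absolute differences get mid-ranks.
* The exact Wilcoxon two-sided p doubles the smaller tail probability of
  W+ (sum of positive ranks), capped at 1.
* Spearman rho is the Pearson correlation of mid-ranks; the p-value is an
  exact full permutation enumeration when n <= 10 and there are no ties,
  otherwise the t approximation on n-2 df.
* Quartiles for median [Q1;Q3] summaries use linear (type-7)
  interpolation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import dataset as ds
from .dataset import LongitudinalDataset
from .errors import DegenerateTestError, ValidationError

GLUCOSE_MGDL_PER_MMOLL = 18.016  # molar mass of glucose, mg/dL per mmol/L


@dataclass(frozen=True)
class PairedComparisonResult:
    variable: str
    summary_t0: str
    summary_t6: str
    test_used: Literal["paired_t", "wilcoxon_signed_rank", "none"]
    estimate: float  # location of the T6 - T0 differences (mean or median)
    statistic: float
    p_value: float
    n: int

    def __post_init__(self):
        if not np.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "spearman"

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValidationError(f"rho {self.rho} outside [-1, 1]")


def homa_ir(insulin_uIU_ml, glucose_mg_dl):
    """Homeostatic model assessment of insulin resistance.

    HOMA-IR = insulin [uIU/mL] x glucose [mmol/L] / 22.5, with glucose
    converted from mg/dL by the molar mass of glucose (18.016 mg/dL per
    mmol/L).
    """
    insulin = np.asarray(insulin_uIU_ml, dtype=float)
    glucose = np.asarray(glucose_mg_dl, dtype=float)
    if np.any(insulin <= 0) or np.any(glucose <= 0):
        raise ValidationError("insulin and glucose must be positive for HOMA-IR")
    out = insulin * (glucose / GLUCOSE_MGDL_PER_MMOLL) / 22.5
    return float(out) if out.ndim == 0 else out


def _paired_diffs(x_t0, x_t6) -> np.ndarray:
    x0 = np.asarray(x_t0, dtype=float)
    x6 = np.asarray(x_t6, dtype=float)
    if x0.shape != x6.shape or x0.ndim != 1:
        raise ValidationError("paired vectors must be 1-d and of equal length")
    if len(x0) < 2:
        raise ValidationError("need at least 2 pairs")
    if np.any(~np.isfinite(x0)) or np.any(~np.isfinite(x6)):
        raise ValidationError("missing values in paired vectors")
    return x6 - x0


def paired_t_test(x_t0, x_t6, variable: str = "") -> PairedComparisonResult:
    """Two-sided paired t-test on d = x_t6 - x_t0 with n-1 df."""
    d = _paired_diffs(x_t0, x_t6)
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError(
            "paired t-test undefined: all differences are equal (zero variance)"
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedComparisonResult(
        variable=variable,
        summary_t0=_mean_sd(np.asarray(x_t0, dtype=float)),
        summary_t6=_mean_sd(np.asarray(x_t6, dtype=float)),
        test_used="paired_t",
        estimate=float(d.mean()),
        statistic=float(t),
        p_value=float(min(p, 1.0)),
        n=n,
    )


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero differences; mid-ranks of |d| and the sign of each."""
    d = d[d != 0]
    if len(d) == 0:
        raise DegenerateTestError("Wilcoxon test undefined: all differences are zero")
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    return ranks, np.sign(d)


def _wilcoxon_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p for W+ over all 2^n sign assignments.

    Mid-ranks are multiples of 1/2, so doubling makes them integers and
    the null distribution of 2*W+ is built by dynamic programming over
    the sign-assignment generating function — algebraically identical to
    enumerating all 2^n assignments.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_obs))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    x_t0,
    x_t6,
    mode: Literal["exact", "approximate"] = "exact",
    variable: str = "",
) -> PairedComparisonResult:
    """Wilcoxon signed-rank test for paired data.

    The statistic is W+ = sum of ranks of the positive differences
    (d = x_t6 - x_t0, zeros dropped, mid-ranks for ties). ``mode="exact"``
    computes the two-sided p from the full null distribution of W+ over
    all sign assignments and requires at most 25 nonzero differences;
    ``mode="approximate"`` uses the tie-corrected normal approximation.
    """
    d = _paired_diffs(x_t0, x_t6)
    ranks, signs = _signed_ranks(d)
    n = len(ranks)
    w = float(ranks[signs > 0].sum())
    if mode == "exact":
        if n > 25:
            raise ValidationError(
                f"exact mode enumerates 2^n sign assignments; n={n} > 25 "
                "(use mode='approximate')"
            )
        p = _wilcoxon_exact_p(ranks, w)
    elif mode == "approximate":
        mean_w = n * (n + 1) / 4.0
        var_w = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var_w -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var_w <= 0:
            raise DegenerateTestError("Wilcoxon variance is zero (all ranks tied away)")
        z = (w - mean_w) / np.sqrt(var_w)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return PairedComparisonResult(
        variable=variable,
        summary_t0=_median_iqr(np.asarray(x_t0, dtype=float)),
        summary_t6=_median_iqr(np.asarray(x_t6, dtype=float)),
        test_used="wilcoxon_signed_rank",
        estimate=float(np.median(d)),
        statistic=w,
        p_value=p,
        n=len(d),
    )


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """P(|rho| >= |rho_obs|) by full enumeration of pairings of the ranks."""
    n = len(rx)
    n_perm = math.factorial(n)
    # rho is an increasing affine function of S = sum(rx * perm(ry))
    mx, my = rx.mean(), ry.mean()
    sx = np.sqrt(((rx - mx) ** 2).sum())
    sy = np.sqrt(((ry - my) ** 2).sum())
    thresh = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    it = itertools.permutations(ry)
    chunk_size = 50_000
    while True:
        block = list(itertools.islice(it, chunk_size))
        if not block:
            break
        arr = np.asarray(block, dtype=float)
        s = arr @ rx
        rho = (s - n * mx * my) / (sx * sy)
        count += int((np.abs(rho) >= thresh).sum())
        total += len(block)
    assert total == n_perm
    return count / total


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties).

    p-value: exact permutation enumeration when n <= 10 and neither input
    has ties; otherwise the two-sided t approximation on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-d and of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("need n >= 3 for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 10 and no_ties:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n)


def _fmt(v: float) -> str:
    return f"{v:.4g}"


def _mean_sd(x: np.ndarray) -> str:
    return f"{_fmt(x.mean())} ± {_fmt(x.std(ddof=1))}"


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # type-7 interpolation
    return f"{_fmt(med)} [{_fmt(q1)};{_fmt(q3)}]"


def is_normal(values, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk normality decision on the pooled values."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return False
    return stats.shapiro(values).pvalue > alpha


def summarize_cohort(
    cohort: LongitudinalDataset,
    variables: Sequence[str] | None = None,
    alpha: float = 0.05,
    overrides: Mapping[str, str] | None = None,
    wilcoxon_mode: Literal["exact", "approximate"] = "exact",
) -> pd.DataFrame:
    """Pre/post comparison table: one row per variable.

    Numeric variables are routed by a Shapiro-Wilk normality check on the
    pooled values (threshold ``alpha``): normal -> mean +/- SD with the
    paired t-test, otherwise median [Q1;Q3] with the Wilcoxon signed-rank
    test. ``overrides`` forces ``"paired_t"`` or ``"wilcoxon"`` per
    variable. Categorical variables get frequency summaries and no test.
    """
    overrides = dict(overrides or {})
    if variables is None:
        reserved = {ds.SUBJECT, ds.TIMEPOINT}
        variables = [c for c in cohort.data.columns if c not in reserved]
    rows = []
    for var in variables:
        col = cohort.data[var]
        if not pd.api.types.is_numeric_dtype(col):
            t0 = cohort.timepoint("T0")[var]
            t6 = cohort.timepoint("T6")[var]
            rows.append(
                PairedComparisonResult(
                    variable=var,
                    summary_t0=_freq(t0),
                    summary_t6=_freq(t6),
                    test_used="none",
                    estimate=float("nan"),
                    statistic=float("nan"),
                    p_value=float("nan"),
                    n=len(t0),
                )
            )
            continue
        x0, x6 = cohort.paired(var)
        choice = overrides.get(var)
        if choice is None:
            choice = "paired_t" if is_normal(col.to_numpy(), alpha=alpha) else "wilcoxon"
        try:
            if choice == "paired_t":
                res = paired_t_test(x0, x6, variable=var)
            elif choice in ("wilcoxon", "wilcoxon_signed_rank"):
                res = wilcoxon_signed_rank(x0, x6, mode=wilcoxon_mode, variable=var)
            else:
                raise ValidationError(f"unknown test override {choice!r} for {var!r}")
        except DegenerateTestError:
            res = PairedComparisonResult(
                variable=var,
                summary_t0=_mean_sd(x0),
                summary_t6=_mean_sd(x6),
                test_used="none",
                estimate=float(np.mean(x6 - x0)),
                statistic=float("nan"),
                p_value=float("nan"),
                n=len(x0),
            )
        rows.append(res)
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "summary_t0": [r.summary_t0 for r in rows],
            "summary_t6": [r.summary_t6 for r in rows],
            "test": [r.test_used for r in rows],
            "estimate": [r.estimate for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_value": [r.p_value for r in rows],
            "n": [r.n for r in rows],
        }
    )


def _freq(values: pd.Series) -> str:
    counts = values.value_counts().sort_index()
    n = counts.sum()
    return "; ".join(f"{k}: {v} ({100*v/n:.0f}%)" for k, v in counts.items())


def age_correlations(cohort: LongitudinalDataset) -> pd.DataFrame:
    """Spearman correlation of chronological vs DNAm age, per timepoint."""
    if ds.DNAM_AGE not in cohort.data.columns:
        raise ValidationError(f"column {ds.DNAM_AGE!r} missing; run the clock first")
    rows = []
    for tp in ds.TIMEPOINTS:
        sub = cohort.timepoint(tp)
        res = spearman(sub[ds.AGE], sub[ds.DNAM_AGE])
        rows.append({"timepoint": tp, "rho": res.rho, "p_value": res.p_value, "n": res.n})
    return pd.DataFrame(rows)
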