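"""Longitudinal paired-cohort container.

The canonical in-memory representation is a long-format pandas DataFrame:
one row per subject x timepoint, with columns

    subject_id, timepoint (T0/T6), age_years, <methylation columns>,
    <covariate columns>, and optionally dnam_age / age_acceleration.

:class:`LongitudinalDataset` is a thin validated wrapper: construction
checks the complete-pairs design (every subject present at exactly T0 and
T6) that the paired statistics and random-intercept models rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

SUBJECT = "subject_id"
TIMEPOINT = "timepoint"
AGE = "age_years"
DNAM_AGE = "dnam_age"
ACCEL = "age_acceleration"

TIMEPOINTS = ("T0", "T6")

#: methylation columns of the default clock, by gene alias
METH_COLUMNS = ("ELOVL2", "C1orf132", "TRIM59", "KLF14", "FHL2")


@dataclass(frozen=True)
class LongitudinalDataset:
    """A validated paired pre/post cohort in long format."""

    data: pd.DataFrame

    def __post_init__(self):
        validate_longitudinal(self.data)

    @property
    def subjects(self) -> list:
        return sorted(self.data[SUBJECT].unique().tolist())

    @property
    def n_subjects(self) -> int:
        return self.data[SUBJECT].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def timepoint(self, tp: str) -> pd.DataFrame:
        """Rows for one timepoint, ordered by subject."""
        if tp not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {tp!r}; expected one of {TIMEPOINTS}")
        return (
            self.data[self.data[TIMEPOINT] == tp]
            .sort_values(SUBJECT, kind="stable")
            .reset_index(drop=True)
        )

    def paired(self, column: str) -> tuple[np.ndarray, np.ndarray]:
        """Subject-aligned (T0, T6) value arrays for ``column``."""
        t0 = self.timepoint("T0")
        t6 = self.timepoint("T6")
        if column not in self.data.columns:
            raise ValidationError(f"column {column!r} not in dataset")
        return t0[column].to_numpy(), t6[column].to_numpy()

    def with_columns(self, **columns) -> "LongitudinalDataset":
        """A copy with extra/replaced columns (index-aligned)."""
        return LongitudinalDataset(self.data.assign(**columns))


def validate_longitudinal(data: pd.DataFrame) -> None:
    """Check the paired long-format contract; raise ValidationError listing offenders."""
    for col in (SUBJECT, TIMEPOINT, AGE):
        if col not in data.columns:
            raise ValidationError(f"required column {col!r} missing")
    bad_tp = sorted(set(data[TIMEPOINT].unique()) - set(TIMEPOINTS))
    if bad_tp:
        raise ValidationError(
            f"unknown timepoint labels {bad_tp}; expected {list(TIMEPOINTS)}"
        )
    counts = data.groupby([SUBJECT, TIMEPOINT]).size()
    dup = counts[counts > 1]
    if len(dup):
        raise ValidationError(
            "duplicated subject x timepoint rows: "
            + ", ".join(f"{s}/{t}" for s, t in dup.index[:10])
        )
    per_subject = data.groupby(SUBJECT)[TIMEPOINT].agg(set)
    incomplete = per_subject[per_subject != set(TIMEPOINTS)]
    if len(incomplete):
        missing = {
            s: sorted(set(TIMEPOINTS) - tps) for s, tps in incomplete.items()
        }
        raise ValidationError(
            "subjects without complete T0/T6 pairs: "
            + ", ".join(f"{s} missing {m}" for s, m in list(missing.items())[:10])
        )
    ages = data[AGE].to_numpy(dtype=float)
    if not np.all(np.isfinite(ages)) or np.any(ages <= 0):
        bad_rows = data.index[~(np.isfinite(ages) & (ages > 0))].tolist()
        raise ValidationError(f"non-positive or missing {AGE} at rows {bad_rows[:10]}")
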