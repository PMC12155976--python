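import numpy as np
import pandas as pd
import pytest

import epiaccel as ea
from epiaccel import dataset as ds


@pytest.fixture(scope="session")
def clock():
    return ea.default_clock()


@pytest.fixture(scope="session")
def cohort10():
    """Default-condition synthetic cohort (n=10), fixed seed."""
    return ea.generate_cohort(ea.CohortParams(n_subjects=10, seed=42))


@pytest.fixture(scope="session")
def scored10(cohort10):
    """The same cohort with DNAm age and pooled age acceleration attached."""
    lds = cohort10.dataset.with_columns(dnam_age=ea.batch_compute(cohort10.dataset.data))
    lds, fit = ea.add_age_acceleration(lds, scope="pooled")
    return lds, fit


def make_paired_frame(accel_t0, accel_t6, covariate=None):
    """Minimal paired long-format frame with a given acceleration response."""
    accel_t0 = np.asarray(accel_t0, dtype=float)
    accel_t6 = np.asarray(accel_t6, dtype=float)
    n = len(accel_t0)
    subjects = [f"S{i:03d}" for i in range(n)]
    rows = []
    for j, (tp, vals) in enumerate((("T0", accel_t0), ("T6", accel_t6))):
        for i in range(n):
            row = {
                ds.SUBJECT: subjects[i],
                ds.TIMEPOINT: tp,
                ds.AGE: 8.0 + i * 0.5 + 0.5 * j,
                ds.ACCEL: vals[i],
            }
            if covariate is not None:
                row["cov"] = float(covariate[j][i])
            rows.append(row)
    return ds.LongitudinalDataset(pd.DataFrame(rows))
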