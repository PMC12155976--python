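#!/usr/bin/env python
"""Residual age acceleration: regress DNAm age on chronological age (pooled).

Reads results/ages.csv, writes results/accel.csv with the per-observation
residuals. With a pooled fit over complete pairs the T0 and T6 group means
are equal in magnitude and opposite in sign by construction.
"""

from pathlib import Path

import epiaccel as ea
from epiaccel import dataset as ds

RESULTS = Path("results")


def main() -> None:
    src = RESULTS / "ages.csv"
    if not src.exists():
        raise SystemExit("run analysis/02_compute_dnam_age.py first")
    cohort = ea.read_cohort_csv(src)
    cohort, fit = ea.add_age_acceleration(cohort, scope="pooled")
    ea.write_cohort_csv(cohort, RESULTS / "accel.csv")

    print(f"age regression ({fit.scope}, n={fit.n_obs}): "
          f"DNAm age = {fit.intercept:.3f} + {fit.slope:.3f} x age")
    m = cohort.data.groupby(ds.TIMEPOINT)[ds.ACCEL].agg(["mean", "std"])
    for tp, row in m.iterrows():
        print(f"  acceleration at {tp}: {row['mean']:+.2f} +/- {row['std']:.2f} years")
    print(f"wrote {RESULTS/'accel.csv'}")


if __name__ == "__main__":
    main()
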