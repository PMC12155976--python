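#!/usr/bin/env python
"""Evaluate the five-CpG DNAm-age clock on the simulated cohort.

Reads results/cohort.csv, appends a dnam_age column, writes
results/ages.csv.
"""

from pathlib import Path

import epiaccel as ea

RESULTS = Path("results")


def main() -> None:
    src = RESULTS / "cohort.csv"
    if not src.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    cohort = ea.read_cohort_csv(src)
    clock = ea.default_clock()
    cohort = cohort.with_columns(dnam_age=ea.batch_compute(cohort.data, clock))
    ea.write_cohort_csv(cohort, RESULTS / "ages.csv")

    for tp in ("T0", "T6"):
        sub = cohort.timepoint(tp)
        print(f"  {tp}: chronological {sub.age_years.mean():5.2f} years, "
              f"DNAm age {sub.dnam_age.mean():5.2f} years (n={len(sub)})")
    print(f"wrote {RESULTS/'ages.csv'}")


if __name__ == "__main__":
    main()
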