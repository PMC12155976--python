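#!/usr/bin/env python
"""Paired pre/post comparison table and chronological-vs-DNAm-age correlations.

Reads results/accel.csv; writes results/table1.csv (per-variable summary +
paired test routed by a Shapiro-Wilk normality check) and
results/fig1_correlations.csv (per-timepoint Spearman rho).
"""

from pathlib import Path

import epiaccel as ea
from epiaccel import dataset as ds
from epiaccel.io import write_table

RESULTS = Path("results")


def main() -> None:
    src = RESULTS / "accel.csv"
    if not src.exists():
        raise SystemExit("run analysis/03_age_acceleration.py first")
    cohort = ea.read_cohort_csv(src)

    variables = [ds.AGE, ds.DNAM_AGE, ds.ACCEL, "sex", "igf1", "glucose_mgdl",
                 "insulin_mUl", "homa_ir", "hv_cmyr", "hv_sds", "height_sds",
                 "tc_mgdl", "hdl_mgdl", "ldl_mgdl", "tg_mgdl", "crp_mgdl",
                 "hba1c_pct"]
    table1 = ea.summarize_cohort(cohort, variables=variables)
    write_table(table1, RESULTS / "table1.csv")
    print("paired pre/post comparisons (summary T0 | T6 | test | p):")
    for _, r in table1.iterrows():
        p = "" if r.test == "none" else f"p={r.p_value:.4f} ({r.test})"
        print(f"  {r['variable']:<16} {r.summary_t0:>22} | {r.summary_t6:>22}  {p}")

    corr = ea.age_correlations(cohort)
    write_table(corr, RESULTS / "fig1_correlations.csv")
    for _, r in corr.iterrows():
        print(f"chronological vs DNAm age at {r.timepoint}: "
              f"Spearman rho={r.rho:.2f}, p={r.p_value:.4f} (n={r.n})")
    print(f"wrote {RESULTS/'table1.csv'} and {RESULTS/'fig1_correlations.csv'}")


if __name__ == "__main__":
    main()
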