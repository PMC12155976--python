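"""End-to-end pipeline: clock -> acceleration -> descriptives -> mixed models.

``run_pipeline`` wires the stages in order and writes one CSV per result
table. All output content is deterministic for a fixed config and seed
(wall-clock timing is reported on stderr only, never written to output
files, so reruns are byte-identical).
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dataset as ds
from .acceleration import add_age_acceleration
from .clock import batch_compute, default_clock, load_clock
from .descriptives import age_correlations, summarize_cohort
from .errors import ValidationError
from .io import PipelineConfig, read_cohort_csv, write_cohort_csv, write_table
from .mixed_models import (
    fit_adjusted_model,
    fit_change_model,
    fit_interaction_model,
    marginal_means,
)
from .synthetic import CohortParams, generate_cohort

_PKG_VERSION = "0.1.0"


@dataclass
class RunLog:
    """Per-stage records of a pipeline run.

    The persisted JSON holds stage names, the config hash, package
    versions and warnings — no wall-clock timestamps, so logs from
    identical runs are identical. Durations go to stderr.
    """

    config_digest: str
    records: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, message: str) -> None:
        self.records.append({"stage": stage, "message": message})
        print(f"[epiaccel] {stage}: {message}", file=sys.stderr)

    def warn(self, stage: str, message: str) -> None:
        self.warnings.append(f"{stage}: {message}")
        print(f"[epiaccel] WARNING {stage}: {message}", file=sys.stderr)

    def to_json(self) -> str:
        return json.dumps(
            {
                "package": {"name": "epiaccel", "version": _PKG_VERSION},
                "config_digest": self.config_digest,
                "stages": self.records,
                "warnings": self.warnings,
            },
            indent=2,
        )


def effect_row(covariate: str, label: str, eff) -> dict:
    return {
        "covariate": covariate,
        "term": label,
        "beta": eff.beta,
        "se": eff.se,
        "ci_low": eff.ci_low,
        "ci_high": eff.ci_high,
        "p_value": eff.p_value,
    }


def run_pipeline(config: PipelineConfig) -> RunLog:
    """Run every stage and write the result CSVs under ``config.outdir``."""
    t_start = time.perf_counter()
    log = RunLog(config_digest=config.digest())
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    clock = default_clock() if config.clock == "default" else load_clock(config.clock)

    # --- load or simulate ---------------------------------------------------
    if config.input_csv is not None:
        cohort = read_cohort_csv(config.input_csv)
        log.record("load", f"read {cohort.n_obs} rows / {cohort.n_subjects} subjects")
    else:
        params = CohortParams(n_subjects=config.n_subjects, seed=config.seed)
        syn = generate_cohort(params, clock)
        cohort = syn.dataset
        (outdir / "truth.json").write_text(syn.truth.to_json() + "\n")
        log.record("simulate", f"generated {cohort.n_subjects}-subject synthetic cohort")

    unknown = [c for c in config.covariates if c not in cohort.data.columns]
    unknown += [c for c in config.marginal_means if c not in cohort.data.columns]
    if unknown:
        raise ValidationError(f"unknown covariates in config: {sorted(set(unknown))}")

    # --- clock --------------------------------------------------------------
    cohort = cohort.with_columns(dnam_age=batch_compute(cohort.data, clock))
    write_cohort_csv(cohort, outdir / "ages.csv")
    log.record("compute-age", f"DNAm age for {cohort.n_obs} observations")

    # --- acceleration -------------------------------------------------------
    cohort, fit = add_age_acceleration(cohort, scope=config.residual_scope)
    accel_cols = [ds.SUBJECT, ds.TIMEPOINT, ds.AGE, ds.DNAM_AGE, ds.ACCEL]
    write_table(cohort.data[accel_cols], outdir / "accel.csv")
    log.record(
        "accel",
        f"residual regression ({fit.scope}): slope {fit.slope:.4f}, "
        f"intercept {fit.intercept:.4f}, n={fit.n_obs}",
    )

    # --- descriptives -------------------------------------------------------
    variables = [ds.AGE, ds.DNAM_AGE, ds.ACCEL, "sex"] + [
        c
        for c in cohort.data.columns
        if c not in (ds.SUBJECT, ds.TIMEPOINT, ds.AGE, ds.DNAM_AGE, ds.ACCEL, "sex")
        and c not in ds.METH_COLUMNS
    ]
    table1 = summarize_cohort(
        cohort,
        variables=variables,
        alpha=config.normality_alpha,
        overrides=config.test_overrides,
    )
    write_table(table1, outdir / "table1.csv")
    fig1 = age_correlations(cohort)
    write_table(fig1, outdir / "fig1_correlations.csv")
    log.record("descriptives", f"{len(table1)} variables summarized")

    # --- mixed models -------------------------------------------------------
    kwargs = dict(df_method=config.df_method, ci_level=config.ci_level)

    t2_rows = []
    uni = fit_change_model(cohort, **kwargs)
    t2_rows.append(effect_row("", "T6-T0 (univariate)", uni.time_contrast))
    if uni.fit.singular:
        log.warn("mixed-models", "univariate change model: singular random-effect variance")
    for cov in config.marginal_means:
        adj = fit_change_model(cohort, covariate=cov, **kwargs)
        t2_rows.append(effect_row(cov, f"T6-T0 (adjusted for {cov})", adj.time_contrast))
        if adj.fit.singular:
            log.warn("mixed-models", f"change model adjusted for {cov}: singular fit")
    write_table(pd.DataFrame(t2_rows), outdir / "table2.csv")

    t3_rows = []
    t4_rows = []
    for cov in config.covariates:
        inter = fit_interaction_model(cohort, cov, **kwargs)
        for label, eff in (("effect at T0", inter.effect_at_t0), ("effect at T6", inter.effect_at_t6)):
            row = effect_row(cov, label, eff)
            row["interaction_p"] = inter.interaction_p
            t3_rows.append(row)
        adj = fit_adjusted_model(cohort, cov, **kwargs)
        t4_rows.append(effect_row(cov, "adjusted for time", adj.covariate_effect))
    t3_cols = ["covariate", "term", "beta", "se", "ci_low", "ci_high", "p_value", "interaction_p"]
    write_table(pd.DataFrame(t3_rows, columns=t3_cols), outdir / "table3.csv")
    t4_cols = ["covariate", "term", "beta", "se", "ci_low", "ci_high", "p_value"]
    write_table(pd.DataFrame(t4_rows, columns=t4_cols), outdir / "table4.csv")
    log.record(
        "mixed-models",
        f"tables 2-4 for {len(config.covariates)} covariates",
    )

    # --- marginal means -----------------------------------------------------
    mm_rows = []
    for cov, fixed in config.marginal_means.items():
        mm = marginal_means(cohort, cov, fixed, **kwargs)
        for tp, eff in (("T0", mm.mean_t0), ("T6", mm.mean_t6)):
            mm_rows.append(
                {
                    "covariate": cov,
                    "fixed_value": fixed,
                    "timepoint": tp,
                    "mean": eff.beta,
                    "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high,
                    "comparison_p": mm.p_value,
                }
            )
    mm_cols = ["covariate", "fixed_value", "timepoint", "mean", "ci_low", "ci_high", "comparison_p"]
    write_table(pd.DataFrame(mm_rows, columns=mm_cols), outdir / "fig2_marginal_means.csv")
    log.record("marginal-means", f"{len(config.marginal_means)} covariate(s)")

    (outdir / "runlog.json").write_text(log.to_json() + "\n")
    print(
        f"[epiaccel] done in {time.perf_counter() - t_start:.2f}s -> {outdir}",
        file=sys.stderr,
    )
    return log
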