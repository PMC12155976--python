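"""CSV readers/writers and pipeline configuration.

The canonical interchange is a single long-format UTF-8 CSV (one row per
subject x timepoint). All result tables are written with at least 10
significant digits so downstream round trips are lossless at the
tolerances the analyses use.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import dataset as ds
from .dataset import LongitudinalDataset
from .errors import ValidationError

FLOAT_FORMAT = "%.10g"


def read_cohort_csv(path: str | Path) -> LongitudinalDataset:
    """Read and validate a long-format cohort CSV.

    Checks the complete-pairs contract and, for any methylation columns
    recognized by the default clock's gene aliases, the [0, 100] percent
    range; errors name the offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file {path} does not exist")
    data = pd.read_csv(path)
    for col in ds.METH_COLUMNS:
        if col in data.columns:
            bad = data.index[(data[col] < 0) | (data[col] > 100) | data[col].isna()]
            if len(bad):
                raise ValidationError(
                    f"methylation column {col!r} outside [0, 100] at rows "
                    f"{bad.tolist()[:10]}"
                )
    return LongitudinalDataset(data)


def write_cohort_csv(cohort: LongitudinalDataset, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.data.to_csv(path, index=False, float_format="%.12g")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the end-to-end analysis run."""

    input_csv: str | None = None  # None -> simulate a synthetic cohort
    outdir: str = "results"
    clock: str = "default"  # "default" or a clock JSON path
    residual_scope: str = "pooled"
    normality_alpha: float = 0.05
    test_overrides: Mapping[str, str] = field(default_factory=dict)
    covariates: Sequence[str] = ("igf1",)
    marginal_means: Mapping[str, float] = field(default_factory=lambda: {"igf1": 120.0})
    df_method: str = "between-within"
    ci_level: float = 0.95
    seed: int = 0
    n_subjects: int = 10

    def __post_init__(self):
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError("ci_level must be in (0, 1)")
        if self.residual_scope not in ("pooled", "baseline_only"):
            raise ValidationError(f"unknown residual scope {self.residual_scope!r}")
        if self.clock != "default" and not Path(self.clock).exists():
            raise ValidationError(f"clock file {self.clock!r} does not exist")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ValidationError(f"input file {self.input_csv!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "input_csv": self.input_csv,
            "outdir": self.outdir,
            "clock": self.clock,
            "residual_scope": self.residual_scope,
            "normality_alpha": self.normality_alpha,
            "test_overrides": dict(self.test_overrides),
            "covariates": list(self.covariates),
            "marginal_means": dict(self.marginal_means),
            "df_method": self.df_method,
            "ci_level": self.ci_level,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
        }

    def digest(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
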