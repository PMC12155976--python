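"""Linear DNA-methylation age clocks.

A clock is an affine score over CpG methylation levels measured in
percentage points (0-100):

    DNAm age = intercept + sum_i coefficient_i * methylation_i

The built-in default is a five-CpG blood clock (ELOVL2, C1orf132/MIR29B2C,
TRIM59, KLF14, FHL2) whose constants are stored as decimal strings in a
packaged JSON file and parsed at load time, so the 15-digit coefficients
are never retyped in code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import MethylationRangeError, MissingSiteError, ValidationError

__all__ = [
    "ClockSite",
    "ClockModel",
    "MethylationProfile",
    "default_clock",
    "load_clock",
    "compute_dnam_age",
    "batch_compute",
]


@dataclass(frozen=True)
class ClockSite:
    """One CpG site of a linear clock.

    ``coefficient`` is in years of DNAm age per percentage-point
    methylation; ``coefficient_str`` preserves the exact decimal string it
    was parsed from, so a clock round-trips through serialization without
    drift.
    """

    site_key: str
    gene: str
    coefficient: float
    coefficient_str: str

    def __post_init__(self):
        if not np.isfinite(self.coefficient):
            raise ValidationError(f"coefficient for {self.site_key!r} is not finite")


@dataclass(frozen=True)
class ClockModel:
    """An affine DNAm-age model over a fixed panel of CpG sites."""

    name: str
    intercept: float
    intercept_str: str
    sites: tuple[ClockSite, ...]
    description: str = ""

    def __post_init__(self):
        keys = [s.site_key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValidationError("clock site keys must be unique")
        if not np.isfinite(self.intercept):
            raise ValidationError("clock intercept is not finite")

    @property
    def site_keys(self) -> tuple[str, ...]:
        return tuple(s.site_key for s in self.sites)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(s.gene for s in self.sites)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([s.coefficient for s in self.sites])

    def coefficient(self, key: str) -> float:
        return self.site(key).coefficient

    def site(self, key: str) -> ClockSite:
        key = self.resolve_key(key)
        for s in self.sites:
            if s.site_key == key:
                return s
        raise MissingSiteError(key, context="unknown clock site")

    def resolve_key(self, key_or_gene: str) -> str:
        """Map a gene symbol alias (e.g. ``"KLF14"``) to its site key."""
        keys = {s.site_key for s in self.sites}
        if key_or_gene in keys:
            return key_or_gene
        aliases = {s.gene: s.site_key for s in self.sites}
        if key_or_gene in aliases:
            return aliases[key_or_gene]
        raise MissingSiteError(key_or_gene, context="unknown clock site or gene alias")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "intercept": self.intercept_str,
            "sites": [
                {"key": s.site_key, "gene": s.gene, "coefficient": s.coefficient_str}
                for s in self.sites
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass(frozen=True)
class MethylationProfile:
    """Methylation values (percentage points) for one sample."""

    sample_id: str
    values: Mapping[str, float] = field(default_factory=dict)

    def value(self, site_key: str) -> float:
        try:
            return float(self.values[site_key])
        except KeyError:
            raise MissingSiteError(site_key, context=f"sample {self.sample_id!r}") from None


def _clock_from_dict(d: dict) -> ClockModel:
    sites = tuple(
        ClockSite(
            site_key=s["key"],
            gene=s.get("gene", s["key"]),
            coefficient=float(s["coefficient"]),
            coefficient_str=str(s["coefficient"]),
        )
        for s in d["sites"]
    )
    return ClockModel(
        name=d.get("name", "custom"),
        intercept=float(d["intercept"]),
        intercept_str=str(d["intercept"]),
        sites=sites,
        description=d.get("description", ""),
    )


def load_clock(path: str | Path) -> ClockModel:
    """Load a clock definition from a JSON file (coefficients as strings)."""
    with open(path) as fh:
        return _clock_from_dict(json.load(fh))


def default_clock() -> ClockModel:
    """The packaged five-CpG blood clock.

    Returns the clock with its printed intercept and coefficients at full
    decimal precision, sites in canonical order (ELOVL2, C1orf132, TRIM59,
    KLF14, FHL2).
    """
    ref = resources.files("epiaccel.data").joinpath("default_clock.json")
    clock = _clock_from_dict(json.loads(ref.read_text()))
    if len(clock.sites) != 5:
        raise ValidationError("default clock must have exactly 5 sites")
    return clock


def _check_value(key: str, v: float, context: str = "") -> float:
    v = float(v)
    if not np.isfinite(v) or v < 0.0 or v > 100.0:
        raise MethylationRangeError(key, v, context)
    return v


def compute_dnam_age(profile: MethylationProfile, clock: ClockModel | None = None) -> float:
    """Evaluate the clock on one methylation profile.

    Parameters
    ----------
    profile
        Methylation values keyed by site key (or gene alias).
    clock
        Clock model; the packaged default when omitted.

    Returns
    -------
    float
        DNAm age in years: ``intercept + sum(coef * methylation)``.

    Raises
    ------
    MissingSiteError
        If a clock site is absent from the profile.
    MethylationRangeError
        If any value falls outside [0, 100]. Values are never clamped.
    """
    if clock is None:
        clock = default_clock()
    # accept gene aliases transparently
    resolved = {}
    for k, v in profile.values.items():
        try:
            resolved[clock.resolve_key(k)] = v
        except MissingSiteError:
            resolved[k] = v  # extra, non-clock keys are ignored
    age = clock.intercept
    for s in clock.sites:
        if s.site_key not in resolved:
            raise MissingSiteError(s.site_key, context=f"sample {profile.sample_id!r}")
        v = _check_value(s.site_key, resolved[s.site_key], context=f"sample {profile.sample_id!r}")
        age += s.coefficient * v
    return age


def batch_compute(
    data: pd.DataFrame,
    clock: ClockModel | None = None,
    columns: Iterable[str] | None = None,
) -> pd.Series:
    """Evaluate the clock on every row of a long-format table.

    ``data`` must carry one methylation column per clock site, named by
    site key or gene alias. Returns a Series ``dnam_age`` aligned with
    ``data``; equals element-wise :func:`compute_dnam_age`.
    """
    if clock is None:
        clock = default_clock()
    colmap: dict[str, str] = {}
    cols = list(columns) if columns is not None else list(data.columns)
    for c in cols:
        try:
            colmap[clock.resolve_key(str(c))] = c
        except MissingSiteError:
            continue
    missing = [k for k in clock.site_keys if k not in colmap]
    if missing:
        raise MissingSiteError(missing[0], context="no matching column in table")

    vals = data[[colmap[k] for k in clock.site_keys]].to_numpy(dtype=float)
    bad = ~np.isfinite(vals) | (vals < 0.0) | (vals > 100.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        key = clock.site_keys[j]
        raise MethylationRangeError(key, vals[i, j], context=f"row {data.index[i]!r}")
    ages = clock.intercept + vals @ clock.coefficients
    return pd.Series(ages, index=data.index, name="dnam_age")
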