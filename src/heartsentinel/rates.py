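"""Rate engine: stratum rates per 100 000 and direct age standardization.

Rates are simple count/population ratios scaled to 100 000 person-years,
with SEs scaled from the count SDs.  Age standardization uses the direct
method: a weighted average of age-specific rates under a fixed standard
population, with the variance of the standardized rate taken as the
weight-squared sum of the age-specific variances (age groups treated as
independent) and symmetric normal 95% intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from importlib import resources

from .strata import AGE_GROUPS

__all__ = [
    "StandardPopulation", "default_standard_population", "compute_rates",
    "age_standardize", "relative_change", "category_share",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class StandardPopulation:
    """Fixed age distribution (proportions over the four age groups)."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.weights) != set(AGE_GROUPS):
            raise ValueError(f"standard population must cover exactly {AGE_GROUPS}")
        w = np.array(list(self.weights.values()))
        if (w < 0).any():
            raise ValueError("standard population weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("standard population weights must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StandardPopulation":
        with open(path) as fh:
            return cls({str(k): float(v) for k, v in yaml.safe_load(fh).items()})


def default_standard_population() -> StandardPopulation:
    """Approximate 2010 US decennial census adult age distribution."""
    ref = resources.files("heartsentinel").joinpath("data/standard_population.yaml")
    return StandardPopulation({str(k): float(v) for k, v in yaml.safe_load(ref.read_text()).items()})


def compute_rates(counts: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Rates per 100 000 with SEs from combined counts and denominators.

    ``counts`` must have (year, sex, age_group, count, sd); ``population``
    must supply a population row for every count row.
    """
    keys = ["year", "sex", "age_group"]
    merged = counts.merge(population[keys + ["population"]], on=keys, how="left")
    if merged["population"].isna().any():
        missing = merged.loc[merged["population"].isna(), keys].drop_duplicates()
        raise ValueError(f"missing population rows:\n{missing}")
    if (merged["population"] <= 0).any():
        raise ValueError("non-positive population")
    merged["rate"] = 1e5 * merged["count"] / merged["population"]
    merged["se"] = 1e5 * merged["sd"] / merged["population"]
    return merged[keys + ["rate", "se", "population", "count", "sd"]]


def age_standardize(rates: pd.DataFrame, std: StandardPopulation) -> tuple[float, float, float]:
    """Directly age-standardize one year/scope's age-specific rates.

    ``rates`` holds exactly one row per age group with ``rate`` and ``se``
    columns.  Returns (standardized rate, ci_low, ci_high).
    """
    if sorted(rates["age_group"]) != sorted(AGE_GROUPS):
        raise ValueError("need exactly one rate per age group")
    idx = rates.set_index("age_group")
    w = np.array([std.weights[a] for a in AGE_GROUPS])
    r = idx.loc[list(AGE_GROUPS), "rate"].to_numpy(dtype=float)
    se = idx.loc[list(AGE_GROUPS), "se"].to_numpy(dtype=float)
    rate = float(w @ r)
    std_se = float(np.sqrt(np.sum(w**2 * se**2)))
    return rate, rate - Z95 * std_se, rate + Z95 * std_se


def relative_change(rate_start: float, rate_end: float) -> float:
    """Percent change between two rates: 100 x (end - start) / start."""
    if rate_start <= 0:
        raise ValueError("relative change undefined for non-positive start rate")
    return 100.0 * (rate_end - rate_start) / rate_start


def category_share(part: float, whole: float) -> float:
    """Percent contribution of a part to a whole count."""
    if whole <= 0:
        raise ValueError("share undefined for non-positive whole")
    if part < 0 or part > whole:
        raise ValueError("part must lie in [0, whole]")
    return 100.0 * part / whole
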