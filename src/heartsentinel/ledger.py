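"""Event ledger: classification, exclusion cascade, tabulation, combination.

The ledger turns raw encounter records into mutually exclusive event
counts.  Records are first classified against the active case definition
(prefix match on normalized codes, per code system).  A disposition-based
exclusion cascade then prevents one clinical episode from being counted
in two sources: ED visits that ended in death in the ED, transfer to
another hospital, or admission to the same hospital are dropped (the
episode surfaces in the hospitalization or death file instead), as are
hospitalizations flagged elective, in-hospital death, or transfer-out.
Death-certificate records are never excluded.  Surviving records are
tabulated as weighted counts per (year, stratum, source, category) with a
standard deviation attached per the configured per-source variance model,
and source counts are combined into mutually exclusive totals whose
variances add under independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .definitions import CaseDefinitionSet
from .strata import ED_EXCLUSION_FLAGS, HOSP_EXCLUSION_FLAGS, KNOWN_FLAGS, SOURCES

__all__ = [
    "SdModel", "default_variance_model", "poisson_variance_model",
    "classify_event", "classify_records", "apply_exclusions",
    "tabulate_counts", "attach_sd", "combine_sources",
]


@dataclass(frozen=True)
class SdModel:
    """How to attach an SD to a weighted count for one source.

    kind 'relative': sd = value * count (survey-style relative SE);
    kind 'poisson':  sd = sqrt(count);
    kind 'zero':     sd = 0 (near-census source).
    """

    kind: str
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("relative", "poisson", "zero"):
            raise ValueError(f"unknown sd model kind {self.kind!r}")
        if self.kind == "relative" and self.value < 0:
            raise ValueError("relative SE must be non-negative")

    def sd(self, count: np.ndarray | float) -> np.ndarray | float:
        if self.kind == "relative":
            return self.value * count
        if self.kind == "poisson":
            return np.sqrt(count)
        return np.zeros_like(np.asarray(count, dtype=float)) if np.ndim(count) else 0.0


def default_variance_model() -> dict[str, SdModel]:
    """Survey-flavoured defaults: ED 3% relative SE, hospitalization
    near-census (sd 0), deaths 0.5% relative SE for registry process error."""
    return {
        "ed": SdModel("relative", 0.03),
        "hospitalization": SdModel("zero"),
        "death": SdModel("relative", 0.005),
    }


def poisson_variance_model() -> dict[str, SdModel]:
    """sd = sqrt(count) for every source; the attribution that matches the
    synthetic generator's Poisson noise, used in calibration studies."""
    return {src: SdModel("poisson") for src in SOURCES}


def classify_event(code: str, source: str, defs: CaseDefinitionSet) -> tuple[str, str] | None:
    """Classify one code against the case definition; None if not a case."""
    if not code:
        return None
    return defs.classify(code, source)


def classify_records(records: pd.DataFrame, defs: CaseDefinitionSet) -> pd.DataFrame:
    """Vectorized classification: returns case records with added
    ``category`` and ``subtype`` columns; non-case records are dropped."""
    out = records.copy()
    cache: dict[tuple[str, str], tuple[str, str] | None] = {}

    def lookup(code: str, source: str):
        key = (code, source)
        if key not in cache:
            cache[key] = classify_event(code, source, defs)
        return cache[key]

    pairs = [lookup(c, s) for c, s in zip(records["code"], records["source"])]
    mask = np.array([p is not None for p in pairs])
    out = out.loc[mask].copy()
    out["category"] = [p[0] for p in pairs if p is not None]
    out["subtype"] = [p[1] for p in pairs if p is not None]
    return out.reset_index(drop=True)


def _flag_sets(flags: pd.Series) -> list[frozenset[str]]:
    sets = []
    for raw in flags.fillna(""):
        tokens = frozenset(t for t in str(raw).split(";") if t)
        unknown = tokens - KNOWN_FLAGS
        if unknown:
            raise ValueError(f"unknown disposition flag token(s): {sorted(unknown)}")
        sets.append(tokens)
    return sets


def apply_exclusions(records: pd.DataFrame) -> pd.DataFrame:
    """Drop records whose disposition flags mark them as captured by
    another source; death records are always retained."""
    sets = _flag_sets(records["flags"]) if len(records) else []
    keep = np.ones(len(records), dtype=bool)
    for i, (src, flags) in enumerate(zip(records["source"], sets)):
        if src == "ed" and flags & ED_EXCLUSION_FLAGS:
            keep[i] = False
        elif src == "hospitalization" and flags & HOSP_EXCLUSION_FLAGS:
            keep[i] = False
        # death: never excluded
    return records.loc[keep].reset_index(drop=True)


def attach_sd(counts: pd.DataFrame, variance_model: dict[str, SdModel] | None = None) -> pd.DataFrame:
    """Attach the configured per-source SD to a counts frame in place of,
    or alongside, an existing ``sd`` column."""
    model = variance_model or default_variance_model()
    out = counts.copy()
    sd = np.zeros(len(out))
    for src, m in model.items():
        mask = (out["source"] == src).to_numpy()
        sd[mask] = np.asarray(m.sd(out.loc[mask, "count"].to_numpy(dtype=float)))
    out["sd"] = sd
    return out


def tabulate_counts(
    records: pd.DataFrame,
    variance_model: dict[str, SdModel] | None = None,
) -> pd.DataFrame:
    """Sum record weights into counts per (year, stratum, source, category)
    and attach SDs.  Records must already be classified and retained."""
    if len(records) and (records["weight"].to_numpy(dtype=float) < 0).any():
        raise ValueError("negative record weight")
    if "category" not in records.columns:
        raise ValueError("records must be classified before tabulation")
    grouped = (
        records.groupby(["year", "sex", "age_group", "source", "category"], as_index=False)[
            "weight"
        ]
        .sum()
        .rename(columns={"weight": "count"})
    )
    return attach_sd(grouped, variance_model)


def rollup_categories(
    counts: pd.DataFrame, variance_model: dict[str, SdModel] | None = None
) -> pd.DataFrame:
    """Sum category counts within each (year, stratum, source) cell and
    re-derive the SD from the rolled-up count.  Category counts within one
    source share that source's design, so their errors are not independent;
    re-applying the per-source SD model to the total is the consistent
    treatment (and coincides with quadrature for the Poisson model)."""
    keys = ["year", "sex", "age_group", "source"]
    rolled = counts.groupby(keys, as_index=False)["count"].sum()
    return attach_sd(rolled, variance_model)


def combine_sources(counts: pd.DataFrame, by_category: bool = False) -> pd.DataFrame:
    """Combine per-source counts into mutually exclusive totals.

    Totals sum across sources; variances add under the independence of the
    three data systems, so sd = sqrt(sum of source variances).  At most one
    entry per (year, stratum, source[, category]) is allowed; zero entries
    mean a zero count.  If category-level rows are passed with
    ``by_category=False``, roll them up first with :func:`rollup_categories`.
    """
    keys = ["year", "sex", "age_group"] + (["category"] if by_category else [])
    work = counts.copy()
    if not by_category and "category" in work.columns and work["category"].nunique() > 1:
        raise ValueError("category-level counts: roll up with rollup_categories() first")
    if work.duplicated(subset=keys + ["source"]).any():
        raise ValueError("duplicate source entries for the same cell")
    out = work.groupby(keys, as_index=False).agg(
        count=("count", "sum"), var=("sd", lambda s: float(np.sum(np.square(s)))))
    out["sd"] = np.sqrt(out.pop("var"))
    return out
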