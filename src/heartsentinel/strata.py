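"""Sex and age-group stratification used throughout the pipeline.

Surveillance quantities are computed per stratum: sex (men/women) crossed
with four adult age groups (18-44, 45-64, 65-74, >=75) that are disjoint
and together exhaust ages >=18.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

SEXES: tuple[str, ...] = ("men", "women")
AGE_GROUPS: tuple[str, ...] = ("18-44", "45-64", "65-74", ">=75")

SOURCES: tuple[str, ...] = ("ed", "hospitalization", "death")
CATEGORIES: tuple[str, ...] = ("ami", "stroke", "symptomatic_precursor", "other_cvd")

# Disposition flags that trigger exclusion, per source.  Death-certificate
# records are never excluded.
ED_EXCLUSION_FLAGS = frozenset({"died_in_facility", "transferred_out", "admitted_same_hospital"})
HOSP_EXCLUSION_FLAGS = frozenset({"elective", "died_in_facility", "transferred_out"})
KNOWN_FLAGS = ED_EXCLUSION_FLAGS | HOSP_EXCLUSION_FLAGS


@dataclass(frozen=True, order=True)
class Stratum:
    """One sex x age-group cell."""

    sex: str
    age_group: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}; expected one of {AGE_GROUPS}")

    @property
    def label(self) -> str:
        return f"{self.sex} {self.age_group}"


def all_strata() -> list[Stratum]:
    """The eight strata in a fixed (sex, age) order."""
    return [Stratum(s, a) for s in SEXES for a in AGE_GROUPS]


def iter_strata() -> Iterator[Stratum]:
    yield from all_strata()
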