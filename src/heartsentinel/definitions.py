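"""Case definitions: ICD code lists per event category, with prefix matching.

A case definition maps each event category (ami, stroke, symptomatic
precursor, other CVD) to named subtypes, each carrying two code systems:
``ed_hosp_codes`` (primary-diagnosis prefixes for ED visits and
hospitalizations, ICD-9-CM style) and ``death_codes`` (underlying-cause
prefixes for death certificates, ICD-10 style).  Codes are normalized by
stripping dots and upper-casing before prefix comparison, so "410.71"
matches the prefix "410".

The default definition shipped with the package is editable configuration,
not authoritative: load your own YAML for real surveillance work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .strata import CATEGORIES

__all__ = [
    "CaseDefinition",
    "CaseDefinitionSet",
    "load_case_definitions",
    "default_case_definitions",
    "normalize_code",
]


def normalize_code(code: str) -> str:
    """Strip dots and upper-case, the canonical form for prefix matching."""
    return code.replace(".", "").upper().strip()


@dataclass(frozen=True)
class CaseDefinition:
    """One subtype's code lists within an event category."""

    category: str
    subtype: str
    ed_hosp_codes: tuple[str, ...]
    death_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        for codes in (self.ed_hosp_codes, self.death_codes):
            if any(not c or not c.strip() for c in codes):
                raise ValueError("code patterns must be non-empty strings")

    def codes_for(self, source: str) -> tuple[str, ...]:
        return self.death_codes if source == "death" else self.ed_hosp_codes


@dataclass
class CaseDefinitionSet:
    """All subtypes of the active case definition, validated for disjointness.

    The defining invariant is that no code prefix appears under two
    categories within the same code system; a violation makes
    classification ambiguous and is rejected at load time.
    """

    definitions: list[CaseDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate_disjoint()
        # Longest-prefix-first so a more specific pattern (e.g. 4275) wins
        # over a shorter one if both were configured within one category.
        self._index = {
            system: sorted(
                [
                    (normalize_code(code), d)
                    for d in self.definitions
                    for code in d.codes_for(system)
                ],
                key=lambda t: -len(t[0]),
            )
            for system in ("ed_hosp", "death")
        }

    def _validate_disjoint(self) -> None:
        for system in ("ed_hosp", "death"):
            seen: dict[str, str] = {}
            pats = [
                (normalize_code(c), d.category)
                for d in self.definitions
                for c in (d.death_codes if system == "death" else d.ed_hosp_codes)
            ]
            for pat, cat in pats:
                for other, other_cat in seen.items():
                    if other_cat != cat and (pat.startswith(other) or other.startswith(pat)):
                        raise ValueError(
                            f"ambiguous case definition: {system} pattern {pat!r} ({cat}) "
                            f"overlaps {other!r} ({other_cat})"
                        )
                seen[pat] = cat

    def classify(self, code: str, source: str) -> tuple[str, str] | None:
        """Return (category, subtype) for a code, or None if not a case.

        ``source`` selects the code system: death records match only
        ``death_codes``; ED and hospitalization records match only
        ``ed_hosp_codes``.
        """
        system = "death" if source == "death" else "ed_hosp"
        norm = normalize_code(code)
        for prefix, d in self._index[system]:
            if norm.startswith(prefix):
                return d.category, d.subtype
        return None

    def codes(self, category: str, source: str) -> list[str]:
        return [
            c for d in self.definitions if d.category == category for c in d.codes_for(source)
        ]

    @property
    def categories(self) -> list[str]:
        return [c for c in CATEGORIES if any(d.category == c for d in self.definitions)]


def load_case_definitions(path: str | Path) -> CaseDefinitionSet:
    """Load a case-definition YAML: category -> subtype -> code lists."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _from_mapping(raw)


def _from_mapping(raw: dict) -> CaseDefinitionSet:
    defs = []
    for category, subtypes in raw.items():
        for subtype, codes in subtypes.items():
            defs.append(
                CaseDefinition(
                    category=category,
                    subtype=subtype,
                    ed_hosp_codes=tuple(str(c) for c in codes.get("ed_hosp_codes", [])),
                    death_codes=tuple(str(c) for c in codes.get("death_codes", [])),
                )
            )
    return CaseDefinitionSet(defs)


def default_case_definitions() -> CaseDefinitionSet:
    """The editable default definition shipped with the package."""
    ref = resources.files("heartsentinel").joinpath("data/case_definitions.yaml")
    return _from_mapping(yaml.safe_load(ref.read_text()))
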