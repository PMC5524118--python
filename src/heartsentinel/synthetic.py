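"""Synthetic multi-source administrative event data with known ground truth.

Real national surveillance draws on three restricted sources: a
survey-weighted emergency-department sample, a near-census hospitalization
file, and a death registry.  This module emulates their statistical
structure so every downstream stage (classification, exclusion cascade,
tabulation, trend fitting, projection, prevented-events inference) can be
tested against known generating values without any external data.

Each stratum (sex x age group) follows a log-linear true rate trajectory:

    rate(year) = base_rate * (1 + true_apc/100) ** (year - start_year)

Events are split across sources by a fixed mix, thinned by per-source
disposition-flag probabilities (the exclusion cascade's targets), and
optionally perturbed with Poisson noise.  Two generation paths exist:

* :func:`generate_dataset` materializes encounter-level records (one row
  per ED visit / hospitalization / death) for exercising the record-level
  ledger stages;
* :func:`generate_counts` draws post-exclusion stratum-level counts
  directly (a thinned Poisson is Poisson, so the two paths share the same
  expectation) and is the fast path for Monte Carlo replicate studies.

Randomness uses one master seed with per-stratum substreams, so adding a
stratum never reshuffles the draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .definitions import CaseDefinitionSet, default_case_definitions
from .strata import (
    AGE_GROUPS,
    CATEGORIES,
    ED_EXCLUSION_FLAGS,
    HOSP_EXCLUSION_FLAGS,
    SEXES,
    SOURCES,
    Stratum,
    all_strata,
)

__all__ = ["SimConfig", "default_sim_config", "generate_dataset", "generate_counts",
           "true_parameters", "expected_counts"]

# Plausible non-CVD codes so classification has true negatives.
NONCASE_ED_HOSP_CODES = ("486", "4659", "78650", "5990", "8470")
NONCASE_DEATH_CODES = ("J189", "C349", "E119", "A419", "W19")

RECORD_COLUMNS = ["source", "year", "sex", "age_group", "code", "flags", "weight"]


@dataclass(frozen=True)
class SimConfig:
    """Generating conditions for the synthetic surveillance world.

    Rates are events per 100 000 person-years at the start year;
    ``true_apc`` is the annual percent change of the true rate;
    ``population`` is persons per stratum (held constant across years).
    ``source_mix`` gives the pre-exclusion split of case events across
    ED / hospitalization / death; ``disposition_probs`` the independent
    per-flag probabilities that drive the exclusion cascade.
    """

    years: tuple[int, int] = (2006, 2013)
    base_rate: dict[Stratum, float] = field(default_factory=dict)
    true_apc: dict[Stratum, float] = field(default_factory=dict)
    population: dict[Stratum, float] = field(default_factory=dict)
    source_mix: dict[str, float] = field(
        default_factory=lambda: {"ed": 0.121, "hospitalization": 0.742, "death": 0.137}
    )
    disposition_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "ed": {"died_in_facility": 0.01, "transferred_out": 0.03, "admitted_same_hospital": 0.25},
            "hospitalization": {"elective": 0.08, "died_in_facility": 0.04, "transferred_out": 0.03},
            "death": {},
        }
    )
    category_mix: dict[str, float] = field(
        default_factory=lambda: {"ami": 0.21, "stroke": 0.21,
                                 "symptomatic_precursor": 0.12, "other_cvd": 0.46}
    )
    ed_weight_mean: float = 4.5
    ed_weight_sigma: float = 0.3
    noncase_fraction: float = 0.10
    noise_model: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years[1] < self.years[0]:
            raise ValueError("years must be an inclusive (start, end) range")
        if abs(sum(self.source_mix.values()) - 1.0) > 1e-9:
            raise ValueError("source_mix proportions must sum to 1")
        if set(self.source_mix) != set(SOURCES):
            raise ValueError(f"source_mix must cover exactly {SOURCES}")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix proportions must sum to 1")
        for st in self.strata:
            if self.base_rate[st] <= 0:
                raise ValueError(f"non-positive base rate for {st.label}")
            if self.population[st] <= 0:
                raise ValueError(f"non-positive population for {st.label}")
        for probs in self.disposition_probs.values():
            for flag, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"disposition probability {flag}={p} outside [0, 1]")
        if self.ed_weight_mean <= 1.0:
            raise ValueError("ed_weight_mean must exceed 1 (weights are >= 1)")
        if self.noise_model not in ("poisson", "none"):
            raise ValueError("noise_model must be 'poisson' or 'none'")

    @property
    def strata(self) -> list[Stratum]:
        return sorted(self.base_rate)

    @property
    def year_range(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def true_rate(self, stratum: Stratum, year: int) -> float:
        growth = 1.0 + self.true_apc[stratum] / 100.0
        return self.base_rate[stratum] * growth ** (year - self.years[0])

    def retention(self, source: str) -> float:
        """P(record survives the exclusion cascade), flags independent."""
        exclusion = {"ed": ED_EXCLUSION_FLAGS, "hospitalization": HOSP_EXCLUSION_FLAGS,
                     "death": frozenset()}[source]
        keep = 1.0
        for flag, p in self.disposition_probs.get(source, {}).items():
            if flag in exclusion:
                keep *= 1.0 - p
        return keep

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


# Published modeled 2011 stratum rates (per 100 000) and 2006-2011 APCs from
# national surveillance; used to back-cast realistic default base rates.
_MODELED_2011 = {
    ("men", "18-44"): (152.9, -2.1),
    ("men", "45-64"): (1184.1, -1.1),
    ("men", "65-74"): (2827.4, -2.7),
    ("men", ">=75"): (7031.0, -1.7),
    ("women", "18-44"): (106.3, -1.4),
    ("women", "45-64"): (735.1, -1.7),
    ("women", "65-74"): (2069.8, -3.4),
    ("women", ">=75"): (6842.6, -1.6),
}


def default_sim_config(seed: int = 0, population: float = 1_000_000,
                       noise_model: str = "poisson") -> SimConfig:
    """Default study conditions: eight strata whose true trajectories are
    back-cast from published modeled 2011 rates and 2006-2011 APCs, on a
    synthetic population of 1e6 persons per stratum."""
    base_rate, true_apc, pop = {}, {}, {}
    for (sex, age), (rate_2011, apc) in _MODELED_2011.items():
        st = Stratum(sex, age)
        true_apc[st] = apc
        base_rate[st] = rate_2011 / (1.0 + apc / 100.0) ** (2011 - 2006)
        pop[st] = float(population)
    return SimConfig(base_rate=base_rate, true_apc=true_apc, population=pop,
                     noise_model=noise_model, seed=seed)


def true_parameters(config: SimConfig) -> pd.DataFrame:
    """The exact generating values, for parameter-recovery tests.

    One row per stratum and year: (sex, age_group, true_apc, year, true_rate).
    """
    rows = [
        {"sex": st.sex, "age_group": st.age_group, "true_apc": config.true_apc[st],
         "year": y, "true_rate": config.true_rate(st, y)}
        for st in config.strata
        for y in config.year_range
    ]
    return pd.DataFrame(rows)


def expected_counts(config: SimConfig) -> pd.DataFrame:
    """Closed-form expected post-exclusion weighted counts per
    (year, stratum, source): population x rate x mix x retention / 1e5."""
    rows = []
    for st in config.strata:
        for y in config.year_range:
            lam_all = config.population[st] * config.true_rate(st, y) / 1e5
            for src in SOURCES:
                rows.append({
                    "year": y, "sex": st.sex, "age_group": st.age_group, "source": src,
                    "expected_count": lam_all * config.source_mix[src] * config.retention(src),
                })
    return pd.DataFrame(rows)


def population_table(config: SimConfig) -> pd.DataFrame:
    rows = [
        {"year": y, "sex": st.sex, "age_group": st.age_group,
         "population": config.population[st]}
        for st in config.strata
        for y in config.year_range
    ]
    return pd.DataFrame(rows)


def _stratum_rng(config: SimConfig, stratum_index: int) -> np.random.Generator:
    # Per-stratum substream: adding strata never reshuffles existing draws.
    return np.random.default_rng(np.random.SeedSequence([config.seed, stratum_index]))


def generate_counts(config: SimConfig) -> pd.DataFrame:
    """Draw post-exclusion case counts directly at stratum level.

    Returns one row per (year, sex, age_group, source, category) with a
    ``count`` column.  Under ``noise_model='poisson'`` each cell is an
    independent Poisson draw around the closed-form expectation (records
    thinned by exclusions remain Poisson); under ``'none'`` counts equal
    the expectation exactly.  This is the fast path for replicate studies
    where record-level bookkeeping is not under test.
    """
    cats = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats])
    rows = []
    for k, st in enumerate(config.strata):
        rng = _stratum_rng(config, k)
        for y in config.year_range:
            lam_all = config.population[st] * config.true_rate(st, y) / 1e5
            for src in SOURCES:
                lam = lam_all * config.source_mix[src] * config.retention(src) * probs
                if config.noise_model == "poisson":
                    counts = rng.poisson(lam).astype(float)
                else:
                    counts = lam
                for cat, c in zip(cats, counts):
                    rows.append({"year": y, "sex": st.sex, "age_group": st.age_group,
                                 "source": src, "category": cat, "count": c})
    return pd.DataFrame(rows)


def generate_dataset(
    config: SimConfig, defs: CaseDefinitionSet | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Materialize encounter-level records plus the population table.

    Returns ``(records, population)``.  ``records`` has one row per
    encounter with columns (source, year, sex, age_group, code, flags,
    weight); ``flags`` is a semicolon-joined token set.  Case codes are
    sampled from the active case definition per the category mix; an extra
    ``noncase_fraction`` of records carry non-case codes so classification
    has true negatives.  ED records carry survey-style weights (1 plus a
    lognormal draw); hospitalization and death records carry weight 1.

    Under ``noise_model='none'`` record counts are rounded to integers and
    weights rescaled so each cell's weighted total equals the closed-form
    expectation exactly (a diagnostic mode; unit death weights are
    sacrificed for exactness there).
    """
    if defs is None:
        defs = default_case_definitions()
    code_pool = {
        (cat, src): defs.codes(cat, src) or [""]
        for cat in CATEGORIES
        for src in SOURCES
    }
    cats = list(config.category_mix)
    cat_probs = np.array([config.category_mix[c] for c in cats])
    sigma = config.ed_weight_sigma
    # lognormal for (weight - 1) with mean ed_weight_mean - 1
    mu = np.log(config.ed_weight_mean - 1.0) - sigma**2 / 2.0

    frames: list[pd.DataFrame] = []
    for k, st in enumerate(config.strata):
        rng = _stratum_rng(config, k)
        for y in config.year_range:
            lam_all = config.population[st] * config.true_rate(st, y) / 1e5
            for src in SOURCES:
                lam_weighted = lam_all * config.source_mix[src]
                mean_w = config.ed_weight_mean if src == "ed" else 1.0
                lam_rec = lam_weighted / mean_w
                exact = config.noise_model == "none"
                n_case = int(round(lam_rec)) if exact else int(rng.poisson(lam_rec))
                n_non = (int(round(config.noncase_fraction * lam_rec)) if exact
                         else int(rng.poisson(config.noncase_fraction * lam_rec)))
                n = n_case + n_non
                if n == 0:
                    continue
                codes = np.empty(n, dtype=object)
                if n_case:
                    cat_idx = rng.choice(len(cats), size=n_case, p=cat_probs)
                    for i, ci in enumerate(cat_idx):
                        pool = code_pool[(cats[ci], src)]
                        codes[i] = pool[rng.integers(len(pool))]
                if n_non:
                    pool = NONCASE_DEATH_CODES if src == "death" else NONCASE_ED_HOSP_CODES
                    codes[n_case:] = [pool[j] for j in rng.integers(len(pool), size=n_non)]
                flags = np.full(n, "", dtype=object)
                if src != "death":
                    flag_lists: list[list[str]] = [[] for _ in range(n)]
                    for flag, p in config.disposition_probs.get(src, {}).items():
                        if p <= 0:
                            continue
                        hit = rng.random(n) < p
                        for i in np.nonzero(hit)[0]:
                            flag_lists[i].append(flag)
                    flags = np.array([";".join(fl) for fl in flag_lists], dtype=object)
                if exact:
                    weights = np.full(n_case, lam_weighted / n_case) if n_case else np.array([])
                    weights = np.concatenate([weights, np.ones(n_non)])
                elif src == "ed":
                    weights = 1.0 + rng.lognormal(mu, sigma, size=n)
                else:
                    weights = np.ones(n)
                frames.append(pd.DataFrame({
                    "source": src, "year": y, "sex": st.sex, "age_group": st.age_group,
                    "code": codes, "flags": flags, "weight": weights,
                }))
    if frames:
        records = pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]
    else:
        records = pd.DataFrame(columns=RECORD_COLUMNS)
    return records, population_table(config)
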