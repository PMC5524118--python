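"""Shared fixtures and the replicate-study harness used by the
calibration tests (null type-I error, APC recovery/coverage, injected
deficit)."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import heartsentinel as hs
from heartsentinel.ledger import combine_sources, poisson_variance_model, rollup_categories
from heartsentinel.synthetic import population_table


@pytest.fixture(scope="session")
def default_defs():
    return hs.default_case_definitions()


@pytest.fixture
def toy_defs():
    """A minimal unambiguous case definition for classification tests."""
    return hs.CaseDefinitionSet([
        hs.CaseDefinition("ami", "acute myocardial infarction",
                          ed_hosp_codes=("410",), death_codes=("I21",)),
        hs.CaseDefinition("stroke", "ischemic stroke",
                          ed_hosp_codes=("434",), death_codes=("I63",)),
    ])


def flat_world_config(seed: int, population: float = 1_000_000) -> hs.SimConfig:
    """Null world: every stratum's true rate held flat (APC 0) at the
    level its default trajectory reaches in 2011."""
    cfg = hs.default_sim_config(seed=seed, population=population)
    flat = {st: cfg.base_rate[st] * (1 + cfg.true_apc[st] / 100) ** 5 for st in cfg.strata}
    return dataclasses.replace(cfg, base_rate=flat, true_apc={st: 0.0 for st in cfg.strata})


def overall_retention(cfg: hs.SimConfig) -> float:
    return sum(cfg.source_mix[s] * cfg.retention(s) for s in cfg.source_mix)


def fit_replicate(cfg: hs.SimConfig, fit_window=(2006, 2011), anchor=2011):
    """One replicate of the count-level inferential chain up to trend fits.

    Uses the Poisson variance attribution so the stated SEs match the
    generating noise (the condition under which calibration statements
    are meaningful).  Returns (combined counts, stratum rates, fits).
    """
    pvm = poisson_variance_model()
    counts = hs.generate_counts(cfg)
    combined = combine_sources(rollup_categories(counts, pvm))
    stratum_rates = hs.compute_rates(combined, population_table(cfg))
    fits = hs.fit_all_strata(stratum_rates, fit_window, anchor)
    return combined, stratum_rates, fits


def prevented_overall(
    cfg: hs.SimConfig,
    combined: pd.DataFrame,
    fits,
    observed_years=(2012, 2013),
    strategy: str = "stable",
    n_sims: int = 1000,
    seed_tag: int = 77,
) -> hs.PreventedResult:
    """Observed-vs-expected over all strata for one replicate."""
    years = list(observed_years)
    per = []
    for k, st in enumerate(sorted(fits)):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, seed_tag, k]))
        proj = hs.simulate_baseline(fits[st], strategy, years, n_sims=n_sims, rng=rng)
        pop = {y: cfg.population[st] for y in years}
        exp_mean, exp_sd = hs.expected_events_total(proj, pop, years)
        obs = combined[
            (combined["sex"] == st.sex) & (combined["age_group"] == st.age_group)
            & combined["year"].isin(years)
        ]
        per.append(hs.events_prevented(
            float(obs["count"].sum()), float(np.sqrt(np.sum(np.square(obs["sd"])))),
            exp_mean, exp_sd, strategy=strategy, scope=st.label, years=years))
    return hs.combine(per)
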