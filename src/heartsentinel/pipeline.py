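"""Orchestration: one reproducible run from synthetic records to
events-prevented estimates, with every intermediate written to CSV.

Stage order: simulate (or load records) -> classify -> exclude ->
tabulate -> combine -> rates (stratum + age-standardized) -> trend fits
over the fit window -> baseline projection (both strategies) over the
projection window -> observed-vs-expected prevented estimates for the
years where observed data exist.  The run seed and a hash of the full
configuration are logged and stamped into every output header; a second
run into the same directory with a different configuration refuses to
overwrite unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .definitions import CaseDefinitionSet, default_case_definitions, load_case_definitions
from .ledger import (
    apply_exclusions,
    classify_records,
    combine_sources,
    default_variance_model,
    poisson_variance_model,
    rollup_categories,
    tabulate_counts,
)
from .prevented import PreventedResult, combine, events_prevented, results_to_frame
from .projector import expected_events, expected_events_total, simulate_baseline
from .rates import StandardPopulation, age_standardize, compute_rates, default_standard_population
from .strata import SEXES, Stratum
from .synthetic import SimConfig, default_sim_config, generate_dataset
from .trends import TrendFit, fit_all_strata, fits_to_frame

log = logging.getLogger("heartsentinel")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    sim: SimConfig = field(default_factory=default_sim_config)
    defs_path: str | None = None
    standard_population_path: str | None = None
    fit_window: tuple[int, int] = (2006, 2011)
    anchor_year: int = 2011
    projection_window: tuple[int, int] = (2012, 2016)
    observed_years: tuple[int, ...] = (2012, 2013)
    n_sims: int = 1000
    seed: int = 0
    variance_model: str = "default"  # 'default' or 'poisson'
    observed_fixed: bool = False
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.anchor_year != self.fit_window[1]:
            raise ValueError("anchor year must be the last fit-window year")
        if self.fit_window[1] >= self.projection_window[0]:
            raise ValueError("fit window must precede the projection window")
        if self.variance_model not in ("default", "poisson"):
            raise ValueError("variance_model must be 'default' or 'poisson'")

    def case_definitions(self) -> CaseDefinitionSet:
        if self.defs_path:
            return load_case_definitions(self.defs_path)
        return default_case_definitions()

    def standard_population(self) -> StandardPopulation:
        if self.standard_population_path:
            return StandardPopulation.from_yaml(self.standard_population_path)
        return default_standard_population()

    def sd_models(self):
        return poisson_variance_model() if self.variance_model == "poisson" else default_variance_model()

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, Stratum):
                return o.label
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        payload = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("overwrite", "sim")
        }
        payload["sim"] = {
            **{f.name: getattr(self.sim, f.name)
               for f in dataclasses.fields(self.sim)
               if f.name not in ("base_rate", "true_apc", "population")},
            "base_rate": {st.label: self.sim.base_rate[st] for st in self.sim.strata},
            "true_apc": {st.label: self.sim.true_apc[st] for st in self.sim.strata},
            "population": {st.label: self.sim.population[st] for st in self.sim.strata},
        }
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    records: pd.DataFrame
    population: pd.DataFrame
    counts: pd.DataFrame
    combined: pd.DataFrame
    stratum_rates: pd.DataFrame
    standardized_rates: pd.DataFrame
    fits: dict[Stratum, TrendFit]
    projections: pd.DataFrame
    prevented: list[PreventedResult]
    report: str
    config_hash: str


def _standardized_rates(
    combined: pd.DataFrame, population: pd.DataFrame, std: StandardPopulation
) -> pd.DataFrame:
    """Age-standardized rates per year for overall / men / women scopes.

    The overall scope aggregates counts and denominators across sexes
    before computing age-specific rates (variances add across sexes within
    an age group under source independence)."""
    rows = []
    for year, ygrp in combined.groupby("year"):
        ypop = population[population["year"] == year]
        for scope in ("overall", *SEXES):
            if scope == "overall":
                agg = ygrp.groupby("age_group", as_index=False).agg(
                    count=("count", "sum"), var=("sd", lambda s: float(np.sum(np.square(s)))))
                agg["sd"] = np.sqrt(agg.pop("var"))
                pop = ypop.groupby("age_group", as_index=False)["population"].sum()
                agg["sex"] = "all"
                pop["sex"] = "all"
            else:
                agg = ygrp[ygrp["sex"] == scope].copy()
                pop = ypop[ypop["sex"] == scope]
            agg["year"] = year
            pop = pop.assign(year=year)
            r = compute_rates(agg, pop)
            rate, lo, hi = age_standardize(r, std)
            rows.append({"year": year, "scope": scope, "rate": rate,
                         "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def _render_report(config: RunConfig, std_rates: pd.DataFrame,
                   fits: dict[Stratum, TrendFit], projections: pd.DataFrame,
                   prevented: list[PreventedResult]) -> str:
    lines: list[str] = []
    lines.append("Cardiovascular event surveillance run")
    lines.append(f"config_hash={config.config_hash()}  seed={config.seed}")
    lines.append("")
    lines.append("Age-standardized event rates per 100 000 (95% CI)")
    tab = std_rates.copy()
    tab["rate (95% CI)"] = [
        f"{r.rate:.1f} ({r.ci_low:.1f}, {r.ci_high:.1f})" for r in tab.itertuples()
    ]
    lines.append(tab.pivot(index="year", columns="scope", values="rate (95% CI)").to_string())
    lines.append("")
    lines.append(f"Trend fits, {config.fit_window[0]}-{config.fit_window[1]} "
                 f"(APC = annual percent change; anchor {config.anchor_year})")
    ftab = fits_to_frame(fits)
    ftab["APC (95% CI)"] = [
        f"{r.apc:.1f} ({r.apc_lo:.1f}, {r.apc_hi:.1f})" for r in ftab.itertuples()
    ]
    ftab["modeled anchor rate"] = [
        f"{r.modeled_anchor_rate:.1f}" for r in ftab.itertuples()
    ]
    lines.append(ftab[["sex", "age_group", "APC (95% CI)", "p",
                       "modeled anchor rate"]].to_string(index=False))
    lines.append("")
    lines.append("Expected rates per 100 000 by baseline strategy")
    ptab = projections.copy()
    ptab["rate"] = ptab["rate_mean"].round(1)
    lines.append(
        ptab.pivot_table(index=["strategy", "sex", "age_group"], columns="year",
                         values="rate").to_string()
    )
    lines.append("")
    lines.append("Events prevented (expected - observed; negative = excess)")
    rtab = results_to_frame(prevented)
    for c in ("observed", "expected", "prevented", "ci_lo", "ci_hi"):
        rtab[c] = rtab[c].round().astype(int)
    rtab["z"] = rtab["z"].round(2)
    lines.append(rtab.to_string(index=False))
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute every stage in order; optionally write all outputs."""
    chash = config.config_hash()
    log.info("run starting: seed=%s config_hash=%s", config.seed, chash)
    log.info("conventions in force: fixed-scale WLS covariance; independent "
             "anchor/APC draws; within-draw multi-year totals; normal CIs")
    meta = {"config_hash": chash, "seed": config.seed}

    if out_dir is not None:
        out_dir = Path(out_dir)
        marker = out_dir / "run_meta.json"
        if marker.exists():
            previous = json.loads(marker.read_text())
            if previous.get("config_hash") != chash and not config.overwrite:
                raise FileExistsError(
                    f"{out_dir} holds outputs for config {previous.get('config_hash')}; "
                    "pass overwrite=True (CLI: --overwrite) to replace them"
                )
        out_dir.mkdir(parents=True, exist_ok=True)

    defs = config.case_definitions()
    sim = config.sim.with_seed(config.seed)

    log.info("stage simulate: %d strata, years %s-%s", len(sim.strata), *sim.years)
    try:
        records, population = generate_dataset(sim, defs)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    log.info("stage tabulate: %d records", len(records))
    try:
        cases = classify_records(records, defs)
        retained = apply_exclusions(cases)
        counts = tabulate_counts(retained, config.sd_models())
        combined = combine_sources(rollup_categories(counts, config.sd_models()))
    except Exception as exc:
        raise RuntimeError(f"stage 'tabulate' failed: {exc}") from exc

    log.info("stage rates")
    try:
        stratum_rates = compute_rates(combined, population)
        std_rates = _standardized_rates(combined, population, config.standard_population())
    except Exception as exc:
        raise RuntimeError(f"stage 'rates' failed: {exc}") from exc

    log.info("stage trends: window %s-%s anchor %s", *config.fit_window, config.anchor_year)
    try:
        fits = fit_all_strata(stratum_rates, config.fit_window, config.anchor_year)
    except Exception as exc:
        raise RuntimeError(f"stage 'trends' failed: {exc}") from exc

    proj_years = list(range(config.projection_window[0], config.projection_window[1] + 1))
    log.info("stage project: years %s, n_sims=%d", proj_years, config.n_sims)
    try:
        proj_frames = []
        projections_by_key = {}
        for s_idx, strategy in enumerate(("stable", "trend")):
            for k, st in enumerate(sorted(fits)):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, 1000 + s_idx, k]))
                proj = simulate_baseline(fits[st], strategy, proj_years,
                                         n_sims=config.n_sims, rng=rng)
                projections_by_key[(strategy, st)] = proj
                proj_frames.append(expected_events(proj, population)
                                   if _has_projection_pop(population, proj_years)
                                   else proj.to_frame())
        projections = pd.concat(proj_frames, ignore_index=True)
    except Exception as exc:
        raise RuntimeError(f"stage 'project' failed: {exc}") from exc

    log.info("stage prevented: observed years %s", list(config.observed_years))
    try:
        prevented = _prevented_results(config, combined, population, projections_by_key)
    except Exception as exc:
        raise RuntimeError(f"stage 'prevented' failed: {exc}") from exc

    report = _render_report(config, std_rates, fits, projections, prevented)

    result = PipelineResult(
        records=records, population=population, counts=counts, combined=combined,
        stratum_rates=stratum_rates, standardized_rates=std_rates, fits=fits,
        projections=projections, prevented=prevented, report=report, config_hash=chash,
    )

    if out_dir is not None:
        hio.write_csv(records, out_dir / "records.csv", meta)
        hio.write_csv(population, out_dir / "population.csv", meta)
        hio.write_csv(counts, out_dir / "counts.csv", meta)
        hio.write_csv(combined, out_dir / "combined.csv", meta)
        hio.write_csv(stratum_rates, out_dir / "rates.csv", meta)
        hio.write_csv(std_rates, out_dir / "standardized_rates.csv", meta)
        hio.write_csv(fits_to_frame(fits), out_dir / "fits.csv", meta)
        hio.write_csv(projections, out_dir / "projections.csv", meta)
        hio.write_csv(results_to_frame(prevented), out_dir / "prevented.csv", meta)
        (out_dir / "report.txt").write_text(report)
        (out_dir / "run_meta.json").write_text(
            json.dumps({"config_hash": chash, "seed": config.seed}, indent=2))
        log.info("outputs written to %s", out_dir)
    return result


def _has_projection_pop(population: pd.DataFrame, proj_years: list[int]) -> bool:
    return set(proj_years) <= set(population["year"].astype(int))


def _prevented_results(config, combined, population, projections_by_key):
    """Per-stratum and overall prevented estimates for the observed years
    (skipped when no observed year is present in the data)."""
    observed_years = [
        y for y in config.observed_years if (combined["year"] == y).any()
    ]
    if not observed_years:
        return []
    results: list[PreventedResult] = []
    for strategy in ("stable", "trend"):
        per_stratum = []
        for (strat, st), proj in projections_by_key.items():
            if strat != strategy:
                continue
            obs = combined[
                (combined["sex"] == st.sex) & (combined["age_group"] == st.age_group)
                & combined["year"].isin(observed_years)
            ]
            observed = float(obs["count"].sum())
            observed_sd = 0.0 if config.observed_fixed else float(
                np.sqrt(np.sum(np.square(obs["sd"]))))
            exp_mean, exp_sd = expected_events_total(proj, population, observed_years)
            per_stratum.append(events_prevented(
                observed, observed_sd, exp_mean, exp_sd,
                strategy=strategy, scope=st.label, years=observed_years))
        results.extend(per_stratum)
        results.append(combine(per_stratum, scope="overall"))
    return results
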