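"""Counterfactual baseline projection with Monte Carlo uncertainty.

Two baseline strategies extend a fitted trend past its anchor year:

* ``stable`` — the modeled anchor-year rate is held constant through the
  projection window (no further change assumed);
* ``trend``  — the fitted APC is compounded forward year on year from the
  modeled anchor rate: rate(y) = anchor_rate * (1 + APC/100)^(y - anchor).

Uncertainty is propagated by simulation: each replicate draws an anchor
rate from a normal truncated at zero (and, for the trend strategy, an APC
from a normal truncated at -100) and projects deterministically; one APC
draw per replicate is compounded across all years, so each simulated path
multiplies the preceding year's simulated rate by the same drawn APC.
Per-year means and SDs of the draws summarize the expected rates, and the
retained draw matrix lets multi-year event totals inherit the shared-fit
covariance exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .strata import Stratum
from .trends import TrendFit

__all__ = ["BaselineProjection", "project_deterministic", "simulate_baseline",
           "expected_events", "expected_events_total"]

Z95 = 1.959963984540054
STRATEGIES = ("stable", "trend")


def project_deterministic(fit: TrendFit, strategy: str, years: list[int]) -> pd.Series:
    """Deterministic expected rate per projection year (no uncertainty)."""
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    years = list(years)
    if any(y <= fit.anchor_year for y in years):
        raise ValueError("projection years must follow the anchor year")
    if strategy == "stable":
        vals = [fit.modeled_anchor_rate] * len(years)
    else:
        growth = 1.0 + fit.apc / 100.0
        vals = [fit.modeled_anchor_rate * growth ** (y - fit.anchor_year) for y in years]
    return pd.Series(vals, index=pd.Index(years, name="year"), name="rate")


@dataclass(frozen=True)
class BaselineProjection:
    """Simulated expected rates for one stratum and strategy."""

    strategy: str
    stratum: Stratum | None
    years: tuple[int, ...]
    rate_mean: np.ndarray      # per year
    rate_sd: np.ndarray        # per year
    draws: np.ndarray          # (n_sims, n_years)
    n_sims: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "strategy": self.strategy,
            "sex": self.stratum.sex if self.stratum else "all",
            "age_group": self.stratum.age_group if self.stratum else "all",
            "year": list(self.years),
            "rate_mean": self.rate_mean,
            "rate_sd": self.rate_sd,
        })


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_baseline(
    fit: TrendFit,
    strategy: str,
    years: list[int],
    n_sims: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BaselineProjection:
    """Monte Carlo expected-rate distribution for one stratum/strategy.

    Draws are anchor-rate ~ Normal(modeled rate, anchor SE) truncated at 0
    and, for the trend strategy, APC ~ Normal(APC, APC SE) truncated at
    -100; zero SEs collapse the corresponding draw to its mean exactly.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    if n_sims < 2:
        raise ValueError("need at least 2 simulations")
    years = list(years)
    if any(y <= fit.anchor_year for y in years):
        raise ValueError("projection years must follow the anchor year")
    if rng is None:
        rng = np.random.default_rng(seed)

    degenerate = fit.anchor_rate_se == 0 and (strategy == "stable" or fit.apc_se == 0)
    if degenerate:
        # zero SEs: every draw equals the deterministic projection exactly
        det = project_deterministic(fit, strategy, years).to_numpy()
        draws = np.tile(det, (n_sims, 1))
        return BaselineProjection(
            strategy=strategy, stratum=fit.stratum, years=tuple(years),
            rate_mean=det.copy(), rate_sd=np.zeros(len(years)),
            draws=draws, n_sims=n_sims, seed=seed,
        )

    anchor = _truncated_normal(rng, fit.modeled_anchor_rate, fit.anchor_rate_se, 0.0, n_sims)
    horizons = np.array([y - fit.anchor_year for y in years], dtype=float)
    if strategy == "stable":
        draws = np.repeat(anchor[:, None], len(years), axis=1)
    else:
        apc = _truncated_normal(rng, fit.apc, fit.apc_se, -100.0, n_sims)
        growth = 1.0 + apc / 100.0
        draws = anchor[:, None] * growth[:, None] ** horizons[None, :]
    return BaselineProjection(
        strategy=strategy, stratum=fit.stratum, years=tuple(years),
        rate_mean=draws.mean(axis=0), rate_sd=draws.std(axis=0, ddof=1),
        draws=draws, n_sims=n_sims, seed=seed,
    )


def _populations(
    population: pd.DataFrame | dict,
    projection: BaselineProjection,
    years: list[int] | None = None,
) -> np.ndarray:
    needed = list(years) if years is not None else list(projection.years)
    if isinstance(population, dict):
        pops = {int(y): float(p) for y, p in population.items()}
    else:
        sub = population
        if projection.stratum is not None and "sex" in population.columns:
            sub = population[
                (population["sex"] == projection.stratum.sex)
                & (population["age_group"] == projection.stratum.age_group)
            ]
        pops = dict(zip(sub["year"].astype(int), sub["population"].astype(float)))
    missing = [y for y in needed if y not in pops]
    if missing:
        raise ValueError(f"missing population rows for projection years {missing}")
    return np.array([pops[y] for y in needed])


def expected_events(
    projection: BaselineProjection, population: pd.DataFrame | dict
) -> pd.DataFrame:
    """Convert expected rates to expected event counts with 95% CIs.

    events(y) = rate_mean(y) x population(y) / 1e5; the CI half-width is
    1.96 x rate_sd x population / 1e5 (normal approximation).
    """
    pop = _populations(population, projection)
    mean = projection.rate_mean * pop / 1e5
    half = Z95 * projection.rate_sd * pop / 1e5
    out = projection.to_frame()
    out["population"] = pop
    out["events_mean"] = mean
    out["events_sd"] = projection.rate_sd * pop / 1e5
    out["events_lo"] = mean - half
    out["events_hi"] = mean + half
    return out


def expected_events_total(
    projection: BaselineProjection, population: pd.DataFrame | dict,
    years: list[int] | None = None,
) -> tuple[float, float]:
    """Expected events summed over several projection years, with an SD
    computed within-draw (each simulation path is summed across years
    before taking the spread), so the covariance induced by the shared fit
    is carried through rather than assumed away."""
    sel = np.ones(len(projection.years), dtype=bool)
    if years is not None:
        sel = np.isin(np.array(projection.years), np.array(list(years)))
        if sel.sum() != len(set(years)):
            raise ValueError("requested years not all present in projection")
    kept = [y for y, s in zip(projection.years, sel) if s]
    pop = _populations(population, projection, kept)
    totals = (projection.draws[:, sel] * pop[None, :] / 1e5).sum(axis=1)
    return float(totals.mean()), float(totals.std(ddof=1))
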