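"""Events-prevented inference: observed versus expected with z-tests.

The estimand is prevented = expected - observed for a scope (one stratum
or an aggregate) over one or more years; positive values are events
prevented, negative values are excess events.  Variances of the observed
and expected totals add (the observed data and the baseline fit are
independent), giving z = prevented / sqrt(var) against the standard
normal and a symmetric 95% CI.  Significance is flagged at |z| >= 1.96.

By default the observed total's own sampling variance enters the z
(observed totals from survey sources are themselves estimates); pass
``observed_sd=0`` to treat observed counts as fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["PreventedResult", "events_prevented", "combine"]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class PreventedResult:
    """Observed-vs-expected comparison for one scope and year set."""

    strategy: str
    scope: str
    years: tuple[int, ...]
    observed: float
    observed_sd: float
    expected: float
    expected_sd: float
    prevented: float
    ci: tuple[float, float]
    z: float
    significant: bool
    degenerate: bool = False  # zero variance with a nonzero difference

    def to_row(self) -> dict:
        return {
            "strategy": self.strategy, "scope": self.scope,
            "years": "+".join(str(y) for y in self.years),
            "observed": self.observed, "expected": self.expected,
            "prevented": self.prevented,
            "ci_lo": self.ci[0], "ci_hi": self.ci[1],
            "z": self.z, "significant": self.significant,
        }


def events_prevented(
    observed: float,
    observed_sd: float,
    expected: float,
    expected_sd: float,
    *,
    strategy: str = "stable",
    scope: str = "overall",
    years: Iterable[int] = (),
) -> PreventedResult:
    """Compare one observed total against one expected total."""
    if observed_sd < 0 or expected_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    prevented = expected - observed
    var = observed_sd**2 + expected_sd**2
    degenerate = var == 0 and prevented != 0
    if var > 0:
        z = prevented / np.sqrt(var)
    else:
        z = 0.0 if prevented == 0 else np.inf * np.sign(prevented)
    half = Z95 * np.sqrt(var)
    return PreventedResult(
        strategy=strategy, scope=scope, years=tuple(years),
        observed=float(observed), observed_sd=float(observed_sd),
        expected=float(expected), expected_sd=float(expected_sd),
        prevented=float(prevented), ci=(prevented - half, prevented + half),
        z=float(z), significant=bool(abs(z) >= Z95), degenerate=degenerate,
    )


def combine(results: Iterable[PreventedResult], scope: str = "combined") -> PreventedResult:
    """Pool prevented-events results across disjoint scopes.

    Differences and variances sum (results on disjoint data are
    independent) and z is recomputed from the pooled difference.  All
    inputs must share a strategy.  Note: results for different *years of
    the same stratum and fit* are not independent; build those with
    :func:`heartsentinel.projector.expected_events_total`, which carries
    the shared-fit covariance, rather than by pooling per-year results.
    """
    results = list(results)
    if not results:
        raise ValueError("nothing to combine")
    strategies = {r.strategy for r in results}
    if len(strategies) > 1:
        raise ValueError(f"cannot combine across strategies {sorted(strategies)}")
    observed = sum(r.observed for r in results)
    expected = sum(r.expected for r in results)
    obs_var = sum(r.observed_sd**2 for r in results)
    exp_var = sum(r.expected_sd**2 for r in results)
    years = tuple(sorted({y for r in results for y in r.years}))
    return events_prevented(
        observed, np.sqrt(obs_var), expected, np.sqrt(exp_var),
        strategy=results[0].strategy, scope=scope, years=years,
    )


def results_to_frame(results: Iterable[PreventedResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
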