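"""Inverse-variance-weighted log-linear trend fitting and APC inference.

For each stratum the model is

    ln rate(year) = a + b * (year - anchor) + error,

fitted by weighted least squares with weights equal to the inverse
variance of each log rate, var(ln r) ~= (se/r)^2 by the delta method.
The annual percent change is APC = 100 (e^b - 1); its SE follows from the
delta method (se_APC = 100 e^b se_b) and its 95% CI from transforming the
slope interval.  Because the design is centered at the anchor year, the
intercept is the fitted log rate there, so exp(a) is the modeled anchor
rate and its SE is exp(a) * se_a.

The weights are treated as known inverse measurement variances, so the
parameter covariance is the fixed-scale (X'WX)^{-1} — the meta-regression
convention — rather than a residual-MSE-rescaled covariance.  All tests
use the standard normal reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .strata import Stratum

__all__ = ["TrendFit", "fit_loglinear", "test_apc", "compare_apcs", "fit_all_strata"]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class TrendFit:
    """A fitted log-linear trend for one stratum."""

    stratum: Stratum | None
    slope: float
    slope_se: float
    apc: float
    apc_se: float
    apc_ci: tuple[float, float]
    p_value: float
    modeled_anchor_rate: float
    anchor_rate_se: float
    anchor_year: int
    n_years: int

    @classmethod
    def from_params(
        cls,
        modeled_anchor_rate: float,
        apc: float,
        anchor_year: int,
        *,
        anchor_rate_se: float = 0.0,
        apc_se: float = 0.0,
        stratum: Stratum | None = None,
    ) -> "TrendFit":
        """Build a fit directly from published/modeled values (e.g. a
        surveillance table's modeled anchor rates and APCs)."""
        if modeled_anchor_rate <= 0:
            raise ValueError("anchor rate must be positive")
        if apc <= -100:
            raise ValueError("APC must exceed -100")
        slope = np.log1p(apc / 100.0)
        slope_se = apc_se / (100.0 + apc) if apc_se else 0.0
        if slope_se > 0:
            z = abs(slope) / slope_se
            p = 2.0 * stats.norm.sf(z)
            ci = (100.0 * np.expm1(slope - Z95 * slope_se),
                  100.0 * np.expm1(slope + Z95 * slope_se))
        else:
            p = 0.0 if slope != 0 else 1.0
            ci = (apc, apc)
        return cls(stratum, float(slope), float(slope_se), float(apc), float(apc_se),
                   ci, float(p), float(modeled_anchor_rate), float(anchor_rate_se),
                   anchor_year, 0)


def fit_loglinear(
    rates: pd.DataFrame, anchor_year: int, stratum: Stratum | None = None
) -> TrendFit:
    """Fit the weighted log-linear trend to one stratum's annual rates.

    ``rates`` needs columns (year, rate, se) with at least three years of
    positive rates and positive SEs; weights are 1/var(ln rate).
    """
    years = rates["year"].to_numpy(dtype=float)
    r = rates["rate"].to_numpy(dtype=float)
    se = rates["se"].to_numpy(dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 years to fit a trend")
    if len(np.unique(years)) != len(years):
        raise ValueError("duplicate years in trend input")
    if (r <= 0).any():
        raise ValueError("non-positive rate in trend input; log-linear fit undefined")
    if (se <= 0).any():
        raise ValueError("non-positive rate SE in trend input; weights undefined")

    x = years - anchor_year
    y = np.log(r)
    w = (r / se) ** 2  # 1 / var(ln rate), delta method
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(x), x])
    # QR-based weighted solve; covariance is fixed-scale (X'WX)^{-1}
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    a, b = beta
    se_a, se_b = np.sqrt(np.diag(cov))

    apc = 100.0 * np.expm1(b)
    apc_se = 100.0 * np.exp(b) * se_b
    apc_ci = (100.0 * np.expm1(b - Z95 * se_b), 100.0 * np.expm1(b + Z95 * se_b))
    if se_b > 0:
        p = 2.0 * stats.norm.sf(abs(b) / se_b)
    else:
        p = 0.0 if b != 0 else 1.0
    return TrendFit(
        stratum=stratum,
        slope=float(b), slope_se=float(se_b),
        apc=float(apc), apc_se=float(apc_se), apc_ci=apc_ci, p_value=float(p),
        modeled_anchor_rate=float(np.exp(a)), anchor_rate_se=float(np.exp(a) * se_a),
        anchor_year=anchor_year, n_years=len(years),
    )


def fit_all_strata(
    rates: pd.DataFrame, fit_window: tuple[int, int], anchor_year: int
) -> dict[Stratum, TrendFit]:
    """Fit every stratum found in a (year, sex, age_group, rate, se) frame
    over the inclusive fit window."""
    lo, hi = fit_window
    window = rates[(rates["year"] >= lo) & (rates["year"] <= hi)]
    fits: dict[Stratum, TrendFit] = {}
    for (sex, age), grp in window.groupby(["sex", "age_group"]):
        st = Stratum(sex, age)
        fits[st] = fit_loglinear(grp.sort_values("year"), anchor_year, stratum=st)
    return fits


def test_apc(fit: TrendFit) -> tuple[float, bool]:
    """Two-sided normal test of slope = 0.

    Returns (p_value, significant at 0.05).  A zero slope SE with a
    nonzero slope is the degenerate noiseless limit: p = 0.
    """
    return fit.p_value, fit.p_value < 0.05


def compare_apcs(fit_a: TrendFit, fit_b: TrendFit) -> tuple[float, float]:
    """Compare two strata's trends: z on the slope difference with pooled
    SE (fits on disjoint data assumed independent); returns (z, p)."""
    pooled = np.hypot(fit_a.slope_se, fit_b.slope_se)
    if pooled == 0:
        if fit_a.slope == fit_b.slope:
            return 0.0, 1.0
        return np.inf * np.sign(fit_a.slope - fit_b.slope), 0.0
    z = (fit_a.slope - fit_b.slope) / pooled
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def fits_to_frame(fits: dict[Stratum, TrendFit]) -> pd.DataFrame:
    """Flatten fits for CSV export."""
    rows = []
    for st in sorted(fits):
        f = fits[st]
        rows.append({
            "sex": st.sex, "age_group": st.age_group,
            "slope": f.slope, "slope_se": f.slope_se,
            "apc": f.apc, "apc_se": f.apc_se,
            "apc_lo": f.apc_ci[0], "apc_hi": f.apc_ci[1], "p": f.p_value,
            "modeled_anchor_rate": f.modeled_anchor_rate,
            "anchor_rate_se": f.anchor_rate_se,
            "anchor_year": f.anchor_year,
        })
    return pd.DataFrame(rows)


def fits_from_frame(frame: pd.DataFrame) -> dict[Stratum, TrendFit]:
    """Rebuild TrendFit objects from an exported fits frame."""
    fits = {}
    for _, row in frame.iterrows():
        st = Stratum(row["sex"], row["age_group"])
        slope = float(row["slope"])
        slope_se = float(row["slope_se"])
        apc = float(row["apc"])
        fits[st] = TrendFit(
            stratum=st, slope=slope, slope_se=slope_se, apc=apc,
            apc_se=float(row.get("apc_se", 100.0 * np.exp(slope) * slope_se)),
            apc_ci=(float(row["apc_lo"]), float(row["apc_hi"])),
            p_value=float(row["p"]),
            modeled_anchor_rate=float(row["modeled_anchor_rate"]),
            anchor_rate_se=float(row["anchor_rate_se"]),
            anchor_year=int(row["anchor_year"]), n_years=0,
        )
    return fits
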