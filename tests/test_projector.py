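"""Baseline-projection tests: deterministic compounding, simulation,
expected events."""

import numpy as np
import pandas as pd
import pytest

import heartsentinel as hs


def fit(rate=152.9, apc=-2.1, rate_se=0.0, apc_se=0.0):
    return hs.TrendFit.from_params(rate, apc, 2011, anchor_rate_se=rate_se, apc_se=apc_se)


class TestDeterministic:
    @pytest.mark.parametrize("rate2011,apc,expected2012", [
        (152.9, -2.1, 149.7),   # men 18-44
        (106.3, -1.4, 104.8),   # women 18-44
    ])
    def test_published_one_year_trend_rates(self, rate2011, apc, expected2012):
        out = hs.project_deterministic(fit(rate2011, apc), "trend", [2012])
        assert round(float(out.loc[2012]), 1) == pytest.approx(expected2012, abs=0.1)

    def test_zero_apc_trend_equals_stable(self):
        years = list(range(2012, 2017))
        f = fit(apc=0.0)
        pd.testing.assert_series_equal(
            hs.project_deterministic(f, "trend", years),
            hs.project_deterministic(f, "stable", years))

    def test_stable_is_constant_and_trend_compounds(self):
        years = list(range(2012, 2017))
        f = fit(1000.0, -3.0)
        stable = hs.project_deterministic(f, "stable", years)
        assert (stable == 1000.0).all()
        trend = hs.project_deterministic(f, "trend", years)
        assert np.allclose(trend, 1000.0 * 0.97 ** np.arange(1, 6))
        assert (np.diff(trend) < 0).all()

    def test_years_before_anchor_rejected(self):
        with pytest.raises(ValueError, match="follow the anchor"):
            hs.project_deterministic(fit(), "trend", [2011])

    def test_strategy_ordering_gap_widens_with_negative_apc(self):
        years = list(range(2012, 2017))
        f = fit(2000.0, -2.5)
        gap = (hs.project_deterministic(f, "stable", years)
               - hs.project_deterministic(f, "trend", years))
        assert (gap > 0).all()
        assert (np.diff(gap) > 0).all()


class TestSimulation:
    def test_zero_ses_collapse_to_deterministic(self):
        years = list(range(2012, 2017))
        f = fit(500.0, -2.0)
        proj = hs.simulate_baseline(f, "trend", years, n_sims=100, seed=1)
        det = hs.project_deterministic(f, "trend", years).to_numpy()
        assert np.array_equal(proj.rate_mean, det)
        assert (proj.rate_sd == 0).all()
        assert (proj.draws == det[None, :]).all()

    def test_mean_converges_to_deterministic(self):
        f = fit(500.0, -2.0, rate_se=5.0, apc_se=0.4)
        proj = hs.simulate_baseline(f, "trend", [2012], n_sims=10_000, seed=2)
        det = float(hs.project_deterministic(f, "trend", [2012]).iloc[0])
        tol = 3 * proj.rate_sd[0] / np.sqrt(proj.n_sims)
        assert abs(proj.rate_mean[0] - det) < tol

    def test_stable_sd_scales_with_anchor_se(self):
        p1 = hs.simulate_baseline(fit(500.0, -2.0, rate_se=2.0), "stable", [2012],
                                  n_sims=20_000, seed=3)
        p2 = hs.simulate_baseline(fit(500.0, -2.0, rate_se=4.0), "stable", [2012],
                                  n_sims=20_000, seed=3)
        assert p2.rate_sd[0] / p1.rate_sd[0] == pytest.approx(2.0, rel=0.05)

    def test_stable_draws_identical_across_years(self):
        proj = hs.simulate_baseline(fit(500.0, -2.0, rate_se=5.0), "stable",
                                    [2012, 2013, 2014], n_sims=50, seed=4)
        assert (proj.draws[:, 0:1] == proj.draws).all()

    def test_seed_determinism_and_cross_seed_agreement(self):
        f = fit(800.0, -1.5, rate_se=8.0, apc_se=0.5)
        a = hs.simulate_baseline(f, "trend", [2012, 2013], n_sims=4000, seed=10)
        b = hs.simulate_baseline(f, "trend", [2012, 2013], n_sims=4000, seed=10)
        assert np.array_equal(a.draws, b.draws)
        c = hs.simulate_baseline(f, "trend", [2012, 2013], n_sims=4000, seed=11)
        assert not np.array_equal(a.draws, c.draws)
        tol = 4 * max(a.rate_sd[0], c.rate_sd[0]) / np.sqrt(4000)
        assert abs(a.rate_mean[0] - c.rate_mean[0]) < tol

    def test_draws_respect_truncation(self):
        f = fit(3.0, -2.0, rate_se=5.0)  # heavy truncation at zero
        proj = hs.simulate_baseline(f, "stable", [2012], n_sims=2000, seed=5)
        assert (proj.draws >= 0).all()

    def test_too_few_sims_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            hs.simulate_baseline(fit(), "stable", [2012], n_sims=1)


class TestExpectedEvents:
    def test_definition_and_zero_sd(self):
        proj = hs.simulate_baseline(fit(1000.0, 0.0), "stable", [2012], n_sims=10, seed=0)
        out = hs.expected_events(proj, {2012: 1_000_000})
        assert out["events_mean"].iloc[0] == pytest.approx(10_000.0)
        assert out["events_lo"].iloc[0] == out["events_hi"].iloc[0]

    def test_hand_arithmetic_ci(self):
        proj = hs.BaselineProjection(
            strategy="trend", stratum=None, years=(2012,),
            rate_mean=np.array([149.7]), rate_sd=np.array([1.1]),
            draws=np.array([[149.7]]), n_sims=1, seed=None)
        out = hs.expected_events(proj, {2012: 2_000_000})
        assert out["events_mean"].iloc[0] == pytest.approx(2994.0)
        half = out["events_hi"].iloc[0] - out["events_mean"].iloc[0]
        assert half == pytest.approx(43.1, abs=0.05)

    def test_missing_population_rejected(self):
        proj = hs.simulate_baseline(fit(), "stable", [2012, 2013], n_sims=10, seed=0)
        with pytest.raises(ValueError, match="missing population"):
            hs.expected_events(proj, {2012: 1e6})

    def test_multi_year_total_carries_shared_fit_covariance(self):
        # stable strategy: both years are the same anchor draw, so the SD
        # of the two-year total is twice the one-year SD (perfect
        # correlation), not sqrt(2) times (independence)
        f = fit(500.0, 0.0, rate_se=5.0)
        proj = hs.simulate_baseline(f, "stable", [2012, 2013], n_sims=5000, seed=6)
        total_mean, total_sd = hs.expected_events_total(proj, {2012: 1e6, 2013: 1e6})
        one_year_sd = proj.rate_sd[0] * 1e6 / 1e5
        assert total_sd == pytest.approx(2 * one_year_sd, rel=1e-9)
        assert total_mean == pytest.approx(2 * proj.rate_mean[0] * 10.0, rel=1e-12)

    def test_expected_event_gap_between_strategies_widens(self):
        years = list(range(2012, 2017))
        f = fit(2000.0, -2.5, rate_se=10.0, apc_se=0.3)
        stable = hs.simulate_baseline(f, "stable", years, n_sims=2000, seed=7)
        trend = hs.simulate_baseline(f, "trend", years, n_sims=2000, seed=8)
        pop = {y: 1e6 for y in years}
        gap = (hs.expected_events(stable, pop)["events_mean"].to_numpy()
               - hs.expected_events(trend, pop)["events_mean"].to_numpy())
        assert (gap > 0).all() and (np.diff(gap) > 0).all()

    def test_pooled_population_projection_matches_sum_only_for_equal_rates(self):
        # projecting on pooled denominators is only valid when stratum
        # rates coincide; unequal rates must disagree with the stratum sum
        years = [2012]
        pop_a, pop_b = 1e6, 3e6
        equal_a = hs.project_deterministic(fit(500.0, 0.0), "stable", years).iloc[0]
        equal_b = hs.project_deterministic(fit(500.0, 0.0), "stable", years).iloc[0]
        summed = equal_a * pop_a / 1e5 + equal_b * pop_b / 1e5
        pooled = 500.0 * (pop_a + pop_b) / 1e5
        assert summed == pytest.approx(pooled)
        uneq_a = hs.project_deterministic(fit(200.0, 0.0), "stable", years).iloc[0]
        uneq_b = hs.project_deterministic(fit(800.0, 0.0), "stable", years).iloc[0]
        summed = uneq_a * pop_a / 1e5 + uneq_b * pop_b / 1e5
        pooled_naive = ((200.0 + 800.0) / 2) * (pop_a + pop_b) / 1e5
        assert summed != pytest.approx(pooled_naive)
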