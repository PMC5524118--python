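# heartsentinel

National cardiovascular-event surveillance combines three administrative
systems — a survey-weighted emergency-department sample, a near-census
hospitalization file, and a death registry — to count acute CVD events
(AMI, stroke, symptomatic precursor conditions, and other CVD such as
heart failure) and to judge whether fewer events are occurring than past
rates predict. `heartsentinel` implements that methodology as a tested
Python pipeline for epidemiologists and health-services researchers:

1. **Event ledger** — ICD-coded case definitions (prefix match on
   dot-stripped codes) and a disposition-based exclusion cascade that
   makes the three sources mutually exclusive: ED visits ending in ED
   death, transfer, or same-hospital admission are dropped, as are
   elective / in-hospital-death / transfer-out hospitalizations; deaths
   are never dropped. Source totals sum, with variances adding in
   quadrature.
2. **Rate engine** — stratum rates per 100 000 (eight sex × age strata:
   18–44, 45–64, 65–74, ≥75) and direct age standardization to a fixed
   standard population.
3. **Trend model** — inverse-variance-weighted log-linear regression per
   stratum, ln *r*(year) = *a* + *b*·(year − anchor), weights 1/var(ln *r*);
   the annual percent change is APC = 100(e^*b* − 1), and e^*a* is the
   modeled anchor-year (2011) rate.
4. **Baseline projector** — two counterfactuals past the anchor: the
   *stable* baseline holds the modeled 2011 rate constant; the *trend*
   baseline compounds the APC forward year on year. Uncertainty is
   propagated by 1000 simulation draws of the anchor rate (and APC).
5. **Prevented estimator** — events prevented = expected − observed
   (negative = excess events), with variances summed, z = Δ/√var, and
   significance at |z| ≥ 1.96.
6. **Synthetic data** — because the real inputs are restricted-use files,
   a generator emulates all three sources with known log-linear ground
   truth, so every stage is testable end to end, including the type-I
   error and CI coverage of the final z-tests.

## Worked example

Project both baselines from a published stratum fit (men aged 18–44:
modeled 2011 rate 152.9 per 100 000, APC −2.1 %/year):

```python
import heartsentinel as hs

fit = hs.TrendFit.from_params(152.9, -2.1, 2011,
                              anchor_rate_se=1.0, apc_se=0.3)
print(hs.project_deterministic(fit, "trend", range(2012, 2017)).round(1))
```

```
year
2012    149.7
2013    146.5
2014    143.5
2015    140.5
2016    137.5
```

One APC step from 152.9 at −2.1 %/year gives 149.7 in 2012; compounding
continues to 137.5 by 2016. Adding simulation (`hs.simulate_baseline`,
`hs.expected_events`) turns these into expected event counts with CIs;
on a population of 1 000 000 the stable baseline expects 1528.6 events
per year (95% CI 1508.1, 1549.1) while the trend baseline expects
1496.4 in 2012 falling to 1374.4 by 2016 — the widening gap is the extra
prevention required to beat past trends rather than a flat world.

The `examples/` directory has one short script per capability
(generation, ledger, rates, trends, projection, prevented, full
pipeline); each prints the numbers it computes and what they mean. A thin
CLI mirrors the stages:

```bash
heartsentinel simulate --config sim.yaml --seed 4 --out run/
heartsentinel tabulate --records run/records.csv --out run/counts.csv
heartsentinel rates --counts run/counts.csv --population run/population.csv --out run/rates.csv
heartsentinel trends --rates run/rates.csv --window 2006:2011 --anchor 2011 --out run/fits.csv
heartsentinel project --fits run/fits.csv --years 2012:2016 --nsims 1000 --seed 4 --out run/proj.csv
heartsentinel run --seed 4 --variance-model poisson --out run/
```

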