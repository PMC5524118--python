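# Methods

## Surveillance model

The unit of analysis is the *mutually exclusive acute CVD event*: an
emergency-department visit, hospitalization, or death that (a) meets an
ICD-coded case definition and (b) survives a disposition-based exclusion
cascade designed to keep one clinical episode from appearing in two data
systems. Case matching is prefix-based on normalized codes (dots
stripped, upper-cased), with separate code systems for ED/hospitalization
primary diagnoses (ICD-9-CM style) and underlying causes of death
(ICD-10 style); a code prefix may not appear under two categories, and
violations are rejected at load time. The shipped case-definition YAML is
explicitly editable configuration — plausible defaults, not authoritative
code lists — and tests use toy definitions rather than the defaults.

Exclusions: ED visits flagged `died_in_facility`, `transferred_out`, or
`admitted_same_hospital` are dropped (the episode is expected to surface
as a hospitalization or death); hospitalizations flagged `elective`,
`died_in_facility`, or `transferred_out` are dropped; death records are
never dropped. Post-exclusion weighted counts per (year, stratum, source,
category) get a standard deviation from a per-source model (below), and
sources combine by summing counts with variances adding under
independence of the three systems.

Analyses are stratified by sex (men, women) and four adult age groups
(18–44, 45–64, 65–74, ≥75), which are disjoint and exhaust ages ≥18 —
eight strata in all. Race/ethnicity stratification is out of scope.

## Rates and standardization

Stratum rates are 100 000 × count / population with SE scaled the same
way. Age standardization uses the direct method: the standardized rate is
Σ w(a) r(a) over the four age groups with fixed standard-population
weights w; its variance is Σ w(a)² se(a)² (age groups treated as
independent — any covariance between age-specific estimates from a shared
survey design is ignored), and all intervals are symmetric normal
(±1.96 SE). The default standard population approximates the 2010 US
census adult age distribution and is shipped as editable YAML; tests use
toy weights. Rates render at one decimal, counts as integers, percents at
one decimal.

## Trend model

For each stratum, annual rates over the fit window (default 2006–2011)
are modeled as

    ln r(y) = a + b (y − anchor) + ε,

fitted by weighted least squares with weights 1/var(ln r), where
var(ln r) ≈ (se/r)² by the delta method. The design is centered at the
anchor year (default 2011, the last fit-window year), so the intercept is
the fitted log rate there: exp(a) is the *modeled anchor rate* and its SE
is exp(a)·se(a). The annual percent change is APC = 100(e^b − 1), with
SE 100 e^b se(b) (delta method) and CI 100(e^(b ± 1.96 se(b)) − 1).

Numerical conventions:

* The parameter covariance is the fixed-scale (X'WX)⁻¹ with W the stated
  inverse variances — the meta-regression convention for known
  measurement error — not a residual-MSE-rescaled covariance. With
  six-point fits this is what makes the nominal 95% CI attain ~95%
  coverage when the stated variances are correct; an MSE-rescaled normal
  interval would undercover.
* All tests (slope = 0; APC differences across strata, z on the slope
  difference with pooled SE) use the standard normal reference, not t.
* Fitting requires ≥3 years of strictly positive rates with positive
  SEs; zero rates abort with an error rather than a continuity
  correction (real stratum counts never approach zero).
* The solver is a QR least-squares on the √w-scaled design; tests verify
  agreement with explicit normal equations to 1e-10 and with an
  independent WLS implementation.

## Baseline strategies and simulation

Two counterfactuals extend each stratum fit past the anchor year:

* **stable** — rate(y) = modeled anchor rate for every projection year;
* **trend** — rate(y) = modeled anchor rate × (1 + APC/100)^(y − anchor),
  i.e. each year multiplies the preceding year's rate by the same APC.

Uncertainty is propagated by Monte Carlo (default 1000 draws, matching
the method's convention). Each replicate draws the anchor rate from
Normal(modeled rate, anchor SE) truncated at 0 and — trend only — an APC
from Normal(APC, APC SE) truncated at −100, then projects
deterministically; a single APC draw per replicate is compounded across
all years. Design choices made where the method is genuinely open:

* draws are on the natural scale with truncation (printed CIs in this
  literature are symmetric, favouring a normal over a lognormal);
* the anchor-rate and APC draws are independent — the covariance they
  share through the fit is ignored, which slightly misstates trend-path
  spread but matches the information actually published with such tables;
* zero SEs collapse the simulation exactly to the deterministic path
  (asserted in tests, not just approximately).

Expected events are rate × population / 100 000 with CI half-width
1.96 × rate SD × population / 100 000. **Multi-year totals are computed
within-draw**: each simulation path is summed across years before taking
the spread. This matters: the two years' expected totals come from the
same fitted anchor (correlation ≈ 1), so summing per-year variances as if
independent understates the combined variance by nearly half and inflates
the null rejection rate of the final z-test from ~5% to ~9%. The
draw-level sum carries the shared-fit covariance exactly.

## Events prevented

prevented = expected − observed (positive = prevented, negative =
excess), var = observed SD² + expected SD², z = prevented/√var, CI
± 1.96 √var, significance at |z| ≥ 1.96. The observed total's own
sampling variance is included by default (observed totals from survey
sources are estimates); passing a zero observed SD reproduces the
fixed-observed variant. Combining across disjoint scopes (strata) sums
differences and variances — valid there because strata are estimated from
disjoint data; combining across *years of one stratum* goes through the
within-draw totals above instead. Zero combined variance with a nonzero
difference is flagged degenerate (infinite z).

## Synthetic generator

The generator emulates the statistical structure of the three national
systems so the whole chain can be validated against known truth:

* each stratum's true rate follows rate(y) = base × (1 + APC/100)^(y−start);
  defaults back-cast the published modeled 2011 rates and 2006–2011 APCs
  (men 18–44: 152.9 at −2.1, … women ≥75: 6842.6 at −1.6) to 2006 levels,
  over years 2006–2013;
* events split across sources 0.121 / 0.742 / 0.137
  (ED / hospitalization / death, the published 2013 shares), then thin
  through independent per-flag disposition probabilities (ED: died 0.01,
  transferred 0.03, admitted 0.25; hospitalization: elective 0.08, died
  0.04, transferred 0.03 — invented but plausible plumbing, since only
  the cascade's structure is under test);
* ED records carry survey-style weights 1 + LogNormal (mean 4.5 overall)
  purely so weighted tabulation is exercised; hospitalization and death
  records carry weight 1 (near-census);
* codes are sampled from the active case definition with a published-like
  category mix (AMI 0.21, stroke 0.21, precursor 0.12, other 0.46) plus a
  10% admixture of non-case codes so classification has true negatives;
* noise is Poisson at stratum level (`noise_model="none"` is a diagnostic
  mode in which counts equal the closed form exactly, with record weights
  rescaled to make cell totals exact);
* one master seed spawns per-stratum substreams, so adding strata never
  reshuffles existing draws and equal seeds give byte-identical output.

Two generation paths share the same expectation (thinned Poisson is
Poisson): `generate_dataset` materializes records for the ledger stages,
and `generate_counts` draws post-exclusion stratum counts directly — the
fast path used for replicate studies, where record bookkeeping is not the
thing under test. A consistency test checks the two paths agree in
expectation.

What the generator does **not** emulate: hospital-cluster survey designs
and their Taylor-linearized variances, design changes across years, state
coverage variation, transfer-chain record linkage, or person-level
deduplication. Passing tests therefore validate the inferential chain
under clean sampling assumptions, not robustness to real survey
complexity.

### Variance attribution

Per-source SD models for tabulated counts: `relative` (sd = rel. SE ×
count; default ED 3%, death 0.5%), `zero` (default for the near-census
hospitalization source), and `poisson` (sd = √count). The default mimics
the survey-style SDs that accompany the real data. The replicate studies
(coverage, type-I error, deficit recovery) instead use the Poisson
attribution throughout, because calibration statements are only
meaningful when the stated SEs match the generating noise; under the
survey-style defaults the stated SEs deliberately differ from the
synthetic Poisson noise, and z-scores are mis-scaled by construction.

### Study sizes

Replicate studies use stratum populations of 1 000 000 (stratum-year
counts roughly 900–66 000), 500 replicates for APC recovery/coverage and
null calibration, 300 for deficit recovery, 1000 simulation draws per
projection; the full suite runs in a few minutes on one CPU. These sizes
give Monte Carlo error comfortably inside the asserted bands (binomial
3σ on a 5% rate at 500 replicates is ±2.9 points).

## Known limitations

* Totals count events, not unique persons; survivor bias and over/under
  counting across the cascade are structural features of the design.
* The standardized-rate and combined-total variances assume independence
  across age groups and sources respectively.
* The trend model is a single log-linear segment — no joinpoints, no
  autocorrelation-robust errors.
* Observed-vs-expected differences are descriptive; nothing attributes
  prevented events to any intervention.
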