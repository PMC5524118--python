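"""Estimate events prevented: observed versus expected with z-tests.

prevented = expected - observed; positive values are events prevented,
negative values are excess events.  Variances of the observed and
expected totals add, giving a z-score against the standard normal and a
symmetric 95% CI; |z| >= 1.96 flags significance.
"""

import heartsentinel as hs

# a stratum where observation fell below the stable baseline...
a = hs.events_prevented(observed=9_400, observed_sd=95.0,
                        expected=9_800, expected_sd=120.0,
                        scope="women >=75", years=[2012, 2013])
# ...and one with excess events
b = hs.events_prevented(observed=10_150, observed_sd=100.0,
                        expected=10_000, expected_sd=110.0,
                        scope="men 45-64", years=[2012, 2013])

for r in (a, b):
    kind = "prevented" if r.prevented >= 0 else "excess"
    print(f"{r.scope}: {r.prevented:+.0f} events ({kind}), "
          f"95% CI ({r.ci[0]:.0f}, {r.ci[1]:.0f}), z = {r.z:.2f}, "
          f"significant: {r.significant}")

overall = hs.combine([a, b], scope="overall")
print(f"\noverall: {overall.prevented:+.0f} events, "
      f"95% CI ({overall.ci[0]:.0f}, {overall.ci[1]:.0f}), z = {overall.z:.2f}")
print("\nCombining disjoint strata sums differences and variances; a combined")
print("|z| >= 1.96 means the pooled observed total differs from expectation.")
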