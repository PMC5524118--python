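"""Generate a synthetic multi-source surveillance dataset.

Builds encounter-level records for a survey-weighted ED sample, a
near-census hospitalization file, and a death registry, with each
stratum's true event rate following a known log-linear trend.
"""

import heartsentinel as hs

config = hs.default_sim_config(seed=42, population=100_000)
records, population = hs.generate_dataset(config)

print(f"{len(records)} encounter records, {config.years[0]}-{config.years[1]}")
print(records.head(8).to_string(index=False))
print()
truth = hs.true_parameters(config)
print("Generating truth (one row per stratum):")
print(truth[truth.year == config.years[0]]
      [["sex", "age_group", "true_apc", "true_rate"]].to_string(index=False))
print()
print("Each record carries a diagnosis/cause code, disposition flags, and a")
print("survey weight; true_apc is the annual percent change each stratum's")
print("rate follows, which the trend model should recover downstream.")
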