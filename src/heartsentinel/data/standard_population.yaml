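# Default standard population: approximate 2010 US decennial census
# distribution of adults aged >=18 across the four surveillance age groups.
# EDITABLE CONFIG: replace with the standard appropriate to your analysis.
"18-44": 0.481
"45-64": 0.347
"65-74": 0.0925
">=75": 0.0795
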