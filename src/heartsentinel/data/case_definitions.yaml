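# Default acute-CVD case definition.
#
# EDITABLE CONFIG, not ground truth: these are plausible ICD-9-CM primary
# diagnosis prefixes (ED/hospitalization) and ICD-10 underlying-cause
# prefixes (deaths) for the four event categories tracked by the pipeline.
# Production surveillance should replace this file with the code lists
# governing its own case definition.  Matching is prefix-based on
# dot-stripped, upper-cased codes; no prefix may appear in two categories.
ami:
  acute myocardial infarction:
    ed_hosp_codes: ["410"]
    death_codes: ["I21", "I22"]
stroke:
  acute ischemic cerebral infarction:
    ed_hosp_codes: ["433", "434"]
    death_codes: ["I63"]
  acute hemorrhagic stroke:
    ed_hosp_codes: ["430", "431", "432"]
    death_codes: ["I60", "I61", "I62"]
  acute ill-defined cerebrovascular disease:
    ed_hosp_codes: ["436"]
    death_codes: ["I64"]
symptomatic_precursor:
  other acute and subacute ischemic heart disease:
    ed_hosp_codes: ["411"]
    death_codes: ["I24"]
  stable angina pectoris:
    ed_hosp_codes: ["413"]
    death_codes: ["I20"]
  transient ischemic attack:
    ed_hosp_codes: ["435"]
    death_codes: ["G45"]
other_cvd:
  heart failure:
    ed_hosp_codes: ["428"]
    death_codes: ["I50"]
  hypertension without heart failure:
    ed_hosp_codes: ["401", "402"]
    death_codes: ["I10", "I11"]
  atherosclerosis and peripheral artery disease:
    ed_hosp_codes: ["440", "443"]
    death_codes: ["I70", "I73"]
  abdominal aortic aneurysm:
    ed_hosp_codes: ["441"]
    death_codes: ["I71"]
  cardiac arrest:
    ed_hosp_codes: ["4275"]
    death_codes: ["I46"]
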