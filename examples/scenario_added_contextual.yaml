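# Scenario 1: an additional contextual predictor (the derived county
# smoking rate) becomes available through linkage — a pure config change.
generate:
  n_patients: 2000
  brfss_n_per_county: 500
  tracts_per_county: 2
seed: 17
factors:
  - sex
  - marital_status
  - year_of_diagnosis
  - svi_socioeconomic
  - survival_months
  - county_smoking_rate
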