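# Baseline integration: the published example factor selection.
# Sources are generated synthetically; override `generate` to point the
# same run at a SQLite file or CSV directory via `source:` instead.
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
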