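# Scenario 3: a different grouping of the raw 10-level RUCA codes
# (metropolitan + micropolitan vs small town + rural) — again purely a
# configuration change.
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
  - rurality
ruca_grouping:
  1: metro-or-micro
  2: metro-or-micro
  3: metro-or-micro
  4: metro-or-micro
  5: metro-or-micro
  6: metro-or-micro
  7: town-or-rural
  8: town-or-rural
  9: town-or-rural
  10: town-or-rural
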