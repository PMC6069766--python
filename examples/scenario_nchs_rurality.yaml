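# Scenario 2: rurality resolved by a county-level urban-rural scheme
# instead of the tract-level RUCA codes.  The code table is user-supplied
# (county fips -> label); no external classification data ships.
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
rurality_scheme: nchs
nchs_codes:
  "12001": urban
  "12002": rural
  "12003": rural
  "12004": urban
  "12005": urban
  "12006": rural
  "12007": rural
  "12008": rural
  "12009": rural
  "12010": rural
  "12011": rural
  "12012": urban
  "12013": rural
  "12014": rural
  "12015": urban
  "12016": rural
  "12017": rural
  "12018": rural
  "12019": rural
  "12020": rural
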