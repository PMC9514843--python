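# Demo pipeline: a small synthetic census with selection against girls at
# second births after a first daughter (s=0.2) and at third births after two
# daughters (s=0.35), plus contaminant households at the default rates.
seed: 20
output_dir: csrkit_demo_out
generator:
  n_families: 20000
  baseline_female_prob: 0.48718
  selection_prob:
    "2,0,1": 0.20
    "3,0,2": 0.35
  strata:
    - country_of_residence: Canada
      census_year: 2016
      mother_ethnicity: Indian
      mother_birth_country: India
      n_families: 12000
    - country_of_residence: Canada
      census_year: 2016
      mother_ethnicity: Canadian
      mother_birth_country: Canada
      n_families: 8000
      selection_prob: {}   # domestic comparator: no selection
rules: {}
report:
  min_total: 100
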