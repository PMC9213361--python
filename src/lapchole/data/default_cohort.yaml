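n: 319
seed: 0
age_mean: 55.4
age_sd: 18.2
age_min: 18.0
p_female: 0.5799373040752351
asa_probs:
- 0.34169278996865204
- 0.43260188087774293
- 0.2225705329153605
- 0.003134796238244514
diagnosis_probs:
- 0.025078369905956112
- 0.41379310344827586
- 0.11598746081504702
- 0.445141065830721
admission_probs:
- 0.18181818181818182
- 0.7899686520376176
- 0.02821316614420063
wall_mean: 3.3
wall_sd: 1.7
cbd_mean: 4.9
cbd_sd: 2.1
p_ercp: 0.1974921630094044
alpha: -5.197334122442908
beta: 0.84375
target_prevalence: 0.5172413793103449
couple_covariates: false
cholecystitis_wall_shift: 1.5
outcome_rates:
  low:
    conversion: 0.0
    subtotal: 0.0
    cvs_failed: 0.029411764705882353
    bleeding: 0.0
    bile_leak: 0.0
    cbd_injury: 0.0
  intermediate:
    conversion: 0.016260162601626018
    subtotal: 0.032520325203252036
    cvs_failed: 0.056910569105691054
    bleeding: 0.016260162601626018
    bile_leak: 0.0
    cbd_injury: 0.0
  high:
    conversion: 0.08024691358024691
    subtotal: 0.08641975308641975
    cvs_failed: 0.14814814814814814
    bleeding: 0.024691358024691357
    bile_leak: 0.012345679012345678
    cbd_injury: 0.006172839506172839
exclusion_rates:
- 0.0
- 0.0
- 0.0
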