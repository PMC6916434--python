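n_probes: 2000
class_fractions:
  background_low: 0.325
  background_high: 0.325
  CCN: 0.15
  CIMP: 0.15
  hypo: 0.05
baselines:
  background_low: 0.1
  background_high: 0.85
  CCN: 0.08
  CIMP: 0.1
  hypo: 0.9
group_sizes:
  HNM: 100
  nonCIMP_CC: 20
  CIMP_CC: 20
  TA: 12
  SSAP: 12
age_range:
- 40.0
- 80.0
drift_rate_mean: 0.03
drift_rate_sd: 0.01
cimp_drift_fraction: 0.2
lifestyle_rate_multiplier:
  aspirin: 0.5
  hrt: 0.5
lifestyle_prevalence: 0.3
lifestyle_unknown_rate: 0.05
effect_sizes:
  CCN_in_all_CC: 0.3
  CIMP_in_SSAP: 0.17
  CIMP_in_CIMP_CC: 0.28
  hypo_in_CC: -0.3
precision: 50.0
n_batches: 2
batch_effect_sd: 0.2
location_effect_sd: 0.1
missing_rate: 0.02
sex_probe_fraction: 0.02
seed: 0
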