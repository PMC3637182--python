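# sod1_like_v1 — default parameter profile for the two-arm SOD1-like cohort
# simulator. Single source of truth for tests; values mirror the published
# study design where it states them (schedule, group size, euthanasia-era
# censoring) and otherwise are the package's fixed choices.
n_per_arm: 48
schedule_start_day: 42
schedule_switch_day: 63
schedule_end_day: 200
weibull_shape: 8.0
weibull_scale_control: 160.0
treatment_time_ratio: 1.0
onset_mean: 65.0
onset_sd: 8.0
onset_shift_treated: 6.0
symptom_prob_baseline: 0.0
symptom_prob_ramp: 0.08
weight_asymptote_mean_g: 25.0
weight_asymptote_sd_g: 2.0
weight_growth_midpoint_day: 35.0
weight_growth_tau_days: 12.0
weight_peak_age_mean: 100.0
weight_peak_age_sd: 8.0
weight_decline_rate: 0.005
weight_noise_sd: 0.3
hang_decline_age_mean: 95.0
hang_decline_age_sd: 8.0
hang_decline_rate: 1.5
hang_noise_sd: 3.0
injection_death_rate: 0.006
injection_death_min_age: 110.0
beam_params:
  latency_intercept: 15.0
  latency_size_slope: 1.5
  latency_treatment: -5.0
  latency_sd_intercept: 3.0
  latency_sd_slope: 0.3
  latency_sd_resid: 2.0
  slips_intercept: 0.2
  slips_size_slope: 0.15
  slips_treatment: -0.5
  slips_sd_intercept: 0.3
  slips_sd_slope: 0.05
  test_age_days: 119
seed: 0
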