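# Template run configuration for the mitephen CLI (see RunConfig).
# The simulator values below are a calibration that reproduces the
# qualitative patterns of real chill experiments; they are not measurements.
sim:
  hatch_logit_intercept: -3.3
  chill_day_coef: 0.035
  chill_day_cap: 100.0
  photoperiod_long_bonus: 0.8
  chill_temp_optimum: 4.0
  chill_temp_curvature: 0.02
  t50_base: 55.0
  t50_decay: 0.45
  t50_floor: 12.0
  hatch_time_cv: 0.35
  observation_interval: 10.0
  seed: 0
postdiapause:
  true_threshold: 5.47
  true_degree_days: 263.2
  rate_noise_sd: 0.05
  n_eggs: 50
  seed: 1
weather:
  annual_mean: 13.0
  annual_amplitude: 8.5
  coldest_day_of_year: 15
  daily_noise_sd: 2.0
  seed: 2
t50_denominator: hatched
apply_censoring: true
fit_weighting: null
time_summary: t50
termination_threshold: 0.5
termination_cutoff: 20.0
fill_single_gaps: false
seed: 0
out_dir: results
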