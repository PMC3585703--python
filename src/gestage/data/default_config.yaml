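# Default simulation configuration (schema v1).
#
# Availability rates follow the study conditions the generator emulates:
# LMP reported by 97.4% of women, certain for 76.9% of those; at least one
# ultrasound at 7-20 w for 78.6%, at 21-28 w for 59.8%, at 29+ w for 61.7%;
# Capurro exam recorded for 87.5%. The true GA-at-birth mixture is tuned so
# the cohort is ~12.5% preterm and ~2% postterm. Error-mechanism magnitudes
# (LMP recall SDs, month-slip probability, ultrasound window SDs, Capurro
# shrink) are order-of-magnitude choices documented in docs/methods.md.
schema_version: 1
n: 1483
seed: 0
ga:
  p_preterm: 0.125
  p_term: 0.855
  p_postterm: 0.020
  preterm: {mean_days: 247, sd_days: 16, lo_days: 168, hi_days: 258}
  term: {mean_days: 276, sd_days: 8, lo_days: 259, hi_days: 293}
  postterm: {mean_days: 297, sd_days: 3, lo_days: 294, hi_days: 308}
lmp_available_p: 0.974
lmp_certain_p: 0.769
lmp_error:
  sd_sure_days: 3.0
  sd_unsure_days: 7.0
  month_slip_p: 0.25
  slip_late_p: 0.8
us_window_p: [0.786, 0.598, 0.617]
us_error_sd_days: [4.0, 8.0, 14.0]
capurro_available_p: 0.875
capurro:
  shrink: 0.4
  target_days: 273
  noise_sd_days: 6.0
weight_noise_sd_multiplier: 1.0
gross_error_p: 0.01
sex_male_p: 0.51
covariate_p:
  city: [0.58, 0.42]
  age_group: [0.22, 0.69, 0.09]
  ethnicity: [0.36, 0.42, 0.22]
  schooling: [0.13, 0.44, 0.43]
  marital: [0.75, 0.25]
  parity: [0.45, 0.42, 0.13]
lmp_start: 2007-03-01
lmp_span_days: 365
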