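# Default synthetic cohort parameterization: an ADNI-like MCI sample with
# 391 subjects, 158 of whom convert to AD within 3 years and 15 of whom
# revert to normal cognition.  Group-conditional feature distributions
# (non-converter vs converter) and exact modality-availability counts.
#
# Binary feature probabilities carry their source fractions:
#   male:  158/233 (non-converter), 95/158 (converter)
#   apoe4:  66/198 (non-converter), 145/193 (converter)
n_total: 391
n_converters: 158
n_reverters: 15
correlation: 0.0
features:
- {name: age, kind: continuous, abnormal_direction: low,
   mean_neg: 75.0, sd_neg: 8.0, mean_pos: 74.0, sd_pos: 7.0,
   clip_min: 40.0, clip_max: 110.0}
- {name: male, kind: binary, abnormal_direction: low,
   p_neg: 0.6781115879828327, p_pos: 0.6012658227848101}
- {name: education_years, kind: continuous, abnormal_direction: low,
   mean_neg: 16.0, sd_neg: 3.0, mean_pos: 16.0, sd_pos: 3.0,
   clip_min: 0.0, clip_max: 30.0}
- {name: apoe4, kind: binary, abnormal_direction: high,
   p_neg: 0.3333333333333333, p_pos: 0.7512953367875648}
- {name: mmse, kind: integer, abnormal_direction: low,
   mean_neg: 27.3, sd_neg: 1.8, mean_pos: 26.7, sd_pos: 1.7,
   clip_min: 24, clip_max: 30}
- {name: ravlt_recall, kind: integer, abnormal_direction: low,
   mean_neg: 3.7, sd_neg: 3.6, mean_pos: 1.5, sd_pos: 2.1,
   clip_min: 0, clip_max: 15}
- {name: ravlt_recognition, kind: integer, abnormal_direction: low,
   mean_neg: 10.3, sd_neg: 3.5, mean_pos: 8.7, sd_pos: 3.6,
   clip_min: 0, clip_max: 15}
- {name: adas_cog11, kind: continuous, abnormal_direction: high,
   mean_neg: 10.3, sd_neg: 4.2, mean_pos: 13.3, sd_pos: 4.1,
   clip_min: 0.0, clip_max: 70.0}
- {name: adas_cog13, kind: continuous, abnormal_direction: high,
   mean_neg: 16.7, sd_neg: 6.1, mean_pos: 21.6, sd_pos: 5.4,
   clip_min: 0.0, clip_max: 85.0}
- {name: clock_drawing, kind: continuous, abnormal_direction: low,
   mean_neg: 4.4, sd_neg: 0.8, mean_pos: 3.9, sd_pos: 1.1,
   clip_min: 0.0, clip_max: 5.0}
- {name: digit_span_forward, kind: integer, abnormal_direction: low,
   mean_neg: 8.2, sd_neg: 2.0, mean_pos: 8.2, sd_pos: 2.0,
   clip_min: 0, clip_max: 16}
- {name: digit_span_backward, kind: integer, abnormal_direction: low,
   mean_neg: 6.2, sd_neg: 2.2, mean_pos: 6.0, sd_pos: 1.8,
   clip_min: 0, clip_max: 14}
- {name: category_fluency, kind: continuous, abnormal_direction: low,
   mean_neg: 16.3, sd_neg: 4.9, mean_pos: 15.3, sd_pos: 4.8,
   clip_min: 0.0, clip_max: 60.0}
- {name: tmt_a, kind: continuous, abnormal_direction: high,
   mean_neg: 41.8, sd_neg: 20.1, mean_pos: 49.7, sd_pos: 25.9,
   clip_min: 1.0, clip_max: null}
- {name: tmt_b, kind: continuous, abnormal_direction: high,
   mean_neg: 115.7, sd_neg: 67.5, mean_pos: 151.1, sd_pos: 67.5,
   clip_min: 1.0, clip_max: null}
- {name: digit_symbol, kind: continuous, abnormal_direction: low,
   mean_neg: 38.5, sd_neg: 11.2, mean_pos: 33.8, sd_pos: 11.0,
   clip_min: 0.0, clip_max: 110.0}
- {name: scheltens, kind: integer, abnormal_direction: high,
   mean_neg: 1.8, sd_neg: 0.9, mean_pos: 2.2, sd_pos: 0.9,
   clip_min: 0, clip_max: 4}
- {name: csf_tau, kind: continuous, abnormal_direction: high,
   mean_neg: 93.0, sd_neg: 61.0, mean_pos: 118.0, sd_pos: 57.0,
   clip_min: 1.0, clip_max: null}
- {name: csf_abeta42, kind: continuous, abnormal_direction: low,
   mean_neg: 178.0, sd_neg: 58.0, mean_pos: 144.0, sd_pos: 39.0,
   clip_min: 1.0, clip_max: null}
missingness:
  mri_available_total: 387
  csf_available_total: 199
  both_available_total: 195
  scheltens_available: {non_converter: 230, converter: 157}
  csf_available: {non_converter: 115, converter: 84}
  # APOE genotype availability; the converter count is capped at the
  # group size (the source fraction's denominator exceeds it).
  apoe_available: {non_converter: 198, converter: 158}
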