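# Full-pipeline configuration: synthetic cohort with the published
# regression coefficients injected as generating truths.
generator:
  n: 1934
  seed: 1
  effect_spec:
    gender: {Female: 0.115}
    area: {Eastern: 0.104, Western: 0.134}
    hours_per_week_band: {"<=40": -0.156, "41-60": -0.0817}
    outpatient_hours_band: {"~16": 0.0372, "~24": 0.123, "~40": 0.129, ">40": 0.250}
scheme:
  ov: sample_mean
  pc: minmax_plus1
  ps: scale_max
predictors: [gender, area, hours_per_week_band, outpatient_hours_band]
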