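# Parameter-recovery scenario: a single time-fixed binary covariate with a
# hazard rate ratio of 1.5 on the healthy-working exit, age effects as in
# the default scenario.  Used for coverage/recovery simulation studies.
name: recovery
states: 3
n_subjects: 2000
n_waves: 5
wave_interval: 2.0
wave_jitter: 0.2
max_age: 120
age_bands:
  50-60: 0.30
  60-70: 0.32
  70-80: 0.25
  80-90: 0.12
  90-100: 0.01
init_logit:
  intercept: -0.42
  age_slope: -0.035
baseline_hazards:
  HW-nHW: 0.08
  HW-dead: 0.001
  nHW-HW: 0.35
  nHW-dead: 0.0035
age_hrr:
  HW-nHW: 1.07
  HW-dead: 1.06
  nHW-HW: 0.86
  nHW-dead: 1.10
covariates:
  pain:
    prevalence: 0.28
    hrr: {HW-nHW: 1.5}
    flip_up: 0.0
    flip_down: 0.0
aux_agreement: 0.9
missingness:
  mechanism: none
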