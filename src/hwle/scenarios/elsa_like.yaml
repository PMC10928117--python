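# Default ELSA-like study conditions: ~2-yearly waves from a baseline
# cross-section aged 50+, three binary covariates at their observed
# population prevalences, Gompertz-type age effects matching the reported
# per-year hazard rate ratios, and an initial-state law calibrated so the
# baseline cross-section is ~27% healthy-and-working under the baseline
# age mix.
name: elsa_like
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
baseline_hazards:   # per-year intensities at age 50
  HW-nHW: 0.08
  HW-dead: 0.001
  nHW-HW: 0.35
  nHW-dead: 0.0035
age_hrr:            # per-year-of-age hazard rate ratios
  HW-nHW: 1.07
  HW-dead: 1.06
  nHW-HW: 0.86
  nHW-dead: 1.10
covariates:
  osteoarthritis:
    prevalence: 0.24
    hrr: {HW-nHW: 1.32, nHW-HW: 0.66, nHW-dead: 0.89}
    flip_up: 0.05
    flip_down: 0.0
  mental_health:
    prevalence: 0.25
    hrr: {HW-nHW: 1.36, nHW-HW: 0.51, nHW-dead: 1.63}
    flip_up: 0.05
    flip_down: 0.05
  pain:
    prevalence: 0.28
    hrr: {HW-nHW: 1.50, nHW-HW: 0.57, nHW-dead: 1.25}
    flip_up: 0.05
    flip_down: 0.05
aux_agreement: 0.9
missingness:
  mechanism: none
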