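# Illustrative UKPDS-OM2-style Gompertz proportional-hazards equation for
# renal failure (synthetic placeholder coefficients). The annual-cycle model
# is evaluated as a direct t-year cumulative risk 1 - exp(-H0(t) e^LP).
# The Afro-Caribbean ethnicity indicator is not collected in the target
# cohort and enters as a registry-declared constant (0).
name: ukpds_om2_renal_failure
outcome: renal_failure
family: gompertz_ph
horizon_years: 7.0
baseline:
  rate: 0.0009
  shape: 0.12
coefficients:
  egfr: -0.025
  sbp: 0.010
  female: -0.20
  afro_caribbean: 0.29
  hemoglobin: -0.14
centering:
  egfr: 97.38
  sbp: 127.28
  hemoglobin: 13.09
constants:
  afro_caribbean: 0.0
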