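# Illustrative RECODe-style Cox equation for 7-year microalbuminuria risk.
# Coefficient values are synthetic placeholders in the published structural
# form (baseline survival + centered log hazard ratios); substitute the
# published supplement values for real use.
name: recode_microalbuminuria
outcome: microalbuminuria
family: cox_baseline_survival
horizon_years: 7.0
baseline:
  s0: 0.70
coefficients:
  age: 0.012
  female: -0.08
  sbp: 0.012
  hba1c: 0.12
  uacr: 0.025
  egfr: -0.003
  smoking_current: 0.20
centering:
  age: 63.08
  sbp: 127.28
  hba1c: 7.43
  uacr: 11.93
  egfr: 97.38
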