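# Illustrative RECODe-style Cox equation for 7-year macroalbuminuria risk
# (synthetic placeholder coefficients; see recode_microalbuminuria.yaml).
name: recode_macroalbuminuria
outcome: macroalbuminuria
family: cox_baseline_survival
horizon_years: 7.0
baseline:
  s0: 0.95
coefficients:
  hba1c: 0.15
  uacr: 0.035
  sbp: 0.010
  retinopathy: 0.30
  egfr: -0.004
centering:
  hba1c: 7.43
  uacr: 11.93
  sbp: 127.28
  egfr: 97.38
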