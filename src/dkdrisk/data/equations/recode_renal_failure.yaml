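# Illustrative RECODe-style Cox equation for 7-year renal-failure risk
# (synthetic placeholder coefficients).
name: recode_renal_failure
outcome: renal_failure
family: cox_baseline_survival
horizon_years: 7.0
baseline:
  s0: 0.99
coefficients:
  egfr: -0.030
  hba1c: 0.10
  uacr: 0.020
  hemoglobin: -0.10
centering:
  egfr: 97.38
  hba1c: 7.43
  uacr: 11.93
  hemoglobin: 13.09
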