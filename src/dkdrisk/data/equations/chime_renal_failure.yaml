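# Illustrative CHIME-style Weibull proportional-hazards equation for
# renal failure (synthetic placeholder coefficients).
name: chime_renal_failure
outcome: renal_failure
family: weibull_ph
horizon_years: 7.0
baseline:
  rate: 0.0011
  shape: 1.25
coefficients:
  age: 0.02
  egfr: -0.030
  hba1c: 0.12
  uacr: 0.020
centering:
  age: 63.08
  egfr: 97.38
  hba1c: 7.43
  uacr: 11.93
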