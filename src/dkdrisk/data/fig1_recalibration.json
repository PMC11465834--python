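{
  "microalbuminuria": {
    "outcome": "microalbuminuria",
    "mode": "global",
    "delta": 1.212,
    "strata": [],
    "source_equation": "RECODe-microalbuminuria"
  },
  "macroalbuminuria": {
    "outcome": "macroalbuminuria",
    "mode": "stratified",
    "delta": null,
    "strata": [[0.024, 0.343], [1.0, 1.143]],
    "source_equation": "RECODe-macroalbuminuria"
  },
  "renal_failure": {
    "outcome": "renal_failure",
    "mode": "global",
    "delta": -2.107,
    "strata": [],
    "source_equation": "CHIME-renal-failure"
  }
}
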