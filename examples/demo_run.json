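{
  "seed": 7,
  "outdir": "demo_out",
  "template": {"simulate": true},
  "reads": {"simulate": true},
  "cohort": {"simulate": true},
  "models": [
    {"endpoint": "os", "coding": "tertile", "covariates": ["age", "kps", "idh1"]},
    {"endpoint": "os", "coding": "continuous", "covariates": ["age", "kps", "idh1"]},
    {"endpoint": "pfs", "coding": "tertile", "covariates": ["age", "idh1", "resection"]}
  ],
  "spline": {"basis": "rcs", "n_knots": 5},
  "diagnostics": ["schoenfeld", "martingale"]
}
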