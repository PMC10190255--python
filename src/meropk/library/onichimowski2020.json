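{
  "name": "onichimowski2020",
  "n_compartments": 2,
  "parameterization": "clearance-volume",
  "thetas": {"CL": 15.0, "V1": 22.0, "Q": 9.0, "V2": 30.0},
  "covariate_effects": [],
  "omega": [[0.35, 0.0], [0.0, 0.4]],
  "omega_labels": ["CL", "V1"],
  "residual_error": [
    {"kind": "proportional", "sd_proportional": 0.3, "variant_label": "default"}
  ],
  "population_medians": {},
  "provenance": "Onichimowski et al. 2020, CRRT patients; two-compartment, no covariates; typical CL 15 L/h (the clearance-overestimating candidate). V1/Q/V2, omega and sigma are transcription approximations.",
  "original_units": {}
}
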