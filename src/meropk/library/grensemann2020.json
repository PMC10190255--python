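{
  "name": "grensemann2020",
  "n_compartments": 2,
  "parameterization": "clearance-volume",
  "thetas": {"CL": 5.06, "V1": 14.8, "Q": 6.0, "V2": 17.2},
  "covariate_effects": [],
  "omega": [[0.12, 0.0], [0.0, 0.22]],
  "omega_labels": ["CL", "V1"],
  "residual_error": [
    {"kind": "combined", "sd_additive": 0.4, "sd_proportional": 0.19, "variant_label": "default"}
  ],
  "population_medians": {},
  "provenance": "Grensemann et al. 2020, critically ill CRRT patients; two-compartment, no covariates; typical CL 5.06 L/h. V1/Q/V2, omega and sigma are transcription approximations.",
  "original_units": {}
}
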