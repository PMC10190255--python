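{
  "name": "shekar2014",
  "n_compartments": 1,
  "parameterization": "clearance-volume",
  "thetas": {"CL": 5.1, "V1": 27.0},
  "covariate_effects": [],
  "omega": [[0.2, 0.0], [0.0, 0.15]],
  "omega_labels": ["CL", "V1"],
  "residual_error": [
    {"kind": "proportional", "sd_proportional": 0.23, "variant_label": "default"}
  ],
  "population_medians": {},
  "provenance": "Shekar et al. 2014, critically ill patients on extracorporeal support; one-compartment, no covariates; typical CL 5.1 L/h. V1, omega and sigma are transcription approximations.",
  "original_units": {}
}
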