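{
  "name": "ojeanson2021",
  "n_compartments": 2,
  "parameterization": "clearance-volume",
  "thetas": {"CL": 5.78, "V1": 18.4, "Q": 4.1, "V2": 22.1},
  "covariate_effects": [
    {
      "parameter": "CL",
      "covariate": "residual_diuresis",
      "form": "proportional-shift",
      "coefficients": [0.00033],
      "reference_value": 0.0
    }
  ],
  "omega": [[0.17, 0.0], [0.0, 0.28]],
  "omega_labels": ["CL", "V1"],
  "residual_error": [
    {"kind": "proportional", "sd_proportional": 0.21, "variant_label": "default"}
  ],
  "population_medians": {"residual_diuresis": 845, "weight": 80},
  "provenance": "O'Jeanson et al. 2021, critically ill patients with/without CRRT; two-compartment, residual diuresis (mL/24 h) as covariate on clearance; typical CL 5.78 L/h at zero residual diuresis, model-population median residual diuresis 845 mL/24 h. V1/Q/V2, omega, sigma and the diuresis slope are transcription approximations.",
  "original_units": {"residual_diuresis": "mL/24 h"}
}
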