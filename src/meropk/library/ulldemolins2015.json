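{
  "name": "ulldemolins2015",
  "n_compartments": 1,
  "parameterization": "clearance-volume",
  "thetas": {"CL": 3.7, "V1": 40.0},
  "covariate_effects": [
    {
      "parameter": "CL",
      "covariate": "residual_diuresis",
      "form": "proportional-shift",
      "coefficients": [0.00025],
      "reference_value": 0.0
    }
  ],
  "omega": [[0.18, 0.0], [0.0, 0.2]],
  "omega_labels": ["CL", "V1"],
  "residual_error": [
    {"kind": "proportional", "sd_proportional": 0.25, "variant_label": "default"}
  ],
  "population_medians": {"residual_diuresis": 100},
  "provenance": "Ulldemolins et al. 2015, septic-shock patients on CVVHDF; one-compartment, residual diuresis as covariate on clearance. All numeric values are transcription approximations (no typical clearance printed for this model).",
  "original_units": {"residual_diuresis": "mL/24 h"}
}
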