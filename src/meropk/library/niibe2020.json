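{
  "name": "niibe2020",
  "n_compartments": 2,
  "parameterization": "clearance-volume",
  "thetas": {"CL": 4.4, "V1": 12.9, "Q": 7.9, "V2": 14.2},
  "covariate_effects": [
    {
      "parameter": "CL",
      "covariate": "egfr_cg",
      "form": "power",
      "coefficients": [0.62],
      "reference_value": 31.0
    }
  ],
  "omega": [[0.11, 0.0], [0.0, 0.25]],
  "omega_labels": ["CL", "V1"],
  "residual_error": [
    {"kind": "proportional", "sd_proportional": 0.2, "variant_label": "default"}
  ],
  "population_medians": {"egfr_cg": 31},
  "provenance": "Niibe et al. 2020, CRRT patients; two-compartment, eGFR (Cockcroft-Gault) as covariate on clearance; typical CL 4.4 L/h at the median eGFR of 31. V1/Q/V2, omega, sigma and the eGFR exponent are transcription approximations.",
  "original_units": {"egfr_cg": "mL/min/1.73 m^2"}
}
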