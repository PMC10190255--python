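{
  "name": "burger2018",
  "n_compartments": 2,
  "parameterization": "clearance-volume",
  "thetas": {"CL": 4.7, "V1": 15.6, "Q": 5.2, "V2": 18.9},
  "covariate_effects": [
    {
      "parameter": "CL",
      "covariate": "total_flow_rate",
      "form": "linear",
      "coefficients": [0.0008],
      "reference_value": 2000.0
    }
  ],
  "omega": [[0.14, 0.0], [0.0, 0.3]],
  "omega_labels": ["CL", "V1"],
  "residual_error": [
    {"kind": "combined", "sd_additive": 0.8, "sd_proportional": 0.17, "variant_label": "combined"},
    {"kind": "proportional", "sd_proportional": 0.26, "variant_label": "proportional"},
    {"kind": "additive", "sd_additive": 2.4, "variant_label": "additive"}
  ],
  "population_medians": {"total_flow_rate": 2000},
  "provenance": "Burger et al. 2018, septic patients on CRRT; two-compartment, total flow rate (mL/h) as structural covariate on clearance; typical CL 4.7 L/h at the median total flow rate of 2,000 mL/h; three published residual-error variants. V1/Q/V2, omega, sigma values and the flow slope are transcription approximations.",
  "original_units": {"total_flow_rate": "mL/h"}
}
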