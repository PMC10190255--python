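{
  "name": "hanberg2018",
  "n_compartments": 2,
  "parameterization": "clearance-volume",
  "thetas": {"CL": 1.9, "V1": 11.4, "Q": 6.6, "V2": 12.4},
  "covariate_effects": [
    {
      "parameter": "CL",
      "covariate": "egfr_ckdepi",
      "form": "proportional-shift",
      "coefficients": [0.011],
      "reference_value": 41.0
    }
  ],
  "omega": [[0.25, 0.0], [0.0, 0.3]],
  "omega_labels": ["CL", "V1"],
  "residual_error": [
    {"kind": "combined", "sd_additive": 0.3, "sd_proportional": 0.24, "variant_label": "default"}
  ],
  "population_medians": {"egfr_ckdepi": 41},
  "provenance": "Hanberg et al. 2018, ECMO patients; two-compartment, eGFR (CKD-EPI) as covariate on clearance; typical CL 1.9 L/h at the median eGFR of 41 mL/min (the clearance-underestimating candidate). V1/Q/V2, omega, sigma and the eGFR slope are transcription approximations.",
  "original_units": {"egfr_ckdepi": "mL/min/1.73 m^2"}
}
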