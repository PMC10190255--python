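"""Inspect the bundled candidate models and their covariate effects.

Prints each model's structure and its population clearance at the
reference covariate values of the evaluation cohort (median patient).
The clearances of the well-predicting candidates cluster around 5 L/h;
the two outliers (around 15 and 2 L/h) are the models that over- and
under-predict concentrations, respectively.
"""

from meropk import bundled_model_names, load_bundled_model, typical_parameters

REFERENCE_COVARIATES = {
    "residual_diuresis": 0.0,  # mL/24 h (cohort median)
    "total_flow_rate": 2000.0,  # mL/h
    "egfr_cg": 31.0,
    "egfr_ckdepi": 41.0,  # mL/min
}

for name in bundled_model_names():
    model = load_bundled_model(name)
    params = typical_parameters(model, REFERENCE_COVARIATES)
    covs = ", ".join(e.covariate for e in model.covariate_effects) or "none"
    print(
        f"{name:18s} {model.n_compartments}-compartment  "
        f"CL = {params['CL']:5.2f} L/h  V1 = {params['V1']:5.1f} L  "
        f"covariates on CL: {covs}"
    )
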