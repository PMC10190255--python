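"""Forecast a second-occasion trough from one measured concentration.

A virtual patient is simulated from the O'Jeanson model with individual
random effects.  The a-priori forecast (covariates only) misses the
occasion-2 trough; conditioning the MAP estimate on the single measured
occasion-1 trough pulls the forecast toward the individual's truth —
the single-TDM-sample scenario of model-informed precision dosing.
"""

import numpy as np

from meropk import (
    DoseEvent,
    Observation,
    Subject,
    individual_parameters,
    load_bundled_model,
    map_estimate,
    predict_a_priori,
    predict_bayesian_occasion2,
    predict_concentration,
)

model = load_bundled_model("ojeanson2021")

# an individual clearing the drug slower than the population typical
eta_true = np.array([-0.4, 0.1])  # [CL, V1] on the log scale
doses = [DoseEvent(8.0 * k, 1000.0, 0.5) for k in range(3)]
covs = {"residual_diuresis": 0.0}
params = individual_parameters(model, covs, eta_true)
times = [7.75, 15.75]
truth = predict_concentration(params, doses, times).concentrations

subject = Subject(
    subject_id="demo",
    residual_diuresis=0.0,
    crrt_hours_after_first_dose=72.0,
    doses=doses,
    observations=[Observation(t, c) for t, c in zip(times, truth)],
)

a_priori = [r for r in predict_a_priori(model, subject) if r.occasion_index == 2][-1]
bayes = predict_bayesian_occasion2(model, subject)
est = map_estimate(model, subject, subject.observations[:1])

print(f"true occasion-2 trough     : {truth[1]:6.2f} mg/L")
print(f"a-priori forecast          : {a_priori.predicted:6.2f} mg/L "
      f"(error {a_priori.predicted - truth[1]:+.2f})")
print(f"Bayesian forecast (1 TDM)  : {bayes.predicted:6.2f} mg/L "
      f"(error {bayes.predicted - truth[1]:+.2f})")
print(f"MAP eta-hat = {np.round(est.eta_hat, 3)} vs true eta = {eta_true}")
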