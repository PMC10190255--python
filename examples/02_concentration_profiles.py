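"""Predict meropenem concentration-time profiles under CRRT.

Compares intermittent infusion (1,000 mg over 0.5 h every 8 h) with a
continuous infusion of 3,000 mg/24 h for a typical patient of the
O'Jeanson model without residual diuresis.  The continuous infusion
approaches its steady state rate/CL = 125 mg/h / 5.78 L/h ~= 21.6 mg/L,
while the intermittent regimen oscillates between peak and trough.
"""

import numpy as np

from meropk import DoseEvent, load_bundled_model, predict_concentration, typical_parameters

model = load_bundled_model("ojeanson2021")
params = typical_parameters(model, {"residual_diuresis": 0.0})
print(f"typical parameters: { {k: round(v, 2) for k, v in params.items()} }")

times = np.arange(0.25, 48.0, 0.25)

ii_doses = [DoseEvent(8.0 * k, 1000.0, 0.5) for k in range(6)]
ii = predict_concentration(params, ii_doses, times).concentrations

ci_doses = [DoseEvent(0.0, 3000.0 / 24.0 * 48.0, 48.0)]
ci = predict_concentration(params, ci_doses, times).concentrations

for label, c in [("intermittent", ii), ("continuous", ci)]:
    print(
        f"{label:12s} peak {c.max():5.1f} mg/L   "
        f"trough/terminal {c[-1]:5.1f} mg/L"
    )
print(f"continuous-infusion steady state (rate/CL): "
      f"{(3000 / 24) / params['CL']:.1f} mg/L")
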