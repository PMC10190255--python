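"""Generate a virtual CRRT cohort emulating the evaluation dataset.

The default recipe produces 73 subjects from two centers (56 intermittent
/ 17 continuous infusion) with the covariate medians and ranges of the
study population, and simulates concentrations from a chosen generating
model with inter-individual variability and residual error.  The dataset
round-trips through the rectangular event-table CSV dialect.
"""

import statistics
import tempfile
from pathlib import Path

from meropk import apply_inclusion_filter, read_dataset, write_dataset
from meropk.synthetic import default_recipe, generate_cohort

cohort = generate_cohort(default_recipe(seed=20230501))
included, excluded = apply_inclusion_filter(cohort)

med = lambda attr: statistics.median(getattr(s, attr) for s in cohort)
print(f"subjects: {len(cohort)} (center 1/2: "
      f"{sum(s.center == '1' for s in cohort)}/"
      f"{sum(s.center == '2' for s in cohort)}), "
      f"II/CI: {sum(s.dosing_strategy == 'II' for s in cohort)}/"
      f"{sum(s.dosing_strategy == 'CI' for s in cohort)}")
print(f"samples : {sum(len(s.observations) for s in cohort)}")
print(f"medians : age {med('age'):.0f} y, weight {med('weight'):.0f} kg, "
      f"flow {med('total_flow_rate'):.0f} mL/h, "
      f"residual diuresis {med('residual_diuresis'):.0f} mL/24 h")
print(f"inclusion filter: {len(included)} included, {len(excluded)} excluded")

with tempfile.TemporaryDirectory() as tmp:
    ev, cov = Path(tmp) / "events.csv", Path(tmp) / "covariates.csv"
    write_dataset(cohort, ev, cov)
    back = read_dataset(ev, cov)
    print(f"CSV round-trip: {len(back)} subjects restored, "
          f"{sum(len(s.observations) for s in back)} observations")
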