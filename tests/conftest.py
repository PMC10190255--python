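import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from meropk import (
    DoseEvent,
    Observation,
    Subject,
    apply_inclusion_filter,
    load_bundled_model,
)
from meropk.models import ModelSpec
from meropk.synthetic import default_recipe, generate_cohort

logging.getLogger("meropk").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ojeanson():
    return load_bundled_model("ojeanson2021")


@pytest.fixture(scope="session")
def small_cohort():
    """30 virtual subjects with occasions assigned (all pass inclusion)."""
    cohort = generate_cohort(default_recipe(seed=42, n_subjects=30))
    included, excluded = apply_inclusion_filter(cohort)
    assert not excluded
    return included


@pytest.fixture
def minimal_spec():
    """1-compartment, no covariates, proportional error 0.2."""
    return ModelSpec(
        name="minimal",
        n_compartments=1,
        thetas={"CL": 5.0, "V1": 30.0},
        omega=[[0.1]],
        omega_labels=["CL"],
        residual_error=[
            {"kind": "proportional", "sd_proportional": 0.2, "variant_label": "default"}
        ],
    )


def make_ii_subject(
    subject_id="T001",
    n_doses=3,
    interval=8.0,
    dose_mg=1000.0,
    obs=((7.75, 12.0), (23.0, 8.0)),
    **covs,
):
    """Intermittent-infusion subject with explicit observations."""
    defaults = dict(
        residual_diuresis=0.0,
        total_flow_rate=2000.0,
        crrt_hours_after_first_dose=72.0,
        age=60.0,
        weight=77.0,
        serum_creatinine=2.1,
        sex="male",
    )
    defaults.update(covs)
    return Subject(
        subject_id=subject_id,
        doses=[DoseEvent(interval * k, dose_mg, 0.5) for k in range(n_doses)],
        observations=[Observation(t, c) for t, c in obs],
        **defaults,
    )
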