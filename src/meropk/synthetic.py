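"""Virtual CRRT cohorts: the stand-in for the non-public clinical dataset.

The default recipe emulates the external-evaluation dataset's covariate
structure: 73 subjects from two centers (60/13), 56 intermittent- and 17
continuous-infusion patients (the retrospective second center used
continuous infusion exclusively), dialysis modality mix CVVH/CVVHD/CVVHDF
of roughly 59/32/10%, and covariate medians/ranges of age 60 y (19-89),
weight 77 kg (48-140), total flow rate 2,000 mL/h (1,500-5,700; fixed at
2,000 in center 2) and residual diuresis with median 0 and range up to
1,500 mL/24 h (zero-inflated; categorical classes in center 2, mapped to
their lower limits).  Concentrations are simulated from a chosen
generating model with full inter-individual variability and residual
error, and every generated subject satisfies the study inclusion filter
by construction.

Distribution families are solved from median + range by a simple
moment-matching heuristic: log-normal sigma = (ln high - ln low) / 5,
truncated-normal scale = (high - low) / 5 (a ~73-subject range spans about
+/-2.5 SD), then hard truncation at the declared bounds.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Literal, Mapping, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .cohort import Observation, Subject, map_residual_diuresis_category
from .models import ModelSpec, individual_parameters, load_bundled_model
from .pkcore import DoseEvent, simulate_observations

__all__ = [
    "CovariateDist",
    "CohortRecipe",
    "default_recipe",
    "generate_cohort",
    "inject_missingness",
]

log = logging.getLogger(__name__)

_OBS_FLOOR = 0.01  # mg/L; keeps simulated observations strictly positive


class CovariateDist(BaseModel):
    """One covariate's sampling distribution (median/range parameterized)."""

    family: Literal[
        "lognormal", "truncnorm", "zero-inflated-lognormal", "constant",
        "diuresis-category",
    ]
    median: float = 0.0
    low: float = 0.0
    high: float = 0.0
    p_zero: float = 0.0  # zero-inflated family only
    category_probs: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @model_validator(mode="after")
    def _check(self) -> "CovariateDist":
        if self.family in {"lognormal", "truncnorm", "zero-inflated-lognormal"}:
            if not self.low < self.high:
                raise ValueError("bounds must satisfy low < high")
            if self.family != "zero-inflated-lognormal" and not (
                self.low <= self.median <= self.high
            ):
                raise ValueError("median must lie inside [low, high]")
        if self.family == "diuresis-category":
            if abs(sum(self.category_probs) - 1.0) > 1e-9:
                raise ValueError("category probabilities must sum to 1")
        return self

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "constant":
            return self.median
        if self.family == "diuresis-category":
            cat = int(rng.choice([1, 2, 3], p=self.category_probs))
            return map_residual_diuresis_category(cat)
        if self.family == "truncnorm":
            scale = (self.high - self.low) / 5.0
            for _ in range(100):
                x = rng.normal(self.median, scale)
                if self.low <= x <= self.high:
                    return x
            return float(np.clip(x, self.low, self.high))
        # lognormal families: median/range of the positive part
        if self.family == "zero-inflated-lognormal" and rng.random() < self.p_zero:
            return 0.0
        lo = max(self.low, 1e-6)
        sigma = (np.log(self.high) - np.log(lo)) / 5.0
        mu = np.log(self.median) if self.median > 0 else (np.log(lo) + np.log(self.high)) / 2
        for _ in range(100):
            x = rng.lognormal(mu, sigma)
            if lo <= x <= self.high:
                return x
        return float(np.clip(x, lo, self.high))


class CohortRecipe(BaseModel):
    """Everything needed to generate a reproducible virtual cohort."""

    n_subjects: int = 73
    seed: int  # mandatory: cohorts are byte-identical per seed
    generating_model: str = "ojeanson2021"
    error_variant: Optional[str] = None
    center_fractions: dict[str, float] = Field(
        default_factory=lambda: {"1": 60 / 73, "2": 13 / 73}
    )
    n_continuous_infusion: int = 17  # center 2 is all-CI; remainder from center 1
    male_fraction: dict[str, float] = Field(
        default_factory=lambda: {"1": 0.72, "2": 0.77}
    )
    dialysis_probs: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: {
            "1": (0.72, 0.17, 0.11),  # CVVH, CVVHD, CVVHDF
            "2": (0.0, 1.0, 0.0),
        }
    )
    covariates: dict[str, dict[str, CovariateDist]] = Field(default_factory=dict)
    # regimen templates
    ii_dose_mg: float = 1000.0
    ii_interval_h: float = 8.0
    ii_infusion_duration_h: float = 0.5
    ci_daily_dose_mg: float = 3000.0
    ci_sampling_interval_h: float = 24.0
    # sampling template: one trough per occasion, 2 occasions by default
    p_three_samples: float = 11 / 73
    disable_iiv: bool = False
    disable_residual_error: bool = False

    @model_validator(mode="after")
    def _check(self) -> "CohortRecipe":
        if abs(sum(self.center_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("center fractions must sum to 1")
        if not 0 <= self.n_continuous_infusion <= self.n_subjects:
            raise ValueError("infeasible continuous-infusion count")
        if not self.covariates:
            self.covariates = _default_covariate_dists()
        return self


def _default_covariate_dists() -> dict[str, dict[str, CovariateDist]]:
    c1 = {
        "age": CovariateDist(family="truncnorm", median=56, low=19, high=87),
        "weight": CovariateDist(family="lognormal", median=77, low=48, high=140),
        "height": CovariateDist(family="truncnorm", median=170, low=150, high=190),
        "serum_albumin": CovariateDist(family="truncnorm", median=25, low=17, high=39),
        "serum_creatinine": CovariateDist(
            family="lognormal", median=2.0, low=0.6, high=6.1
        ),
        "total_flow_rate": CovariateDist(
            family="lognormal", median=2000, low=1500, high=5700
        ),
        "residual_diuresis": CovariateDist(
            family="zero-inflated-lognormal",
            median=400,
            low=50,
            high=1500,
            p_zero=0.55,
        ),
        "crrt_hours_after_first_dose": CovariateDist(
            family="truncnorm", median=120, low=24, high=240
        ),
    }
    c2 = {
        "age": CovariateDist(family="truncnorm", median=76, low=55, high=89),
        "weight": CovariateDist(family="lognormal", median=85, low=55, high=120),
        "height": CovariateDist(family="truncnorm", median=170, low=160, high=190),
        "serum_albumin": CovariateDist(family="truncnorm", median=18, low=8, high=28),
        "serum_creatinine": CovariateDist(
            family="lognormal", median=2.3, low=0.9, high=8.6
        ),
        "total_flow_rate": CovariateDist(family="constant", median=2000),
        "residual_diuresis": CovariateDist(
            family="diuresis-category", category_probs=(0.6, 0.2, 0.2)
        ),
        "crrt_hours_after_first_dose": CovariateDist(
            family="truncnorm", median=120, low=24, high=240
        ),
    }
    return {"1": c1, "2": c2}


def default_recipe(seed: int, **overrides) -> CohortRecipe:
    """The study-condition recipe (see module docstring) at a given seed."""
    return CohortRecipe(seed=seed, **overrides)


def generate_cohort(
    recipe: CohortRecipe, model: ModelSpec | None = None
) -> list[Subject]:
    """Generate a virtual cohort with simulated concentrations.

    Deterministic per seed.  All subjects pass the inclusion filter by
    construction (>=24 h CRRT, >=2 samples in >=2 occasions).
    """
    rng = np.random.default_rng(recipe.seed)
    if model is None:
        model = load_bundled_model(recipe.generating_model)

    centers = sorted(recipe.center_fractions)
    n2 = round(recipe.n_subjects * recipe.center_fractions.get("2", 0.0))
    n1 = recipe.n_subjects - n2
    center_of = ["1"] * n1 + ["2"] * n2
    # center 2 is all continuous infusion; the remainder comes from center 1
    n_ci_center1 = max(recipe.n_continuous_infusion - n2, 0)
    ci_flags = [False] * n1 + [True] * n2
    for idx in rng.choice(n1, size=min(n_ci_center1, n1), replace=False):
        ci_flags[idx] = True

    subjects: list[Subject] = []
    for i in range(recipe.n_subjects):
        center = center_of[i]
        dists = recipe.covariates[center]
        sex = "male" if rng.random() < recipe.male_fraction[center] else "female"
        dialysis = ("CVVH", "CVVHD", "CVVHDF")[
            int(rng.choice(3, p=np.asarray(recipe.dialysis_probs[center])
                           / np.sum(recipe.dialysis_probs[center])))
        ]
        cov = {name: dist.sample(rng) for name, dist in dists.items()}
        n_samples = 3 if rng.random() < recipe.p_three_samples else 2
        is_ci = ci_flags[i]
        if is_ci:
            horizon = recipe.ci_sampling_interval_h * n_samples + 12.0
            rate = recipe.ci_daily_dose_mg / 24.0
            doses = [DoseEvent(0.0, rate * horizon, horizon)]
            obs_times = [
                recipe.ci_sampling_interval_h * s - rng.uniform(0.5, 3.0)
                for s in range(1, n_samples + 1)
            ]
        else:
            tau = recipe.ii_interval_h
            doses = [
                DoseEvent(tau * k, recipe.ii_dose_mg, recipe.ii_infusion_duration_h)
                for k in range(n_samples)
            ]
            obs_times = [
                tau * s - rng.uniform(0.1, 0.5) for s in range(1, n_samples + 1)
            ]
        subject = Subject(
            subject_id=f"S{i + 1:03d}",
            center=center,
            sex=sex,
            age=cov["age"],
            weight=cov["weight"],
            height=cov["height"],
            serum_albumin=cov["serum_albumin"],
            serum_creatinine=cov["serum_creatinine"],
            dialysis_type=dialysis,
            total_flow_rate=cov["total_flow_rate"],
            residual_diuresis=cov["residual_diuresis"],
            crrt_hours_after_first_dose=cov["crrt_hours_after_first_dose"],
            dosing_strategy="CI" if is_ci else "II",
            doses=doses,
        )
        eta = np.zeros(model.n_eta)
        if not recipe.disable_iiv and model.n_eta:
            chol = np.linalg.cholesky(
                model.omega_matrix + 1e-12 * np.eye(model.n_eta)
            )
            eta = chol @ rng.standard_normal(model.n_eta)
        params = individual_parameters(
            model, {k: v for k, v in subject.covariates().items() if v is not None},
            eta,
        )
        if recipe.disable_residual_error:
            from .pkcore import predict_concentration

            y = predict_concentration(params, doses, obs_times).concentrations
        else:
            y = simulate_observations(
                model, params, doses, obs_times,
                error_variant=recipe.error_variant,
                rng=np.random.default_rng(rng.integers(2**31)),
            )
        subject.observations = [
            Observation(time=t, concentration=max(float(c), _OBS_FLOOR))
            for t, c in zip(obs_times, y)
        ]
        subjects.append(subject)
    return subjects


def inject_missingness(
    cohort: list[Subject],
    rates: Mapping[str, float],
    seed: int | None = 0,
) -> tuple[list[Subject], list[tuple[str, str]]]:
    """Mask covariate values at the given per-covariate rates.

    Returns the masked cohort and a log of (subject_id, covariate) masks so
    downstream imputation can be audited.  Rates above 1 are rejected; the
    study's reported missingness was below 11% per center.
    """
    for name, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {name!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    masked: list[Subject] = []
    mask_log: list[tuple[str, str]] = []
    for s in cohort:
        new = replace(s)
        for name, rate in rates.items():
            if not hasattr(new, name):
                raise KeyError(f"unknown covariate {name!r}")
            if getattr(new, name) is not None and rng.random() < rate:
                setattr(new, name, None)
                mask_log.append((s.subject_id, name))
        masked.append(new)
    if mask_log:
        log.info("masked %d covariate values", len(mask_log))
    return masked, mask_log
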