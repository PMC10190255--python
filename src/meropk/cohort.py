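"""Clinical-dataset model: subjects, occasions, inclusion, imputation, eGFR.

A *subject* carries covariates (one value each; time-varying covariates are
out of scope), a dosing history and observed concentrations.  An *occasion*
is the interval containing at least one measured concentration between two
dosing events — consecutive dosing events with no intervening measurement
are merged into one occasion.  For continuous infusion without bag changes
there are no internal dose events, so each observation defines its own
occasion with boundaries at the midpoints between consecutive samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import COVARIATE_VOCABULARY, ModelSpec
from .pkcore import DoseEvent

__all__ = [
    "Observation",
    "Subject",
    "OccasionPartition",
    "assign_occasions",
    "apply_inclusion_filter",
    "map_residual_diuresis_category",
    "impute_missing_covariates",
    "egfr_cockcroft_gault",
    "egfr_ckdepi",
    "write_dataset",
    "read_dataset",
]

log = logging.getLogger(__name__)

DIALYSIS_TYPES = ("CVVH", "CVVHD", "CVVHDF")

#: Lower limits of the categorical residual-diuresis classes used by the
#: retrospective center (class 1 > 1,000; class 2 = 500-1,000; class 3 < 500
#: mL/24 h; values set to the lower class limit).
_RESIDUAL_DIURESIS_CATEGORIES = {1: 1000.0, 2: 500.0, 3: 0.0}


@dataclass(frozen=True)
class Observation:
    time: float
    concentration: float
    occasion_index: int | None = None


@dataclass
class Subject:
    """One patient: covariates, dosing history, observed concentrations."""

    subject_id: str
    center: str = "1"
    sex: str | None = "male"  # "male" | "female"
    age: float | None = None  # years
    weight: float | None = None  # kg
    height: float | None = None  # cm
    serum_albumin: float | None = None  # g/L
    serum_creatinine: float | None = None  # mg/dL
    dialysis_type: str | None = None  # CVVH | CVVHD | CVVHDF
    total_flow_rate: float | None = None  # mL/h
    residual_diuresis: float | None = None  # mL/24 h
    crrt_hours_after_first_dose: float | None = None  # h
    dosing_strategy: str = "II"  # II | CI
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.doses = sorted(self.doses, key=lambda d: d.start_time)
        self.observations = sorted(self.observations, key=lambda o: o.time)
        if self.dialysis_type is not None and self.dialysis_type not in DIALYSIS_TYPES:
            raise ValueError(f"unknown dialysis type {self.dialysis_type!r}")

    def covariates(self) -> dict[str, float | None]:
        """Numeric covariate map resolvable by any model spec.

        eGFR values are derived from age/weight/creatinine/sex on the fly;
        categorical covariates are encoded as level indices (sex: male=0,
        female=1; dialysis type: CVVH=0, CVVHD=1, CVVHDF=2).
        """
        egfr_cg = egfr_ckd = None
        if None not in (self.age, self.weight, self.serum_creatinine, self.sex):
            egfr_cg = egfr_cockcroft_gault(
                self.age, self.weight, self.serum_creatinine, self.sex
            )
        if None not in (self.age, self.serum_creatinine, self.sex):
            egfr_ckd = egfr_ckdepi(self.age, self.serum_creatinine, self.sex)
        return {
            "sex": None if self.sex is None else float(self.sex == "female"),
            "age": self.age,
            "weight": self.weight,
            "height": self.height,
            "serum_albumin": self.serum_albumin,
            "serum_creatinine": self.serum_creatinine,
            "egfr_cg": egfr_cg,
            "egfr_ckdepi": egfr_ckd,
            "dialysis_type": (
                None
                if self.dialysis_type is None
                else float(DIALYSIS_TYPES.index(self.dialysis_type))
            ),
            "total_flow_rate": self.total_flow_rate,
            "residual_diuresis": self.residual_diuresis,
            "crrt_hours_after_first_dose": self.crrt_hours_after_first_dose,
        }

    def observation_times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations], dtype=float)


@dataclass
class OccasionPartition:
    subject_id: str
    boundaries: list[tuple[float, float]]  # half-open [lo, hi), 1-based order
    observation_occasions: list[int]  # occasion index per observation
    has_predose_observations: bool = False

    @property
    def n_occasions(self) -> int:
        return len(self.boundaries)


def assign_occasions(subject: Subject) -> OccasionPartition:
    """Partition a subject's timeline into dosing occasions.

    Boundaries sit at dose events; dose events with no intervening
    measurement merge into the following occasion.  Observations before the
    first dose are flagged and assigned pseudo-occasion 0.  The assignment
    is idempotent and earlier occasions are stable under appending later
    observations.
    """
    if not subject.doses or not subject.observations:
        raise ValueError("occasion assignment needs >=1 dose and >=1 observation")
    obs_t = subject.observation_times()
    dose_t = [d.start_time for d in subject.doses]

    if subject.dosing_strategy == "CI" and len(subject.doses) == 1:
        return _assign_occasions_continuous(subject, obs_t, dose_t[0])

    edges = dose_t + [math.inf]
    boundaries: list[tuple[float, float]] = []
    start = dose_t[0]
    for i in range(len(dose_t)):
        lo, hi = edges[i], edges[i + 1]
        if np.any((obs_t >= lo) & (obs_t < hi)):
            boundaries.append((start, hi))
            start = hi
    predose = bool(np.any(obs_t < dose_t[0]))
    if predose:
        log.info(
            "subject %s: observation(s) before first dose assigned to "
            "pseudo-occasion 0",
            subject.subject_id,
        )
    occ_of_obs = []
    for t in obs_t:
        if t < dose_t[0]:
            occ_of_obs.append(0)
            continue
        idx = next(
            (k + 1 for k, (lo, hi) in enumerate(boundaries) if lo <= t < hi), None
        )
        if idx is None:  # cannot happen: last boundary reaches +inf
            raise AssertionError("observation escaped occasion partition")
        occ_of_obs.append(idx)
    return OccasionPartition(
        subject_id=subject.subject_id,
        boundaries=boundaries,
        observation_occasions=occ_of_obs,
        has_predose_observations=predose,
    )


def _assign_occasions_continuous(
    subject: Subject, obs_t: np.ndarray, infusion_start: float
) -> OccasionPartition:
    """Midpoint split for continuous infusion with no bag changes."""
    post = obs_t[obs_t >= infusion_start]
    mids = [(a + b) / 2.0 for a, b in zip(post[:-1], post[1:])]
    edges = [infusion_start] + mids + [math.inf]
    boundaries = list(zip(edges[:-1], edges[1:]))
    occ_of_obs = []
    for t in obs_t:
        if t < infusion_start:
            occ_of_obs.append(0)
        else:
            occ_of_obs.append(
                next(k + 1 for k, (lo, hi) in enumerate(boundaries) if lo <= t < hi)
            )
    return OccasionPartition(
        subject_id=subject.subject_id,
        boundaries=boundaries,
        observation_occasions=occ_of_obs,
        has_predose_observations=bool(np.any(obs_t < infusion_start)),
    )


def with_occasions(subject: Subject) -> Subject:
    """Return a copy whose observations carry their occasion indices."""
    part = assign_occasions(subject)
    obs = [
        replace(o, occasion_index=k)
        for o, k in zip(subject.observations, part.observation_occasions)
    ]
    new = replace(subject)
    new.observations = obs
    return new


def apply_inclusion_filter(
    subjects: Iterable[Subject],
) -> tuple[list[Subject], list[tuple[Subject, str]]]:
    """Study inclusion: >=24 h on CRRT after the first dose and >=2 measured
    concentrations spread over >=2 occasions.

    Returns (included, excluded-with-machine-readable-reason); every
    included subject has occasion indices assigned.
    """
    included: list[Subject] = []
    excluded: list[tuple[Subject, str]] = []
    for s in subjects:
        if s.crrt_hours_after_first_dose is None or s.crrt_hours_after_first_dose < 24:
            excluded.append((s, "crrt_duration<24h"))
            continue
        if len(s.observations) < 2:
            excluded.append((s, "fewer_than_2_observations"))
            continue
        s2 = with_occasions(s)
        real_occ = {o.occasion_index for o in s2.observations if o.occasion_index}
        if len(real_occ) < 2:
            excluded.append((s, "observations_span_fewer_than_2_occasions"))
            continue
        included.append(s2)
    for s, reason in excluded:
        log.info("subject %s excluded: %s", s.subject_id, reason)
    return included, excluded


def map_residual_diuresis_category(category: int) -> float:
    """Map a categorical residual-diuresis class to mL/24 h (lower limit)."""
    try:
        return _RESIDUAL_DIURESIS_CATEGORIES[int(category)]
    except (KeyError, ValueError):
        raise ValueError(
            f"residual diuresis category must be 1, 2 or 3; got {category!r}"
        ) from None


def impute_missing_covariates(subject: Subject, model: ModelSpec) -> Subject:
    """Fill covariates the model needs with its population medians.

    Present values are never overwritten, so re-running is idempotent.
    Raises when a needed median is not declared by the spec.
    """
    covs = subject.covariates()
    new = replace(subject)
    for name in model.required_covariates():
        if covs.get(name) is not None:
            continue
        if name not in model.population_medians:
            raise KeyError(
                f"covariate {name!r} missing for subject {subject.subject_id} and "
                f"model {model.name!r} declares no population median"
            )
        value = float(model.population_medians[name])
        if hasattr(new, name):
            setattr(new, name, value)
            log.info(
                "subject %s: imputed %s=%g from %s population median",
                subject.subject_id,
                name,
                value,
                model.name,
            )
        else:
            raise KeyError(f"cannot impute derived covariate {name!r}")
    return new


def model_covariates(subject: Subject, model: ModelSpec) -> dict[str, float]:
    """Covariate map for a model, imputing missing values from its medians.

    Derived covariates (eGFR) that stay unresolved after imputing their
    inputs fall back to the model's own median when declared.
    """
    s = impute_missing_covariates(subject, model)
    covs = s.covariates()
    for name in model.required_covariates():
        if covs.get(name) is None and name in model.population_medians:
            covs[name] = float(model.population_medians[name])
    return {k: v for k, v in covs.items() if v is not None}


# ---------------------------------------------------------------------------
# eGFR equations


def egfr_cockcroft_gault(
    age: float, weight: float, serum_creatinine: float, sex: str
) -> float:
    """Cockcroft-Gault creatinine clearance in mL/min.

    ``((140 - age) * weight) / (72 * Scr)``, times 0.85 for females.
    """
    if serum_creatinine <= 0:
        raise ValueError("serum creatinine must be > 0")
    if age <= 0 or weight <= 0:
        raise ValueError("age and weight must be > 0")
    cg = (140.0 - age) * weight / (72.0 * serum_creatinine)
    if sex == "female":
        cg *= 0.85
    return cg


def egfr_ckdepi(age: float, serum_creatinine: float, sex: str) -> float:
    """CKD-EPI 2009 creatinine equation, mL/min/1.73 m^2 (race term omitted)."""
    if serum_creatinine <= 0:
        raise ValueError("serum creatinine must be > 0")
    if age <= 0:
        raise ValueError("age must be > 0")
    if sex == "female":
        kappa, alpha, fac = 0.7, -0.329, 1.018
    else:
        kappa, alpha, fac = 0.9, -0.411, 1.0
    r = serum_creatinine / kappa
    return 141.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.209 * 0.993**age * fac


# ---------------------------------------------------------------------------
# dataset I/O: NONMEM-style event table + subject-level covariate table

_EVENT_COLUMNS = ["ID", "TIME", "AMT", "RATE", "DUR", "DV", "EVID"]
_COVARIATE_COLUMNS = [
    "subject_id",
    "center",
    "sex",
    "age",
    "weight",
    "height",
    "serum_albumin",
    "serum_creatinine",
    "dialysis_type",
    "total_flow_rate",
    "residual_diuresis",
    "crrt_hours_after_first_dose",
    "dosing_strategy",
]


def write_dataset(
    subjects: Sequence[Subject],
    events_path: str | Path,
    covariates_path: str | Path,
) -> None:
    """Write a cohort as two CSVs: a rectangular event table (ID, TIME, AMT,
    RATE, DUR, DV, EVID) and a subject-level covariate table."""
    rows = []
    for s in subjects:
        for d in s.doses:
            rows.append(
                dict(
                    ID=s.subject_id,
                    TIME=d.start_time,
                    AMT=d.amount,
                    RATE=d.rate,
                    DUR=d.duration,
                    DV=np.nan,
                    EVID=1,
                )
            )
        for o in s.observations:
            rows.append(
                dict(
                    ID=s.subject_id,
                    TIME=o.time,
                    AMT=np.nan,
                    RATE=np.nan,
                    DUR=np.nan,
                    DV=o.concentration,
                    EVID=0,
                )
            )
    ev = pd.DataFrame(rows, columns=_EVENT_COLUMNS).sort_values(
        ["ID", "TIME", "EVID"], kind="stable"
    )
    ev.to_csv(events_path, index=False)

    cov_rows = [
        {c: getattr(s, c) for c in _COVARIATE_COLUMNS} for s in subjects
    ]
    pd.DataFrame(cov_rows, columns=_COVARIATE_COLUMNS).to_csv(
        covariates_path, index=False
    )


def read_dataset(
    events_path: str | Path, covariates_path: str | Path
) -> list[Subject]:
    """Read a cohort written by :func:`write_dataset` (lossless round-trip)."""
    ev = pd.read_csv(events_path, dtype={"ID": str})
    cov = pd.read_csv(covariates_path, dtype={"subject_id": str})
    missing = set(_EVENT_COLUMNS) - set(ev.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    subjects = []
    for _, row in cov.iterrows():
        sid = row["subject_id"]
        sub_ev = ev[ev["ID"] == sid]
        doses = [
            DoseEvent(start_time=r.TIME, amount=r.AMT, duration=r.DUR)
            for r in sub_ev[sub_ev["EVID"] == 1].itertuples()
        ]
        obs = [
            Observation(time=r.TIME, concentration=r.DV)
            for r in sub_ev[sub_ev["EVID"] == 0].itertuples()
        ]

        def _get(name):
            v = row[name]
            return None if pd.isna(v) else v

        subjects.append(
            Subject(
                subject_id=sid,
                center=str(row["center"]),
                sex=_get("sex"),
                age=_get("age"),
                weight=_get("weight"),
                height=_get("height"),
                serum_albumin=_get("serum_albumin"),
                serum_creatinine=_get("serum_creatinine"),
                dialysis_type=_get("dialysis_type"),
                total_flow_rate=_get("total_flow_rate"),
                residual_diuresis=_get("residual_diuresis"),
                crrt_hours_after_first_dose=_get("crrt_hours_after_first_dose"),
                dosing_strategy=row["dosing_strategy"],
                doses=doses,
                observations=obs,
            )
        )
    return subjects
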