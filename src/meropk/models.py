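"""Declarative population-PK model specifications.

A PopPK model is described by its structural compartment model
(clearance--volume parameterization), typical parameter values (thetas),
covariate effects on those parameters, an inter-individual variability
(IIV) covariance matrix ``omega`` on the log scale, and one or more
residual-error models ``sigma``.  Specs are stored as JSON (or YAML) files
so the evaluation framework never hard-codes a published model.

Canonical units: time h, concentration mg/L, amount mg, CL and Q L/h,
volumes L, flow rates mL/h, residual diuresis mL/24 h.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterator, Literal, Mapping, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "COVARIATE_VOCABULARY",
    "CovariateEffect",
    "ResidualErrorModel",
    "ModelSpec",
    "load_model_spec",
    "save_model_spec",
    "bundled_model_names",
    "load_bundled_model",
    "typical_parameters",
    "individual_parameters",
]

#: Covariates a Subject may carry; every covariate named by a spec must be
#: resolvable against this vocabulary.
COVARIATE_VOCABULARY = frozenset(
    {
        "sex",
        "age",
        "weight",
        "height",
        "serum_albumin",
        "serum_creatinine",
        "egfr_cg",
        "egfr_ckdepi",
        "dialysis_type",
        "total_flow_rate",
        "residual_diuresis",
        "crrt_hours_after_first_dose",
    }
)

_PK_PARAMS_1CMT = ("CL", "V1")
_PK_PARAMS_2CMT = ("CL", "V1", "Q", "V2")


class CovariateEffect(BaseModel):
    """One covariate effect on one PK parameter.

    Supported functional forms (``theta`` is the running parameter value,
    ``x`` the covariate, ``r`` the reference value, ``c`` the coefficients):

    - ``linear``: ``theta + c[0] * (x - r)`` (additive slope)
    - ``power``: ``theta * (x / r) ** c[0]``
    - ``proportional-shift``: ``theta * (1 + c[0] * (x - r))``
    - ``categorical-factor``: ``theta * c[int(x)]`` (level index into the
      coefficient list; the reference level carries an explicit 1.0)

    Effects are applied in declaration order, which is preserved by the
    loaders (round-trip stable).
    """

    parameter: str
    covariate: str
    form: Literal["linear", "power", "proportional-shift", "categorical-factor"]
    coefficients: list[float]
    reference_value: float = 0.0

    @field_validator("coefficients")
    @classmethod
    def _finite(cls, v: list[float]) -> list[float]:
        if not v or not np.all(np.isfinite(v)):
            raise ValueError("coefficients must be nonempty and finite")
        return v

    @model_validator(mode="after")
    def _check(self) -> "CovariateEffect":
        if self.covariate not in COVARIATE_VOCABULARY:
            raise ValueError(
                f"covariate {self.covariate!r} is not in the subject vocabulary"
            )
        if self.form == "power" and self.reference_value <= 0:
            raise ValueError("power form requires reference_value > 0")
        return self

    def apply(self, value: float, covariate_value: float) -> float:
        x, r, c = covariate_value, self.reference_value, self.coefficients
        if self.form == "linear":
            return value + c[0] * (x - r)
        if self.form == "power":
            return value * (x / r) ** c[0]
        if self.form == "proportional-shift":
            return value * (1.0 + c[0] * (x - r))
        # categorical-factor
        level = int(round(x))
        if not 0 <= level < len(c):
            raise ValueError(
                f"categorical level {level} outside coefficient list for "
                f"{self.covariate!r}"
            )
        return value * c[level]


class ResidualErrorModel(BaseModel):
    """Residual unexplained variability on observed concentrations.

    ``y = f * (1 + eps_prop) + eps_add`` with centered normal errors of
    standard deviation ``sd_proportional`` (fraction) and ``sd_additive``
    (mg/L).  A model may publish several variants (e.g. Burger 2018 carries
    three); each is identified by ``variant_label``.
    """

    kind: Literal["additive", "proportional", "combined"]
    sd_additive: float = Field(default=0.0, ge=0.0)
    sd_proportional: float = Field(default=0.0, ge=0.0)
    variant_label: str = "default"

    @model_validator(mode="after")
    def _check(self) -> "ResidualErrorModel":
        if self.kind == "additive" and self.sd_additive <= 0:
            raise ValueError("additive error requires sd_additive > 0")
        if self.kind == "proportional" and self.sd_proportional <= 0:
            raise ValueError("proportional error requires sd_proportional > 0")
        if self.kind == "combined" and (
            self.sd_additive <= 0 or self.sd_proportional <= 0
        ):
            raise ValueError("combined error requires both SDs > 0")
        return self

    def variance(self, f: np.ndarray) -> np.ndarray:
        """Residual variance g^2(f) = sd_add^2 + sd_prop^2 * f^2."""
        return self.sd_additive**2 + (self.sd_proportional * np.asarray(f)) ** 2


class ModelSpec(BaseModel):
    """A complete published PopPK model in declarative form."""

    name: str
    n_compartments: Literal[1, 2]
    parameterization: Literal["clearance-volume"] = "clearance-volume"
    thetas: dict[str, float]
    covariate_effects: list[CovariateEffect] = Field(default_factory=list)
    omega: list[list[float]]
    omega_labels: list[str]
    residual_error: list[ResidualErrorModel]
    population_medians: dict[str, float] = Field(default_factory=dict)
    provenance: str = ""
    original_units: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "ModelSpec":
        required = _PK_PARAMS_1CMT if self.n_compartments == 1 else _PK_PARAMS_2CMT
        missing = [p for p in required for _ in [0] if p not in self.thetas]
        if missing:
            raise ValueError(f"thetas missing required parameters {missing}")
        for k, v in self.thetas.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"theta {k!r} must be finite and > 0, got {v}")
        om = (
            np.zeros((0, 0))
            if not self.omega
            else np.asarray(self.omega, dtype=float)
        )
        if om.ndim != 2 or om.shape[0] != om.shape[1]:
            raise ValueError("omega must be a square matrix")
        if om.shape[0] != len(self.omega_labels):
            raise ValueError("omega dimension must match omega_labels length")
        if not np.allclose(om, om.T, atol=1e-12):
            raise ValueError("omega must be symmetric")
        if om.size and np.linalg.eigvalsh(om).min() < -1e-10:
            raise ValueError("omega is not positive semi-definite")
        for lbl in self.omega_labels:
            if lbl not in self.thetas:
                raise ValueError(f"omega label {lbl!r} has no matching theta")
        if not self.residual_error:
            raise ValueError("at least one residual error model is required")
        for eff in self.covariate_effects:
            if eff.parameter not in self.thetas:
                raise ValueError(
                    f"covariate effect targets unknown parameter {eff.parameter!r}"
                )
        return self

    # -- convenience accessors -------------------------------------------
    @property
    def pk_parameter_names(self) -> tuple[str, ...]:
        return _PK_PARAMS_1CMT if self.n_compartments == 1 else _PK_PARAMS_2CMT

    @property
    def omega_matrix(self) -> np.ndarray:
        if not self.omega:
            return np.zeros((0, 0))
        return np.asarray(self.omega, dtype=float)

    @property
    def n_eta(self) -> int:
        return len(self.omega_labels)

    def error_variant(self, label: str | None = None) -> ResidualErrorModel:
        if label is None:
            return self.residual_error[0]
        for re_ in self.residual_error:
            if re_.variant_label == label:
                return re_
        available = [r.variant_label for r in self.residual_error]
        raise KeyError(
            f"model {self.name!r} has no residual-error variant {label!r}; "
            f"available: {available}"
        )

    def required_covariates(self) -> list[str]:
        seen: list[str] = []
        for eff in self.covariate_effects:
            if eff.covariate not in seen:
                seen.append(eff.covariate)
        return seen


# ---------------------------------------------------------------------------
# spec I/O


def load_model_spec(path: str | Path) -> ModelSpec:
    """Load and validate a model spec from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return ModelSpec.model_validate(data)


def save_model_spec(spec: ModelSpec, path: str | Path) -> None:
    """Write a spec to JSON (or YAML when the suffix says so)."""
    path = Path(path)
    data = spec.model_dump(mode="json")
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


_LIBRARY_DIR = Path(__file__).parent / "library"


def bundled_model_names() -> list[str]:
    """Names of the candidate model specs shipped with the package."""
    return sorted(p.stem for p in _LIBRARY_DIR.glob("*.json"))


def load_bundled_model(name: str) -> ModelSpec:
    path = _LIBRARY_DIR / f"{name}.json"
    if not path.exists():
        raise FileNotFoundError(
            f"no bundled model {name!r}; available: {bundled_model_names()}"
        )
    return load_model_spec(path)


def iter_bundled_models() -> Iterator[ModelSpec]:
    for name in bundled_model_names():
        yield load_bundled_model(name)


# ---------------------------------------------------------------------------
# parameter computation


def typical_parameters(
    model: ModelSpec, covariates: Mapping[str, float]
) -> dict[str, float]:
    """Population-typical PK parameters for a covariate vector.

    Applies each covariate effect to its theta in declaration order.
    Raises ``KeyError`` when a required covariate is absent (imputation is
    the caller's job, see :mod:`meropk.cohort`).
    """
    params = {k: float(v) for k, v in model.thetas.items()}
    for eff in model.covariate_effects:
        if eff.covariate not in covariates or covariates[eff.covariate] is None:
            raise KeyError(
                f"covariate {eff.covariate!r} required by model {model.name!r} "
                "is missing"
            )
        params[eff.parameter] = eff.apply(
            params[eff.parameter], float(covariates[eff.covariate])
        )
    bad = {k: v for k, v in params.items() if not (np.isfinite(v) and v > 0)}
    if bad:
        raise ValueError(
            f"non-positive typical parameters {bad} for model {model.name!r}"
        )
    return params


def individual_parameters(
    model: ModelSpec,
    covariates: Mapping[str, float],
    eta: Sequence[float] | np.ndarray,
) -> dict[str, float]:
    """Individual parameters under log-normal IIV.

    ``param_k = typical_k * exp(eta_k)`` for every parameter with IIV;
    ``eta = 0`` reproduces :func:`typical_parameters` exactly.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (model.n_eta,):
        raise ValueError(
            f"eta has shape {eta.shape}, expected ({model.n_eta},) for model "
            f"{model.name!r}"
        )
    params = typical_parameters(model, covariates)
    for lbl, e in zip(model.omega_labels, eta):
        params[lbl] = params[lbl] * float(np.exp(e))
    return params
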