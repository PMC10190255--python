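"""A-priori (population) and single-sample MAP Bayesian forecasting.

Two prediction arms mirror clinical use of a PopPK model:

* *a priori* — covariates only, individual random effects at zero; the
  prediction available before any drug level is measured.
* *Bayesian* — the individual random effects are set to their maximum a
  posteriori (MAP) value conditioned on measured concentration(s); by
  default exactly one sample, the last (trough) measurement of the first
  dosing occasion, is used to forecast the trough of the second occasion.

The MAP objective is the standard extended-least-squares posterior mode::

    sum_j [ (y_j - f_j(eta))^2 / g_j^2 + ln g_j^2 ]  +  eta' Omega^-1 eta

with residual variance ``g_j^2 = sd_add^2 + sd_prop^2 f_j^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .cohort import Observation, Subject, model_covariates, with_occasions
from .models import ModelSpec, individual_parameters, typical_parameters
from .pkcore import predict_concentration

__all__ = [
    "PredictionRecord",
    "MapEstimate",
    "predict_a_priori",
    "map_estimate",
    "predict_bayesian_occasion2",
    "trough_observation",
]

log = logging.getLogger(__name__)

_VARIANCE_FLOOR = 1e-10  # keeps the likelihood finite when f -> 0
_N_JITTER_STARTS = 4
_JITTER_SEED = 202306  # fixed multistart seed: MAP is deterministic given inputs


@dataclass(frozen=True)
class PredictionRecord:
    subject_id: str
    time: float
    observed: float
    predicted: float
    prediction_type: str  # "a_priori" | "bayesian"
    occasion_index: int

    def __post_init__(self) -> None:
        if self.observed <= 0:
            raise ValueError("observed concentration must be > 0")
        if self.predicted < 0:
            raise ValueError("predicted concentration must be >= 0")


@dataclass
class MapEstimate:
    eta_hat: np.ndarray
    objective_value: float
    converged: bool
    n_restarts_used: int


def predict_a_priori(model: ModelSpec, subject: Subject) -> list[PredictionRecord]:
    """Population predictions (eta = 0) at every observation time."""
    subject = _ensure_occasions(subject)
    params = typical_parameters(model, model_covariates(subject, model))
    times = subject.observation_times()
    prof = predict_concentration(params, subject.doses, times)
    return [
        PredictionRecord(
            subject_id=subject.subject_id,
            time=o.time,
            observed=o.concentration,
            predicted=float(c),
            prediction_type="a_priori",
            occasion_index=o.occasion_index,
        )
        for o, c in zip(subject.observations, prof.concentrations)
    ]


def _map_objective(
    eta: np.ndarray,
    model: ModelSpec,
    covariates: dict[str, float],
    subject: Subject,
    obs_times: np.ndarray,
    obs_y: np.ndarray,
    err,
    omega_inv: np.ndarray,
) -> float:
    params = individual_parameters(model, covariates, eta)
    f = predict_concentration(params, subject.doses, obs_times).concentrations
    g2 = np.maximum(err.variance(f), _VARIANCE_FLOOR)
    resid = np.sum((obs_y - f) ** 2 / g2 + np.log(g2))
    prior = float(eta @ omega_inv @ eta)
    return float(resid + prior)


def map_estimate(
    model: ModelSpec,
    subject: Subject,
    conditioning_obs: Sequence[Observation],
    error_variant: str | None = None,
) -> MapEstimate:
    """MAP estimate of the individual random effects.

    Minimized by a derivative-free / quasi-Newton hybrid (Nelder-Mead with
    BFGS polish) from eta=0 plus four jittered starts drawn with a fixed
    seed, so the estimate is deterministic given its inputs.  Non-converged
    runs return the best point found, flagged.
    """
    if model.n_eta == 0:
        return MapEstimate(np.zeros(0), 0.0, True, 0)
    if not conditioning_obs:
        raise ValueError("conditioning_obs must be nonempty")
    covariates = model_covariates(subject, model)
    err = model.error_variant(error_variant)
    omega = model.omega_matrix
    try:
        omega_inv = np.linalg.inv(omega)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(omega) / omega.shape[0]
        log.warning(
            "singular omega for model %s; ridge-repaired with %g", model.name, jitter
        )
        omega_inv = np.linalg.inv(omega + jitter * np.eye(omega.shape[0]))
    obs_t = np.array([o.time for o in conditioning_obs], dtype=float)
    obs_y = np.array([o.concentration for o in conditioning_obs], dtype=float)
    args = (model, covariates, subject, obs_t, obs_y, err, omega_inv)

    rng = np.random.default_rng(_JITTER_SEED)
    sd = np.sqrt(np.clip(np.diag(omega), 1e-12, None))
    starts = [np.zeros(model.n_eta)] + [
        rng.normal(0.0, sd) for _ in range(_N_JITTER_STARTS)
    ]
    best = None
    converged = False
    n_used = 0
    for x0 in starts:
        n_used += 1
        res = optimize.minimize(
            _map_objective,
            x0,
            args=args,
            method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-8, "maxiter": 2000},
        )
        res2 = optimize.minimize(
            _map_objective, res.x, args=args, method="BFGS", options={"gtol": 1e-8}
        )
        cand = res2 if res2.fun <= res.fun else res
        if best is None or cand.fun < best.fun:
            best = cand
        converged = converged or bool(res.success or res2.success)
    if not converged:
        log.warning(
            "MAP estimation did not converge for subject %s under model %s; "
            "returning best objective %g",
            subject.subject_id,
            model.name,
            best.fun,
        )
    return MapEstimate(
        eta_hat=np.asarray(best.x, dtype=float),
        objective_value=float(best.fun),
        converged=converged,
        n_restarts_used=n_used,
    )


def trough_observation(subject: Subject, occasion_index: int) -> Observation | None:
    """The trough of an occasion: its last measured concentration."""
    subject = _ensure_occasions(subject)
    obs = [o for o in subject.observations if o.occasion_index == occasion_index]
    return obs[-1] if obs else None


def predict_bayesian_occasion2(
    model: ModelSpec,
    subject: Subject,
    error_variant: str | None = None,
) -> PredictionRecord | None:
    """Forecast the occasion-2 trough from the occasion-1 trough alone.

    Conditions the MAP estimate on exactly the last measured concentration
    of the first occasion (the real-world single-TDM-sample scenario) and
    returns the individual prediction at the occasion-2 trough time.
    Subjects without both troughs are skipped with a logged reason.
    """
    subject = _ensure_occasions(subject)
    occ1 = trough_observation(subject, 1)
    occ2 = trough_observation(subject, 2)
    if occ1 is None or occ2 is None:
        log.info(
            "subject %s skipped for Bayesian forecasting: missing occasion-%d trough",
            subject.subject_id,
            1 if occ1 is None else 2,
        )
        return None
    est = map_estimate(model, subject, [occ1], error_variant=error_variant)
    covariates = model_covariates(subject, model)
    params = individual_parameters(model, covariates, est.eta_hat)
    pred = predict_concentration(params, subject.doses, [occ2.time]).concentrations[0]
    return PredictionRecord(
        subject_id=subject.subject_id,
        time=occ2.time,
        observed=occ2.concentration,
        predicted=float(pred),
        prediction_type="bayesian",
        occasion_index=2,
    )


def _ensure_occasions(subject: Subject) -> Subject:
    if any(o.occasion_index is None for o in subject.observations):
        return with_occasions(subject)
    return subject
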