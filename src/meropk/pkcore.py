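"""Closed-form concentration prediction for 1- and 2-compartment models.

All dosing is zero-order (infusion) input into the central compartment:
intermittent infusions are short finite events, continuous infusion is one
long event spanning the regimen horizon.  Profiles are exact macro-constant
mono-/bi-exponential solutions superposed over the dosing history, so the
engine is linear in dose amount by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .models import ModelSpec

__all__ = [
    "DoseEvent",
    "ConcentrationProfile",
    "predict_concentration",
    "simulate_observations",
]

log = logging.getLogger(__name__)

#: Relative eigenvalue gap below which the bi-exponential solution becomes
#: numerically degenerate and the inter-compartment rate is perturbed.
_DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order input: ``amount`` mg infused over ``duration`` h."""

    start_time: float
    amount: float
    duration: float = 0.5

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.duration <= 0:
            raise ValueError(f"infusion duration must be > 0, got {self.duration}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.duration


@dataclass
class ConcentrationProfile:
    """Central-compartment concentrations (mg/L) on a caller-supplied grid."""

    times: np.ndarray
    concentrations: np.ndarray
    compartment: str = "central"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < -1e-9):
            raise ValueError("negative concentration in profile")


def _disposition_terms(params: Mapping[str, float]) -> list[tuple[float, float]]:
    """Macro-constants of the unit-bolus solution.

    Returns ``[(lambda_i, coef_i)]`` such that a bolus dose D gives central
    concentration ``D * sum_i coef_i * exp(-lambda_i * t)``.
    """
    cl, v1 = float(params["CL"]), float(params["V1"])
    if cl <= 0 or v1 <= 0:
        raise ValueError("CL and V1 must be positive")
    k10 = cl / v1
    if "Q" not in params or "V2" not in params or params.get("Q", 0) == 0:
        return [(k10, 1.0 / v1)]
    q, v2 = float(params["Q"]), float(params["V2"])
    if q < 0 or v2 <= 0:
        raise ValueError("Q must be >= 0 and V2 > 0")
    k12, k21 = q / v1, q / v2
    s = k10 + k12 + k21
    disc_sq = s * s - 4.0 * k10 * k21
    if disc_sq < _DEGENERACY_RTOL * s * s:
        # alpha ~= beta: nudge the peripheral return rate to split them
        log.warning("degenerate disposition eigenvalues; perturbing k21")
        k21 *= 1.0 + 1e-6
        s = k10 + k12 + k21
        disc_sq = s * s - 4.0 * k10 * k21
    disc = np.sqrt(disc_sq)
    alpha, beta = (s + disc) / 2.0, (s - disc) / 2.0
    a = (alpha - k21) / (v1 * (alpha - beta))
    b = (k21 - beta) / (v1 * (alpha - beta))
    return [(alpha, a), (beta, b)]


def _single_infusion(
    terms: list[tuple[float, float]],
    rate: float,
    duration: float,
    t: np.ndarray,
) -> np.ndarray:
    """Central concentration for one zero-order input starting at t=0."""
    c = np.zeros_like(t, dtype=float)
    active = t > 0
    if not np.any(active):
        return c
    ta = t[active]
    t_on = np.minimum(ta, duration)  # time infused
    t_off = np.maximum(ta - duration, 0.0)  # time since infusion stop
    acc = np.zeros_like(ta)
    for lam, coef in terms:
        acc += (coef / lam) * (1.0 - np.exp(-lam * t_on)) * np.exp(-lam * t_off)
    c[active] = rate * acc
    return c


def predict_concentration(
    params: Mapping[str, float],
    doses: Sequence[DoseEvent],
    times: Sequence[float] | np.ndarray,
) -> ConcentrationProfile:
    """Noise-free central concentrations at ``times`` (h since first-dose origin).

    Superposes the exact analytic infusion solution across all dose events.
    An empty dosing history yields an all-zero profile.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("observation times must be >= 0")
    c = np.zeros_like(t)
    if doses:
        terms = _disposition_terms(params)
        for d in doses:
            c += _single_infusion(terms, d.rate, d.duration, t - d.start_time)
    return ConcentrationProfile(times=t, concentrations=np.maximum(c, 0.0))


def predict_concentration_matrix(
    param_arrays: Mapping[str, np.ndarray],
    doses: Sequence[DoseEvent],
    times: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Profiles for K parameter vectors at once: returns shape (K, n_times).

    Same analytic solution as :func:`predict_concentration`, broadcast over
    a batch of parameter sets (used by the simulation-based diagnostics,
    where thousands of replicate individuals share one dosing history).
    """
    t = np.asarray(times, dtype=float)[None, :]  # (1, T)
    cl = np.asarray(param_arrays["CL"], dtype=float)[:, None]  # (K, 1)
    v1 = np.asarray(param_arrays["V1"], dtype=float)[:, None]
    if np.any(cl <= 0) or np.any(v1 <= 0):
        raise ValueError("CL and V1 must be positive")
    two_cmt = "Q" in param_arrays and "V2" in param_arrays
    k10 = cl / v1
    if two_cmt:
        q = np.asarray(param_arrays["Q"], dtype=float)[:, None]
        v2 = np.asarray(param_arrays["V2"], dtype=float)[:, None]
        k12, k21 = q / v1, q / v2
        s = k10 + k12 + k21
        disc_sq = s * s - 4.0 * k10 * k21
        degen = disc_sq < _DEGENERACY_RTOL * s * s
        if np.any(degen):
            log.warning("degenerate eigenvalues in %d batch rows; perturbing k21",
                        int(degen.sum()))
            k21 = np.where(degen, k21 * (1.0 + 1e-6), k21)
            s = k10 + k12 + k21
            disc_sq = s * s - 4.0 * k10 * k21
        disc = np.sqrt(disc_sq)
        alpha, beta = (s + disc) / 2.0, (s - disc) / 2.0
        lams = [alpha, beta]
        coefs = [
            (alpha - k21) / (v1 * (alpha - beta)),
            (k21 - beta) / (v1 * (alpha - beta)),
        ]
    else:
        lams, coefs = [k10], [1.0 / v1]
    c = np.zeros((cl.shape[0], t.shape[1]))
    for d in doses:
        td = t - d.start_time
        active = td > 0
        t_on = np.clip(td, 0.0, d.duration)
        t_off = np.maximum(td - d.duration, 0.0)
        acc = np.zeros_like(c)
        for lam, coef in zip(lams, coefs):
            acc += (coef / lam) * (1.0 - np.exp(-lam * t_on)) * np.exp(-lam * t_off)
        c += d.rate * acc * active
    return np.maximum(c, 0.0)


def simulate_observations(
    model: ModelSpec,
    params: Mapping[str, float],
    doses: Sequence[DoseEvent],
    times: Sequence[float] | np.ndarray,
    error_variant: str | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw observed concentrations ``y = f*(1+eps_prop) + eps_add``.

    Errors are centered normals with the SDs of the requested residual-error
    variant; negative draws are truncated at zero (and counted in the log).
    Passing the same seed reproduces the draws bit-for-bit.
    """
    err = model.error_variant(error_variant)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    f = predict_concentration(params, doses, times).concentrations
    y = f.copy()
    if err.sd_proportional > 0:
        y = y * (1.0 + gen.normal(0.0, err.sd_proportional, size=f.shape))
    if err.sd_additive > 0:
        y = y + gen.normal(0.0, err.sd_additive, size=f.shape)
    n_neg = int(np.sum(y < 0))
    if n_neg:
        log.debug("truncated %d negative simulated concentrations at 0", n_neg)
    return np.maximum(y, 0.0)
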