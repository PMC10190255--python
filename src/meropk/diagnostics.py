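"""Simulation-based model diagnostics: NPDE, pcVPC and goodness-of-fit.

Normalized prediction distribution errors (NPDE) judge a model against the
full predictive distribution: each subject's observation vector is compared
with many replicate vectors simulated under the model (IIV plus residual
error), decorrelated with the empirical simulated mean and a Cholesky
square-root of the simulated covariance.  Under a correct model the NPDE
are standard normal; a t-test on the mean, a chi-square (Fisher-type)
variance test against 1 and a global Shapiro-Wilk test are reported.

Prediction-corrected visual predictive checks (pcVPC) rescale observations
and simulations within a time-after-dose bin by the bin-median population
prediction, removing covariate and dose heterogeneity before comparing
observed percentiles with simulated percentile bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Subject, model_covariates, with_occasions
from .forecast import PredictionRecord
from .models import ModelSpec, typical_parameters
from .pkcore import predict_concentration, predict_concentration_matrix

__all__ = [
    "NpdeResult",
    "PcvpcBin",
    "compute_npde",
    "compute_pcvpc",
    "gof_table",
]

log = logging.getLogger(__name__)

_RIDGE = 1e-8
_MIN_BIN_OCCUPANCY = 1


@dataclass
class NpdeResult:
    npde: np.ndarray
    mean_stat: float
    mean_test_p: float
    variance_stat: float
    variance_test_p: float
    shapiro_p: float
    n_simulations: int
    n_observations: int


@dataclass
class PcvpcBin:
    bin_interval: tuple[float, float]
    observed_percentiles: dict[int, float]  # {5, 50, 95} of pc-observations
    simulated_percentile_bands: dict[int, tuple[float, float]]  # 95% ribbons
    n_obs: int
    stratum: str = "all"


def _simulate_replicates(
    model: ModelSpec,
    subject: Subject,
    times: np.ndarray,
    n_simulations: int,
    rng: np.random.Generator,
    error_variant: str | None,
) -> np.ndarray:
    """K replicate observation vectors under the full model: (K, n_times)."""
    covs = model_covariates(subject, model)
    typ = typical_parameters(model, covs)
    omega = model.omega_matrix
    if model.n_eta:
        chol = np.linalg.cholesky(omega + _RIDGE * np.eye(omega.shape[0]))
        etas = rng.standard_normal((n_simulations, model.n_eta)) @ chol.T
    else:
        etas = np.zeros((n_simulations, 0))
    arrays = {}
    for name, value in typ.items():
        if name in model.omega_labels:
            j = model.omega_labels.index(name)
            arrays[name] = value * np.exp(etas[:, j])
        else:
            arrays[name] = np.full(n_simulations, value)
    f = predict_concentration_matrix(arrays, subject.doses, times)
    err = model.error_variant(error_variant)
    y = f.copy()
    if err.sd_proportional > 0:
        y = y * (1.0 + rng.normal(0.0, err.sd_proportional, size=f.shape))
    if err.sd_additive > 0:
        y = y + rng.normal(0.0, err.sd_additive, size=f.shape)
    return np.maximum(y, 0.0)


def compute_npde(
    model: ModelSpec,
    subjects: Sequence[Subject],
    n_simulations: int = 1000,
    seed: int | None = 0,
    error_variant: str | None = None,
) -> NpdeResult:
    """NPDE with mean, variance and normality tests.

    Per subject the observed vector is decorrelated together with its
    simulated replicates; pd (the fraction of decorrelated simulations
    below the decorrelated observation) is clamped to
    ``[1/(2K), 1 - 1/(2K)]`` so the normal quantile stays finite.
    """
    if n_simulations < 100:
        raise ValueError("n_simulations must be >= 100")
    if not subjects:
        raise ValueError("dataset must be nonempty")
    rng = np.random.default_rng(seed)
    k = n_simulations
    clamp_lo, clamp_hi = 1.0 / (2 * k), 1.0 - 1.0 / (2 * k)
    all_npde: list[np.ndarray] = []
    for subject in subjects:
        times = subject.observation_times()
        if times.size == 0:
            continue
        y_obs = np.array([o.concentration for o in subject.observations])
        sims = _simulate_replicates(model, subject, times, k, rng, error_variant)
        mean = sims.mean(axis=0)
        centered = sims - mean
        cov = centered.T @ centered / (k - 1)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            log.warning(
                "singular simulated covariance for subject %s; ridge-regularized",
                subject.subject_id,
            )
            chol = np.linalg.cholesky(cov + _RIDGE * np.trace(cov) * np.eye(len(mean)))
        y_star = np.linalg.solve(chol, y_obs - mean)
        sims_star = np.linalg.solve(chol, centered.T).T  # (K, n)
        pd_frac = (sims_star < y_star).mean(axis=0)
        pd_frac = np.clip(pd_frac, clamp_lo, clamp_hi)
        all_npde.append(stats.norm.ppf(pd_frac))
    npde = np.concatenate(all_npde)
    n = npde.size
    mean_stat = float(npde.mean())
    if n < 2:  # degenerate dataset: tests undefined
        mean_p = var_stat = var_p = float("nan")
    else:
        mean_p = float(stats.ttest_1samp(npde, 0.0).pvalue)
        var_stat = float(npde.var(ddof=1))
        # Fisher-type variance test: (n-1) s^2 ~ chi2(n-1) under N(0,1)
        chi = (n - 1) * var_stat
        var_p = min(
            2.0 * min(stats.chi2.cdf(chi, n - 1), stats.chi2.sf(chi, n - 1)), 1.0
        )
    shapiro_p = float(stats.shapiro(npde).pvalue) if 3 <= n <= 5000 else float("nan")
    return NpdeResult(
        npde=npde,
        mean_stat=mean_stat,
        mean_test_p=mean_p,
        variance_stat=var_stat,
        variance_test_p=float(var_p),
        shapiro_p=shapiro_p,
        n_simulations=k,
        n_observations=n,
    )


def _time_after_dose(subject: Subject, t: float) -> float:
    """Binning variable: time since the most recent dose start (continuous
    infusion: time since infusion start)."""
    starts = [d.start_time for d in subject.doses if d.start_time <= t]
    if not starts:
        return t
    if subject.dosing_strategy == "CI":
        return t - subject.doses[0].start_time
    return t - max(starts)


def compute_pcvpc(
    model: ModelSpec,
    subjects: Sequence[Subject],
    n_simulations: int = 500,
    bins: int | Sequence[float] = 8,
    stratify_by: str | None = "dosing_strategy",
    seed: int | None = 0,
    error_variant: str | None = None,
) -> list[PcvpcBin]:
    """Prediction-corrected VPC bins, one stratum at a time.

    ``bins`` may be a bin count (quantile-spaced on time-after-dose) or
    explicit strictly increasing edges.  Empty bins are dropped with a
    warning.  Percentile ribbons are the 2.5/97.5 percentiles across
    replicates of each bin's 5th/50th/95th percentile.
    """
    if n_simulations < 200:
        raise ValueError("n_simulations must be >= 200")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        strata = {"all": list(subjects)}
    else:
        strata = {}
        for s in subjects:
            strata.setdefault(str(getattr(s, stratify_by)), []).append(s)

    out: list[PcvpcBin] = []
    for label in sorted(strata):
        members = strata[label]
        binvar, obs, pred, sim_cols = [], [], [], []
        for subject in members:
            times = subject.observation_times()
            if times.size == 0:
                continue
            covs = model_covariates(subject, model)
            prof = predict_concentration(
                typical_parameters(model, covs), subject.doses, times
            )
            sims = _simulate_replicates(
                model, subject, times, n_simulations, rng, error_variant
            )
            for j, o in enumerate(subject.observations):
                binvar.append(_time_after_dose(subject, o.time))
                obs.append(o.concentration)
                pred.append(prof.concentrations[j])
                sim_cols.append(sims[:, j])
        if not obs:
            continue
        binvar = np.asarray(binvar)
        obs = np.asarray(obs)
        pred = np.asarray(pred)
        sims = np.column_stack(sim_cols)  # (K, N)

        if np.isscalar(bins):
            qs = np.linspace(0, 1, int(bins) + 1)
            edges = np.unique(np.quantile(binvar, qs))
            edges[-1] = edges[-1] + 1e-9
        else:
            edges = np.asarray(bins, dtype=float)
            if np.any(np.diff(edges) <= 0):
                raise ValueError("bin edges must be strictly increasing")
        for lo, hi in zip(edges[:-1], edges[1:]):
            idx = np.flatnonzero((binvar >= lo) & (binvar < hi))
            if idx.size < _MIN_BIN_OCCUPANCY:
                log.warning("dropping empty pcVPC bin [%g, %g) in stratum %s",
                            lo, hi, label)
                continue
            med_pred = np.median(pred[idx])
            if med_pred <= 0 or np.any(pred[idx] <= 0):
                log.warning("dropping pcVPC bin [%g, %g): non-positive PRED", lo, hi)
                continue
            factor = med_pred / pred[idx]
            pc_obs = obs[idx] * factor
            pc_sims = sims[:, idx] * factor[None, :]
            obs_pct = {p: float(np.percentile(pc_obs, p)) for p in (5, 50, 95)}
            bands = {}
            for p in (5, 50, 95):
                rep_pct = np.percentile(pc_sims, p, axis=1)  # per replicate
                bands[p] = tuple(np.percentile(rep_pct, [2.5, 97.5]).tolist())
            out.append(
                PcvpcBin(
                    bin_interval=(float(lo), float(hi)),
                    observed_percentiles=obs_pct,
                    simulated_percentile_bands=bands,
                    n_obs=int(idx.size),
                    stratum=label,
                )
            )
    return out


def gof_table(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Tidy (population prediction, observation) pairs for identity-line
    goodness-of-fit plotting."""
    if not records:
        raise ValueError("gof_table requires at least one record")
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "time": [r.time for r in records],
            "observed": [r.observed for r in records],
            "predicted": [r.predicted for r in records],
            "prediction_type": [r.prediction_type for r in records],
            "occasion_index": [r.occasion_index for r in records],
        }
    )
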