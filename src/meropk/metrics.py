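"""Accuracy/precision statistics and clinical-acceptance classification.

Per-sample prediction error uses the symmetric (scale-free) form

    PE = (c_pred - c_obs) / ((c_pred + c_obs) / 2)

bounded in (-2, 2) for positive concentrations.  Model accuracy is the
median PE (MPE, %), precision the median absolute PE (MAPE, %).  A model is
clinically acceptable when MPE lies within +/-20% with a 95% CI including
zero (accuracy) and MAPE <= 30% (precision).

The 95% CI of the MPE is a nonparametric percentile bootstrap resampling
*subjects* (not records), which respects within-subject correlation; the
median convention is linear interpolation between order statistics
(numpy's default), making results bit-for-bit reproducible at fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .forecast import PredictionRecord

__all__ = [
    "EvaluationResult",
    "prediction_error",
    "pe_values",
    "mpe",
    "mape",
    "mpe_confidence_interval",
    "classify_acceptance",
    "evaluate_records",
    "ACCURACY_LIMIT_PERCENT",
    "PRECISION_LIMIT_PERCENT",
]

log = logging.getLogger(__name__)

ACCURACY_LIMIT_PERCENT = 20.0
PRECISION_LIMIT_PERCENT = 30.0


@dataclass
class EvaluationResult:
    mpe_percent: float
    mape_percent: float
    mpe_ci95: tuple[float, float]
    n_records: int
    stratum: str = "total"
    prediction_type: str = ""
    model_name: str = ""
    acceptable_accuracy: bool | None = None
    acceptable_precision: bool | None = None
    n_excluded: int = 0


def prediction_error(c_pred: float, c_obs: float) -> float:
    """Symmetric prediction error for a single time point (fraction)."""
    denom = (c_pred + c_obs) / 2.0
    if denom <= 0:
        raise ValueError(
            f"prediction error undefined for c_pred={c_pred}, c_obs={c_obs}"
        )
    return (c_pred - c_obs) / denom


def pe_values(records: Sequence[PredictionRecord]) -> tuple[np.ndarray, int]:
    """Per-record PEs; records with non-positive pred+obs are excluded and
    counted (second return value)."""
    pes, excluded = [], 0
    for r in records:
        if r.observed <= 0 or (r.predicted + r.observed) <= 0:
            excluded += 1
            continue
        pes.append(prediction_error(r.predicted, r.observed))
    if excluded:
        log.info("excluded %d records with undefined prediction error", excluded)
    return np.asarray(pes, dtype=float), excluded


def mpe(records: Sequence[PredictionRecord]) -> float:
    """Median prediction error in percent (accuracy)."""
    pes, _ = pe_values(records)
    if pes.size == 0:
        raise ValueError("MPE requires at least one valid record")
    return float(np.median(pes) * 100.0)


def mape(records: Sequence[PredictionRecord]) -> float:
    """Median absolute prediction error in percent (precision)."""
    pes, _ = pe_values(records)
    if pes.size == 0:
        raise ValueError("MAPE requires at least one valid record")
    return float(np.median(np.abs(pes)) * 100.0)


def mpe_confidence_interval(
    records: Sequence[PredictionRecord],
    n_boot: int = 1000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """95% percentile-bootstrap CI of the MPE, resampling subjects."""
    by_subject: dict[str, list[float]] = {}
    for r in records:
        if r.observed <= 0 or (r.predicted + r.observed) <= 0:
            continue
        by_subject.setdefault(r.subject_id, []).append(
            prediction_error(r.predicted, r.observed)
        )
    ids = sorted(by_subject)
    if not ids:
        raise ValueError("CI requires at least one valid record")
    if len(ids) == 1:
        log.warning("single subject: degenerate bootstrap CI")
    pe_lists = [np.asarray(by_subject[i]) for i in ids]
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    n = len(ids)
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        pooled = np.concatenate([pe_lists[k] for k in take])
        stats[b] = np.median(pooled) * 100.0
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def classify_acceptance(result: EvaluationResult) -> EvaluationResult:
    """Clinical-acceptance verdicts: accuracy iff MPE within +/-20% with the
    95% CI spanning zero; precision iff MAPE <= 30%."""
    lo, hi = result.mpe_ci95
    result.acceptable_accuracy = (
        -ACCURACY_LIMIT_PERCENT <= result.mpe_percent <= ACCURACY_LIMIT_PERCENT
        and lo <= 0.0 <= hi
    )
    result.acceptable_precision = result.mape_percent <= PRECISION_LIMIT_PERCENT
    return result


def evaluate_records(
    records: Sequence[PredictionRecord],
    stratum: str = "total",
    prediction_type: str = "",
    model_name: str = "",
    n_boot: int = 1000,
    seed: int | None = 0,
) -> EvaluationResult:
    """MPE, MAPE, bootstrap CI and acceptance verdicts for one stratum."""
    pes, excluded = pe_values(records)
    if pes.size == 0:
        raise ValueError("evaluation requires at least one valid record")
    result = EvaluationResult(
        mpe_percent=float(np.median(pes) * 100.0),
        mape_percent=float(np.median(np.abs(pes)) * 100.0),
        mpe_ci95=mpe_confidence_interval(records, n_boot=n_boot, seed=seed),
        n_records=int(pes.size),
        stratum=stratum,
        prediction_type=prediction_type,
        model_name=model_name,
        n_excluded=excluded,
    )
    return classify_acceptance(result)
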