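"""End-to-end evaluation: models x arms x strata, diagnostics, manifest.

Three evaluation arms mirror the clinical workflow: ``a_priori_all``
(population predictions for every measured concentration),
``a_priori_occ2_trough`` (population prediction of the occasion-2 trough
only) and ``bayesian_occ2_trough`` (MAP forecast of the occasion-2 trough
conditioned on the occasion-1 trough).  Results can be stratified by
center and by infusion mode in addition to the total dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cohort import Subject, apply_inclusion_filter
from .diagnostics import NpdeResult, compute_npde, compute_pcvpc, gof_table
from .forecast import (
    PredictionRecord,
    predict_a_priori,
    predict_bayesian_occasion2,
)
from .metrics import EvaluationResult, evaluate_records
from .models import ModelSpec, load_bundled_model, load_model_spec

__all__ = ["RunConfig", "ReportBundle", "run_evaluation", "summarize_across_models"]

log = logging.getLogger(__name__)

ARMS = ("a_priori_all", "a_priori_occ2_trough", "bayesian_occ2_trough")
STRATA = ("total", "center", "infusion_mode")


class RunConfig(BaseModel):
    """Configuration of one evaluation run."""

    models: list[str]  # bundled names or spec file paths
    error_variants: dict[str, list[str]] = Field(default_factory=dict)
    arms: list[str] = Field(default_factory=lambda: list(ARMS))
    strata: list[str] = Field(default_factory=lambda: ["total"])
    n_boot: int = 1000
    seed: int = 0
    npde_simulations: int = 1000
    pcvpc_simulations: int = 500
    run_diagnostics: bool = False
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not self.models:
            raise ValueError("at least one model is required")
        if not self.arms:
            raise ValueError("at least one evaluation arm is required")
        bad = set(self.arms) - set(ARMS)
        if bad:
            raise ValueError(f"unknown arms {sorted(bad)}; choose from {ARMS}")
        bad = set(self.strata) - set(STRATA)
        if bad:
            raise ValueError(f"unknown strata {sorted(bad)}; choose from {STRATA}")
        return self


@dataclass
class ReportBundle:
    results: pd.DataFrame  # one row per model-arm x stratum value
    records: pd.DataFrame  # per-record predictions (CSV-exportable)
    npde: dict[str, NpdeResult] = field(default_factory=dict)
    pcvpc: dict[str, list] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    n_excluded_subjects: int = 0


def _load_model(name: str) -> ModelSpec:
    if Path(name).suffix in {".json", ".yaml", ".yml"} and Path(name).exists():
        return load_model_spec(name)
    return load_bundled_model(name)


def _model_arms(config: RunConfig, model: ModelSpec) -> list[tuple[str, str | None]]:
    """(arm label suffix, error variant) pairs; models with several
    published residual-error variants are evaluated as separate arms."""
    variants = config.error_variants.get(model.name)
    if variants is None:
        return [("", None)]
    return [(f":{v}", v) for v in variants]


def _arm_records(
    model: ModelSpec,
    subjects: Sequence[Subject],
    arm: str,
    error_variant: str | None,
) -> list[PredictionRecord]:
    records: list[PredictionRecord] = []
    for s in subjects:
        if arm == "a_priori_all":
            records.extend(predict_a_priori(model, s))
        elif arm == "a_priori_occ2_trough":
            occ2 = [r for r in predict_a_priori(model, s) if r.occasion_index == 2]
            if occ2:
                records.append(occ2[-1])
        elif arm == "bayesian_occ2_trough":
            rec = predict_bayesian_occasion2(model, s, error_variant=error_variant)
            if rec is not None:
                records.append(rec)
        else:  # pragma: no cover - guarded by RunConfig
            raise ValueError(f"unknown arm {arm!r}")
    return records


def _strata_of(
    stratum_scheme: str, subjects: Sequence[Subject]
) -> dict[str, set[str]]:
    """Map stratum label -> subject ids it contains."""
    if stratum_scheme == "total":
        return {"total": {s.subject_id for s in subjects}}
    if stratum_scheme == "center":
        out: dict[str, set[str]] = {}
        for s in subjects:
            out.setdefault(f"center:{s.center}", set()).add(s.subject_id)
        return out
    if stratum_scheme == "infusion_mode":
        out = {}
        for s in subjects:
            out.setdefault(f"infusion:{s.dosing_strategy}", set()).add(s.subject_id)
        return out
    raise ValueError(f"unknown stratum scheme {stratum_scheme!r}")


def run_evaluation(config: RunConfig, subjects: Sequence[Subject]) -> ReportBundle:
    """Evaluate every configured model over every arm and stratum.

    A failing model is isolated (logged, run continues).  The returned
    manifest pins the package version, configuration and seeds, and fully
    determines the outputs.
    """
    included, excluded = apply_inclusion_filter(subjects)
    rows = []
    record_rows = []
    npde_results: dict[str, NpdeResult] = {}
    pcvpc_results: dict[str, list] = {}
    for model_name in config.models:
        try:
            model = _load_model(model_name)
            for suffix, variant in _model_arms(config, model):
                label = f"{model.name}{suffix}"
                for arm in config.arms:
                    records = _arm_records(model, included, arm, variant)
                    if not records:
                        log.warning("arm %s produced no records for %s", arm, label)
                        continue
                    for r in records:
                        record_rows.append(
                            dict(
                                model=label,
                                arm=arm,
                                subject_id=r.subject_id,
                                time=r.time,
                                occasion=r.occasion_index,
                                observed=r.observed,
                                predicted=r.predicted,
                                type=r.prediction_type,
                            )
                        )
                    for scheme in config.strata:
                        for stratum, ids in sorted(_strata_of(scheme, included).items()):
                            sub = [r for r in records if r.subject_id in ids]
                            if not sub:
                                continue
                            res = evaluate_records(
                                sub,
                                stratum=stratum,
                                prediction_type=arm,
                                model_name=label,
                                n_boot=config.n_boot,
                                seed=config.seed,
                            )
                            rows.append(_result_row(res))
                if config.run_diagnostics:
                    npde_results[label] = compute_npde(
                        model,
                        included,
                        n_simulations=config.npde_simulations,
                        seed=config.seed,
                        error_variant=None,
                    )
                    pcvpc_results[label] = compute_pcvpc(
                        model,
                        included,
                        n_simulations=config.pcvpc_simulations,
                        seed=config.seed,
                    )
        except Exception:
            log.exception("model %s failed; continuing with remaining models",
                          model_name)
    results = pd.DataFrame(rows)
    records_df = pd.DataFrame(record_rows)
    manifest = {
        "package_version": __version__,
        "config": config.model_dump(),
        "n_subjects_included": len(included),
        "n_subjects_excluded": len(excluded),
        "exclusion_reasons": [(s.subject_id, r) for s, r in excluded],
    }
    bundle = ReportBundle(
        results=results,
        records=records_df,
        npde=npde_results,
        pcvpc=pcvpc_results,
        manifest=manifest,
        n_excluded_subjects=len(excluded),
    )
    if config.output_dir:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _result_row(res: EvaluationResult) -> dict:
    return dict(
        model=res.model_name,
        arm=res.prediction_type,
        stratum=res.stratum,
        n=res.n_records,
        mpe_percent=res.mpe_percent,
        mpe_ci_low=res.mpe_ci95[0],
        mpe_ci_high=res.mpe_ci95[1],
        mape_percent=res.mape_percent,
        acceptable_accuracy=res.acceptable_accuracy,
        acceptable_precision=res.acceptable_precision,
    )


def _write_bundle(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.results.to_csv(outdir / "results.csv", index=False)
    bundle.records.to_csv(outdir / "records.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
    for label, npde in bundle.npde.items():
        pd.DataFrame({"npde": npde.npde}).to_csv(
            outdir / f"npde_{label}.csv", index=False
        )
    for label, bins in bundle.pcvpc.items():
        pd.DataFrame(
            [
                dict(
                    stratum=b.stratum,
                    bin_lo=b.bin_interval[0],
                    bin_hi=b.bin_interval[1],
                    n_obs=b.n_obs,
                    obs_p5=b.observed_percentiles[5],
                    obs_p50=b.observed_percentiles[50],
                    obs_p95=b.observed_percentiles[95],
                    sim_p5_lo=b.simulated_percentile_bands[5][0],
                    sim_p5_hi=b.simulated_percentile_bands[5][1],
                    sim_p50_lo=b.simulated_percentile_bands[50][0],
                    sim_p50_hi=b.simulated_percentile_bands[50][1],
                    sim_p95_lo=b.simulated_percentile_bands[95][0],
                    sim_p95_hi=b.simulated_percentile_bands[95][1],
                )
                for b in bins
            ]
        ).to_csv(outdir / f"pcvpc_{label}.csv", index=False)


def summarize_across_models(results: pd.DataFrame) -> pd.DataFrame:
    """Median MPE and MAPE across models, per arm (total stratum).

    Enables the a-priori versus Bayesian comparison of the occasion-2
    trough forecasts at cohort level.
    """
    total = results[results["stratum"] == "total"]
    if total.empty:
        raise ValueError("no total-stratum rows to summarize")
    return (
        total.groupby("arm")
        .agg(
            n_models=("model", "nunique"),
            median_mpe_percent=("mpe_percent", "median"),
            median_mape_percent=("mape_percent", "median"),
        )
        .reset_index()
    )
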