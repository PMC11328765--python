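"""Reproducible phantom -> quantification -> cohort-statistics pipeline.

Composes the measurement chain and the survival statistics into one seeded
run that emits machine-readable artifacts: a per-case metrics CSV, a
statistics report (Cox fits, risk-tier Kaplan-Meier tables, threshold
log-rank tests, time-dependent AUC), a content-hash manifest, and a log. The
pipeline adds no computation of its own — every number in the report is
produced by the phantom, centerline, morphometry, or survival modules.

Per-case failures are isolated: a case that cannot be quantified is recorded
with its error and the run continues; only a run with zero successful cases
fails outright.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import morphometry, survival
from .io import LabelVolume, PatientRecord, read_cohort_table, read_label_volume, write_label_volume
from .morphometry import DEFAULT_THRESHOLDS
from .phantom import make_phantom, make_synthetic_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("confluencemorph")


class PipelineError(RuntimeError):
    """No case could be quantified."""


@dataclasses.dataclass
class RunConfig:
    """Inputs and options for one pipeline run."""

    out_dir: Path
    # either a synthetic cohort ...
    n_phantoms: int = 0
    effect_itvlc: float = -0.15
    effect_ratio: float = -0.10
    censor_rate: float = 0.3
    # ... or explicit inputs
    volume_paths: Sequence[Path] = ()
    cohort_csv: Path | None = None

    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    horizon_months: float = 12.0
    adjust: Sequence[str] = ()
    n_bootstrap: int = 200
    seed: int = 0
    strict: bool = False
    keep_volumes: bool = False     # write phantom volumes into the run directory

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.thresholds[0] <= 0 or self.thresholds[1] <= 0:
            raise ValueError(f"thresholds must be > 0, got {self.thresholds}")
        if self.n_phantoms == 0 and not self.volume_paths:
            raise ValueError("configure either n_phantoms or volume_paths")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _resolve_cases(
    config: RunConfig,
) -> list[tuple[str, LabelVolume | Path, PatientRecord]]:
    if config.n_phantoms:
        cohort = make_synthetic_cohort(
            config.n_phantoms,
            effect_itvlc=config.effect_itvlc,
            effect_ratio=config.effect_ratio,
            censor_rate=config.censor_rate,
            seed=config.seed,
        )
        cases = []
        for cfg, rec in cohort:
            vol, _ = make_phantom(cfg)
            cases.append((rec.id, vol, rec))
        return cases
    records = {r.id: r for r in read_cohort_table(config.cohort_csv)}
    cases = []
    for path in config.volume_paths:
        case_id = Path(path).name.split(".")[0]
        if case_id not in records:
            raise PipelineError(f"volume {path} has no cohort row with id {case_id!r}")
        cases.append((case_id, Path(path), records[case_id]))
    return cases


def _cohort_stats(
    df: pd.DataFrame, config: RunConfig
) -> dict[str, Any]:
    """Survival analyses over the measured metrics of the successful cases."""
    sample = survival.SurvivalSample(
        time=df["time_months"].to_numpy(),
        event=df["event"].to_numpy(dtype=bool),
        covariates=df[
            ["itvlc_cm3_m2", "ratio"] + [c for c in config.adjust if c in df.columns]
        ].rename(columns={"itvlc_cm3_m2": "itvlc"}),
    )
    report: dict[str, Any] = {"n": sample.n, "n_events": sample.n_events}
    try:
        fit = survival.cox_fit(sample)
        report["cox"] = {
            "covariates": fit.names,
            "coef": fit.beta,
            "hr": fit.hr,
            "ci_lower": fit.ci_lower,
            "ci_upper": fit.ci_upper,
            "p": fit.p_values,
        }
        report["schoenfeld"] = survival.schoenfeld_check(fit, sample).reset_index().to_dict(
            orient="records"
        )
    except (ValueError, survival.ConvergenceError) as exc:
        report["cox_error"] = str(exc)

    # risk-tier KM tables and freedom-from-event at the horizon
    tiers = {}
    for tier in ("low", "medium", "high"):
        idx = np.flatnonzero((df["risk_class"] == tier).to_numpy())
        if idx.size == 0:
            continue
        sub = sample.subset(idx)
        entry: dict[str, Any] = {"n": sub.n, "n_events": sub.n_events}
        if sub.n >= 1:
            km = survival.km_estimate(sub)
            entry["km_times"] = km.times
            entry["km_survival"] = km.survival
            entry["freedom_at_horizon"] = float(km(config.horizon_months))
        tiers[tier] = entry
    report["risk_tiers"] = tiers

    # threshold dichotomizations (log-rank)
    for marker, cut, col in (
        ("itvlc", config.thresholds[0], "itvlc_cm3_m2"),
        ("ratio", config.thresholds[1], "ratio"),
    ):
        above = np.flatnonzero((df[col] >= cut).to_numpy())
        below = np.flatnonzero((df[col] < cut).to_numpy())
        if above.size and below.size:
            try:
                stat, p = survival.logrank_test(
                    sample.subset(above), sample.subset(below)
                )
                report[f"logrank_{marker}"] = {"cut": cut, "stat": stat, "p": p}
            except ValueError as exc:
                report[f"logrank_{marker}"] = {"cut": cut, "error": str(exc)}

    # time-dependent AUC at the horizon
    for marker, col, sign in (("itvlc", "itvlc_cm3_m2", -1.0), ("ratio", "ratio", -1.0)):
        try:
            # markers are protective; negate so higher score = higher risk
            res = survival.td_roc(
                sample,
                sign * df[col].to_numpy(),
                horizon=config.horizon_months,
                n_bootstrap=config.n_bootstrap,
                seed=config.seed,
            )
            report[f"td_auc_{marker}"] = res
        except ValueError as exc:
            report[f"td_auc_{marker}"] = {"error": str(exc)}
    return report


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the run; returns the manifest (also written to the run dir)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        cases = _resolve_cases(config)
        log.info("run started: %d case(s), seed %d", len(cases), config.seed)
        rows = []
        statuses = []
        for case_id, vol_or_path, rec in cases:
            try:
                if isinstance(vol_or_path, Path):
                    vol = read_label_volume(vol_or_path)
                else:
                    vol = vol_or_path
                    if config.keep_volumes:
                        write_label_volume(vol, out / "volumes" / f"{case_id}.nii.gz")
                metrics, _ = morphometry.quantify(
                    vol, bsa_m2=rec.bsa_m2, thresholds=config.thresholds
                )
                row = {"id": case_id, **metrics.as_dict()}
                row.update(
                    {
                        "age_days": rec.age_days,
                        "prepvo": float(rec.prepvo),
                        "time_months": rec.time_months,
                        "event": bool(rec.event),
                    }
                )
                rows.append(row)
                statuses.append({"id": case_id, "status": "ok"})
            except Exception as exc:   # isolate the failing case
                log.warning("case %s failed: %s", case_id, exc)
                statuses.append({"id": case_id, "status": "failed", "error": str(exc)})
        if not rows:
            raise PipelineError("no case could be quantified")
        df = pd.DataFrame(rows)
        metrics_csv = out / "metrics.csv"
        df.to_csv(metrics_csv, index=False)

        report = _cohort_stats(df, config)
        report["seed"] = config.seed
        report["thresholds"] = list(config.thresholds)
        report_path = out / "report.json"
        report_path.write_text(json.dumps(_jsonable(report), indent=2))

        manifest = {
            "seed": config.seed,
            "n_cases": len(cases),
            "n_ok": len(rows),
            "n_failed": len(cases) - len(rows),
            "cases": statuses,
            "artifacts": {
                str(p.relative_to(out)): _sha256(p)
                for p in sorted(out.rglob("*"))
                if p.is_file() and p.name not in ("manifest.json", "run.log")
            },
        }
        (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
        log.info("run finished: %d ok, %d failed", manifest["n_ok"], manifest["n_failed"])
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
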