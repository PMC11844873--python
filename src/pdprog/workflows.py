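"""End-to-end orchestration of the severity-prediction study and its named
workflow variants.

The default workflow computes z-scored ReHo maps, extracts regional means
over every configured parcellation, assembles imaging + clinical +
demographic features (adding the baseline total score for follow-up targets),
and evaluates all model families per parcellation under the per-combination
nested CV scheme.  Variants toggle exactly one stage: C1 disables z-scoring,
C2 swaps fALFF for ALFF, D1 drops the dominant-side feature, D2 the baseline
score, D3 all imaging features, D4 everything but imaging; E1 uses the joint
nested CV (model x hyperparameters x parcellation optimised in the inner
loop) and E2 reports a single fixed model x parcellation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import confounds as conf
from .cohort import (
    SeverityThreshold,
    VisitMatchConfig,
    add_total_scores,
    assemble_features,
    encode_features,
    match_followups,
    severity_threshold,
    TOTAL_COLUMN,
)
from .evaluation import (
    CVScheme,
    EvaluationResult,
    ModelSpec,
    PermutationNull,
    feature_importance,
    nested_cv_joint,
    nested_cv_per_combo,
    permutation_null,
)
from .confounds import framewise_displacement
from .synthetic import SyntheticStudy, regional_feature_table

__all__ = ["WorkflowConfig", "RunReport", "run_workflow", "compare_workflows"]

ALL_FAMILIES = ("elasticnet", "linear_svm", "random_forest", "gradient_boosting")

# variant -> enforced toggles
VARIANT_TOGGLES: dict[str, dict[str, object]] = {
    "default": {},
    "A1": {},  # alternative cohort: supply a different study/cohort as input
    "C1": {"zscore": False},
    "C2": {"feature_type": "alff"},
    "D1": {"feature_set": "no_side"},
    "D2": {"feature_set": "no_baseline_score"},
    "D3": {"feature_set": "clinical_only"},
    "D4": {"feature_set": "imaging_only"},
    "E1": {"scheme_mode": "joint_paper_E1"},
    "E2": {"scheme_mode": "fixed_model_E2"},
}


@dataclass
class WorkflowConfig:
    """Resolved toggles for one workflow run."""

    variant: str = "default"
    feature_type: str = "reho"
    zscore: bool = True
    feature_set: str = "all"
    scheme_mode: str = "per_combo_default"
    timepoints: tuple[str, ...] = ("baseline",)
    model_families: tuple[str, ...] = ALL_FAMILIES
    parcellations: tuple[str, ...] | None = None
    fixed_family: str = "elasticnet"
    fixed_parcellation: str | None = None
    inner_k: int = 10
    outer: str | int = "leave_one_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_TOGGLES:
            raise ValueError(f"unknown variant {self.variant!r}")
        defaults = {
            "feature_type": "reho",
            "zscore": True,
            "feature_set": "all",
            "scheme_mode": "per_combo_default",
        }
        for name, value in VARIANT_TOGGLES[self.variant].items():
            current = getattr(self, name)
            if current != defaults[name] and current != value:
                raise ValueError(
                    f"variant {self.variant!r} implies {name}={value!r} but "
                    f"{name}={current!r} was given"
                )
            setattr(self, name, value)
        if self.feature_type not in ("reho", "falff", "alff"):
            raise ValueError(f"unknown feature_type {self.feature_type!r}")

    def scheme(self) -> CVScheme:
        return CVScheme(
            mode=self.scheme_mode, outer=self.outer, inner_k=self.inner_k, seed=self.seed
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("timepoints", "model_families", "parcellations"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class RunReport:
    """Metrics, importances, QC and provenance for one workflow run."""

    variant: str
    metrics: pd.DataFrame
    best: dict[str, dict]
    importance: dict[str, pd.DataFrame]
    threshold: SeverityThreshold
    qc: dict
    config: WorkflowConfig
    results: dict = field(default_factory=dict, repr=False)
    null: dict[str, PermutationNull] = field(default_factory=dict)

    def best_r2(self, timepoint: str) -> float:
        return float(self.best[timepoint]["r2"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variant": self.variant,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "severity_threshold": {
                "value": self.threshold.value,
                "medians": self.threshold.medians,
            },
            "metrics": self.metrics.to_dict(orient="records"),
            "best": self.best,
            "qc": {
                "mean_fd_mm": self.qc.get("mean_fd_across_participants_mm"),
                "n_flagged": self.qc.get("n_flagged"),
            },
            "null": {
                tp: {"mean_r2": null.mean, "p95_r2": null.percentile_95}
                for tp, null in self.null.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def _targets_for_timepoint(
    cohort: pd.DataFrame, timepoint: str
) -> tuple[pd.Series, pd.DataFrame]:
    """Total-score targets and the matching baseline rows for one time point."""
    scored = add_total_scores(cohort)
    baseline = scored[scored["EVENT_ID"] == "BL"]
    if timepoint == "baseline":
        rows = baseline
    else:
        matched = match_followups(scored, VisitMatchConfig())
        if timepoint not in matched:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        rows = matched[timepoint]
    targets = rows.set_index("PATNO")[TOTAL_COLUMN].astype(float)
    base_rows = baseline[baseline["PATNO"].isin(targets.index)]
    return targets, base_rows


def _study_threshold(cohort: pd.DataFrame) -> SeverityThreshold:
    scored = add_total_scores(cohort)
    baseline = scored[scored["EVENT_ID"] == "BL"]
    matched = match_followups(scored, VisitMatchConfig())
    totals = {"baseline": baseline[TOTAL_COLUMN].to_numpy(dtype=float)}
    for name, rows in matched.items():
        if len(rows):
            totals[name] = rows[TOTAL_COLUMN].to_numpy(dtype=float)
    return severity_threshold(totals)


def _qc_block(study: SyntheticStudy) -> dict:
    fds = {pid: framewise_displacement(m) for pid, m in study.motion.items()}
    return conf.qc_report(fds)


def run_workflow(
    config: WorkflowConfig,
    study: SyntheticStudy,
    compute_null: bool = False,
    n_permutations: int = 100,
) -> RunReport:
    """Execute one workflow variant end-to-end on a (synthetic) study.

    Feature computation is skipped only when the study's precomputed default
    maps already match the configured toggles; otherwise maps are recomputed
    from the per-participant volumes.  Fully deterministic given the study
    and ``config.seed``.
    """
    if (config.feature_type, config.zscore) == (study.feature_type, study.zscore):
        imaging_tables = study.imaging
    else:
        imaging_tables = regional_feature_table(study, config.feature_type, config.zscore)
    parc_names = config.parcellations or tuple(imaging_tables)
    missing = [p for p in parc_names if p not in imaging_tables]
    if missing:
        raise ValueError(f"parcellation(s) not in study: {missing}")

    threshold = _study_threshold(study.cohort)
    scheme = config.scheme()

    metrics_rows: list[dict] = []
    best: dict[str, dict] = {}
    importance: dict[str, pd.DataFrame] = {}
    results: dict = {}
    null: dict[str, PermutationNull] = {}
    for timepoint in config.timepoints:
        targets, base_rows = _targets_for_timepoint(study.cohort, timepoint)
        include_baseline = timepoint != "baseline"
        encoded = (
            None
            if config.feature_set == "imaging_only"
            else encode_features(
                base_rows, config.feature_set, include_baseline_score=include_baseline
            )
        )
        kept = encoded.df.index if encoded is not None else targets.index
        features_by_parc = {
            name: assemble_features(
                encoded,
                imaging_tables[name].loc[kept.intersection(targets.index)],
                config.feature_set,
            )
            for name in parc_names
        }
        tp_results: dict[tuple[str, str], EvaluationResult] = {}
        if scheme.mode == "joint_paper_E1":
            models = [ModelSpec(f) for f in config.model_families]
            res = nested_cv_joint(features_by_parc, targets, models, scheme)
            tp_results[("joint", "joint")] = res
        elif scheme.mode == "fixed_model_E2":
            parc = config.fixed_parcellation or parc_names[0]
            res = nested_cv_per_combo(
                features_by_parc[parc], targets, ModelSpec(config.fixed_family), scheme
            )
            tp_results[(config.fixed_family, parc)] = res
        else:
            for parc in parc_names:
                for family in config.model_families:
                    res = nested_cv_per_combo(
                        features_by_parc[parc], targets, ModelSpec(family), scheme
                    )
                    tp_results[(family, parc)] = res

        for (family, parc), res in tp_results.items():
            row = {
                "timepoint": timepoint,
                "family": family,
                "parcellation": parc,
                "r2": res.r2,
                "rmse": res.rmse,
                "n": len(res.y_true),
            }
            try:
                row.update(res.classification(threshold))
            except ValueError:
                row.update({k: float("nan") for k in ("auc", "ppv", "npv", "sensitivity", "specificity")})
            metrics_rows.append(row)
            results[(timepoint, family, parc)] = res

        best_key = max(tp_results, key=lambda k: tp_results[k].r2)
        best_res = tp_results[best_key]
        best[timepoint] = next(
            r for r in metrics_rows
            if r["timepoint"] == timepoint
            and (r["family"], r["parcellation"]) == best_key
        )
        fm_arg = (
            features_by_parc
            if best_key == ("joint", "joint")
            else features_by_parc[best_key[1]]
        )
        importance[timepoint] = feature_importance(best_res, fm_arg)

        if compute_null:
            null_parc = parc_names[0]
            null[timepoint] = permutation_null(
                features_by_parc[null_parc],
                targets,
                n_permutations=n_permutations,
                seed=config.seed,
            )

    return RunReport(
        variant=config.variant,
        metrics=pd.DataFrame(metrics_rows),
        best=best,
        importance=importance,
        threshold=threshold,
        qc=_qc_block(study),
        config=config,
        results=results,
        null=null,
    )


def compare_workflows(
    reports: list[RunReport], reference: RunReport, margin: float = 0.15
) -> pd.DataFrame:
    """Per time point, difference of each report's best R2 against a
    reference run; |delta| > margin is flagged, as is a best R2 that does not
    beat the reference's permutation chance level."""
    rows = []
    for report in reports:
        shared = set(report.best) & set(reference.best)
        if set(report.best) != set(reference.best):
            raise ValueError("reports cover different time points")
        for timepoint in sorted(shared):
            delta = report.best_r2(timepoint) - reference.best_r2(timepoint)
            row = {
                "variant": report.variant,
                "timepoint": timepoint,
                "best_r2": report.best_r2(timepoint),
                "reference_r2": reference.best_r2(timepoint),
                "delta_r2": delta,
                "flagged": abs(delta) > margin,
            }
            ref_null = reference.null.get(timepoint)
            if ref_null is not None:
                row["null_p95"] = ref_null.percentile_95
                row["better_than_chance"] = (
                    report.best_r2(timepoint) > max(ref_null.percentile_95, 0.0)
                )
            rows.append(row)
    return pd.DataFrame(rows)
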