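"""Cohort logic: outcome totals, follow-up visit matching, clinical and
demographic feature encoding, and the severity threshold.

The prediction target is the MDS-UPDRS total score, the sum of parts Ia
(rater, ``NP1RTOT``), Ib (patient questionnaire, ``NP1PTOT``), II
(``NP2TOT``), III (motor exam, ``NP3TOT``) and IV (``NP4TOT``); a missing
part-IV entry counts as 0.  Follow-up visits are matched to Year 1/2/4 within
a +/- 60 day window around 365/730/1460 days after the baseline visit.  The
high/low severity threshold is the mean of the median total score at the four
time points.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VisitMatchConfig",
    "FeatureMatrix",
    "SeverityThreshold",
    "total_updrs",
    "add_total_scores",
    "filter_on_medication",
    "match_followups",
    "encode_features",
    "assemble_features",
    "severity_threshold",
]

logger = logging.getLogger(__name__)

MANDATORY_PARTS = ["NP1RTOT", "NP1PTOT", "NP2TOT", "NP3TOT"]
PART_COLUMNS = MANDATORY_PARTS + ["NP4TOT"]
BASELINE_VISIT = "BL"
TOTAL_COLUMN = "UPDRS_TOT"

# Shipped categorical code maps (documented stand-ins, overridable).
DEFAULT_CODE_MAP: dict[str, dict[str, int]] = {
    "SEX": {"female": 0, "male": 1},
    "HANDED": {"left": 0, "right": 1, "ambidextrous": 0},  # right-handed indicator
    "DOMSIDE": {"left": 0, "right": 1},
    "RACE": {"white": 0, "black": 1, "asian": 2, "other": 3},
    "ETHNICITY": {"not_hispanic": 0, "hispanic": 1},
}

CONTINUOUS_CLINICAL = ["DISEASE_DURATION", "SYMPTOM_DURATION", "GDS", "MOCA"]
CONTINUOUS_DEMOGRAPHIC = ["AGE", "EDUCYRS"]
BINARY_CLINICAL = ["DOMSIDE", "TREMOR", "RIGIDITY", "POSTURAL_INSTABILITY"]
BINARY_DEMOGRAPHIC = ["SEX", "HANDED"]
CODED_DEMOGRAPHIC = ["RACE", "ETHNICITY"]
BASELINE_SCORE_COLUMN = "BASELINE_UPDRS"

FEATURE_SETS = ("all", "no_side", "no_baseline_score", "imaging_only", "clinical_only")


def total_updrs(row) -> int:
    """MDS-UPDRS total for one visit row; missing NP4TOT counts as 0."""
    missing = [p for p in MANDATORY_PARTS if p not in row or pd.isna(row[p])]
    if missing:
        ident = row.get("PATNO", "<unknown>") if hasattr(row, "get") else "<unknown>"
        raise ValueError(f"row for participant {ident}: missing mandatory part(s) {missing}")
    total = sum(int(row[p]) for p in MANDATORY_PARTS)
    np4 = row["NP4TOT"] if "NP4TOT" in row else None
    if np4 is not None and not pd.isna(np4):
        total += int(np4)
    return total


def add_total_scores(cohort: pd.DataFrame, column: str = TOTAL_COLUMN) -> pd.DataFrame:
    """Return a copy of the cohort table with the total-score column added."""
    out = cohort.copy()
    out[column] = [total_updrs(row) for _, row in cohort.iterrows()]
    return out


def filter_on_medication(
    cohort: pd.DataFrame, column: str = "PAG_NAME", off_value: str = "NUPDRS3"
) -> pd.DataFrame:
    """Keep only visits whose motor exam was conducted ON medication.

    Mirrors the database convention where the page name ``NUPDRS3`` marks an
    OFF-medication part-III exam; such rows are dropped.
    """
    if column not in cohort.columns:
        return cohort
    return cohort[cohort[column] != off_value].copy()


@dataclass
class VisitMatchConfig:
    """Follow-up matching windows: target day offsets and tolerance."""

    targets: dict[str, int] = field(
        default_factory=lambda: {"year1": 365, "year2": 730, "year4": 1460}
    )
    tolerance: int = 60
    tie_break: str = "closest_to_target"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.tie_break not in ("closest_to_target", "earliest"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")


def match_followups(
    cohort: pd.DataFrame, config: VisitMatchConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Match each participant's follow-up visits to the configured time points.

    A visit matches time point Y iff |date - baseline date - target_Y| <=
    tolerance.  Among multiple matches the tie break applies
    (closest-to-target by default; exactly equidistant candidates resolve to
    the earliest visit).  Participants without a match are excluded from that
    time point.
    """
    config = config or VisitMatchConfig()
    dates = pd.to_datetime(cohort["INFODT"], errors="raise")
    cohort = cohort.assign(_date=dates)
    baseline = cohort[cohort["EVENT_ID"] == BASELINE_VISIT]
    if baseline["PATNO"].duplicated().any():
        raise ValueError("multiple baseline visits for some participant(s)")
    base_dates = baseline.set_index("PATNO")["_date"]

    out: dict[str, pd.DataFrame] = {}
    for name, target in config.targets.items():
        rows = []
        for patno, base_date in base_dates.items():
            visits = cohort[(cohort["PATNO"] == patno) & (cohort["EVENT_ID"] != BASELINE_VISIT)]
            if visits.empty:
                continue
            delta = (visits["_date"] - base_date).dt.days
            off_target = (delta - target).abs()
            candidates = visits[off_target <= config.tolerance]
            if candidates.empty:
                continue
            if config.tie_break == "closest_to_target":
                keys = pd.DataFrame(
                    {"off": off_target[candidates.index], "date": candidates["_date"]}
                ).sort_values(["off", "date"])
            else:  # earliest
                keys = candidates[["_date"]].rename(columns={"_date": "date"}).sort_values("date")
            rows.append(candidates.loc[[keys.index[0]]])
        out[name] = (
            pd.concat(rows).drop(columns="_date").reset_index(drop=True)
            if rows
            else cohort.iloc[0:0].drop(columns="_date")
        )
    return out


@dataclass
class FeatureMatrix:
    """Participants x named features with per-column provenance.

    ``provenance`` maps each column to one of ``imaging``, ``clinical``,
    ``demographic`` or ``baseline_score``; ``scale_columns`` lists the
    continuous columns that the modelling layer standardises within each
    training fold (indicator columns pass through raw).
    """

    df: pd.DataFrame
    provenance: dict[str, str]
    scale_columns: list[str]
    code_map: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.df.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("feature columns must be unique")
        missing = [c for c in cols if c not in self.provenance]
        if missing:
            raise ValueError(f"columns without provenance: {missing}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    def columns_with_provenance(self, kind: str) -> list[str]:
        return [c for c in self.df.columns if self.provenance[c] == kind]

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.df.to_csv(path, sep="\t", index=True, index_label="PATNO")
        if sidecar is not None:
            Path(sidecar).write_text(
                json.dumps(
                    {
                        "provenance": self.provenance,
                        "scale_columns": self.scale_columns,
                        "code_map": self.code_map,
                    },
                    indent=2,
                )
            )


def _encode_categorical(series: pd.Series, column: str, mapping: dict[str, int]) -> pd.Series:
    def code(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, (int, np.integer)) and v in mapping.values():
            return int(v)  # already coded
        key = str(v).strip().lower()
        if key not in mapping:
            raise ValueError(
                f"unknown category {v!r} in column {column!r}; known: {sorted(mapping)}"
            )
        return mapping[key]

    return series.map(code)


def encode_features(
    cohort: pd.DataFrame,
    feature_set: str = "all",
    include_baseline_score: bool = False,
    code_map: dict[str, dict[str, int]] | None = None,
) -> FeatureMatrix:
    """Encode clinical/demographic columns of a one-row-per-participant table.

    Binary indicators for sex (male), handedness (right), dominant symptom
    side (right) and tremor/rigidity/postural-instability presence; integer
    codes for race/ethnicity per the shipped (overridable) code map;
    continuous columns pass through.  ``feature_set`` drops the columns its
    name implies; rows with missing continuous values are excluded with a log
    entry (no imputation at this stage).
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature_set {feature_set!r}; expected one of {FEATURE_SETS}")
    code_map = {**DEFAULT_CODE_MAP, **(code_map or {})}
    if cohort["PATNO"].duplicated().any():
        raise ValueError("expected one row per participant")
    cohort = cohort.set_index("PATNO")

    columns: dict[str, pd.Series] = {}
    provenance: dict[str, str] = {}
    scale: list[str] = []

    if feature_set != "imaging_only":
        for col in CONTINUOUS_DEMOGRAPHIC:
            columns[col] = cohort[col].astype(float)
            provenance[col] = "demographic"
            scale.append(col)
        for col in BINARY_DEMOGRAPHIC + CODED_DEMOGRAPHIC:
            columns[col] = _encode_categorical(cohort[col], col, code_map[col])
            provenance[col] = "demographic"
        for col in CONTINUOUS_CLINICAL:
            columns[col] = cohort[col].astype(float)
            provenance[col] = "clinical"
            scale.append(col)
        for col in BINARY_CLINICAL:
            if col == "DOMSIDE":
                if feature_set == "no_side":
                    continue
                columns[col] = _encode_categorical(cohort[col], col, code_map["DOMSIDE"])
            else:
                columns[col] = cohort[col].astype(float)
            provenance[col] = "clinical"
        if include_baseline_score and feature_set != "no_baseline_score":
            columns[BASELINE_SCORE_COLUMN] = cohort[BASELINE_SCORE_COLUMN].astype(float)
            provenance[BASELINE_SCORE_COLUMN] = "baseline_score"
            scale.append(BASELINE_SCORE_COLUMN)

    df = pd.DataFrame(columns, index=cohort.index)
    incomplete = df.isna().any(axis=1)
    if incomplete.any():
        logger.info(
            "encode_features: excluding %d participant(s) with missing values: %s",
            int(incomplete.sum()),
            list(df.index[incomplete]),
        )
        df = df[~incomplete]
    return FeatureMatrix(df, provenance, scale, code_map)


def assemble_features(
    encoded: FeatureMatrix | None,
    imaging: pd.DataFrame | None,
    feature_set: str = "all",
) -> FeatureMatrix:
    """Join encoded clinical/demographic features with imaging regional means.

    Imaging columns carry provenance ``imaging`` and are standardised by the
    modelling layer.  ``feature_set='clinical_only'`` drops the imaging block;
    ``'imaging_only'`` keeps only it.
    """
    if feature_set == "clinical_only" or imaging is None:
        if encoded is None:
            raise ValueError("no features left to assemble")
        return encoded
    if feature_set == "imaging_only" or encoded is None or encoded.df.shape[1] == 0:
        prov = {c: "imaging" for c in imaging.columns}
        return FeatureMatrix(imaging.copy(), prov, list(imaging.columns))
    common = encoded.df.index.intersection(imaging.index)
    df = pd.concat([encoded.df.loc[common], imaging.loc[common]], axis=1)
    provenance = dict(encoded.provenance)
    provenance.update({c: "imaging" for c in imaging.columns})
    scale = list(encoded.scale_columns) + list(imaging.columns)
    return FeatureMatrix(df, provenance, scale, encoded.code_map)


@dataclass
class SeverityThreshold:
    """High/low severity cut point: mean of per-time-point median totals."""

    value: float
    medians: dict[str, float]


def severity_threshold(totals_by_timepoint: dict[str, np.ndarray]) -> SeverityThreshold:
    """Average of the median MDS-UPDRS total at each time point."""
    if len(totals_by_timepoint) == 0:
        raise ValueError("need at least one time point")
    medians = {}
    for name, totals in totals_by_timepoint.items():
        arr = np.asarray(totals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"empty score list for time point {name!r}")
        medians[name] = float(np.median(arr))
    return SeverityThreshold(float(np.mean(list(medians.values()))), medians)
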