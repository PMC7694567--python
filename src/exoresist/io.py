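"""CSV readers/writers and run configuration.

All artifacts are tidy CSV (RFC-4180, UTF-8, dot decimal separator, time in
seconds as floats). Each reader validates its schema and fails with an
error naming the offending column; writer/reader pairs round-trip
losslessly at full float precision.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import BreathSeries, GaitTrial, SessionRecord, validate_outcome_table
from .errors import ValidationError

FLOAT_FMT = "%.10g"


def _read_csv_checked(
    path, required: list[str], *, numeric: list[str] | None = None
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    frame = pd.read_csv(path)
    for col in required:
        if col not in frame.columns:
            raise ValidationError(f"{path.name}: missing required column '{col}'")
    for col in numeric or []:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.isna().sum() > frame[col].isna().sum():
            raise ValidationError(
                f"{path.name}: column '{col}' contains non-numeric values "
                "(note: decimal separator must be '.', not ',')"
            )
        frame[col] = converted
    return frame


def _check_monotone_time(frame: pd.DataFrame, path) -> None:
    t = frame["time_s"].to_numpy(dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise ValidationError(f"{Path(path).name}: time_s must be strictly increasing")


# -- gait trials ------------------------------------------------------------


def write_gait_trial(trial: GaitTrial, path) -> None:
    trial.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_gait_trial(path) -> GaitTrial:
    frame = _read_csv_checked(path, ["time_s"], numeric=["time_s"])
    force_cols = [c for c in frame.columns if c.startswith("force_")]
    moment_cols = [c for c in frame.columns if c.startswith("moment_")]
    if not force_cols or not moment_cols:
        raise ValidationError(
            f"{Path(path).name}: expected force_<limb>_n and moment_<limb>_nm columns"
        )
    frame = _read_csv_checked(
        path, ["time_s"], numeric=["time_s", *force_cols, *moment_cols]
    )
    _check_monotone_time(frame, path)
    return GaitTrial.from_frame(frame)


# -- breath series ----------------------------------------------------------


def write_breath_series(series: BreathSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_breath_series(path) -> BreathSeries:
    frame = _read_csv_checked(
        path,
        ["time_s", "vo2_mlmin", "vco2_mlmin"],
        numeric=["time_s", "vo2_mlmin", "vco2_mlmin"],
    )
    _check_monotone_time(frame, path)
    return BreathSeries.from_frame(frame)


# -- outcome tables ---------------------------------------------------------


def write_outcome_table(table: pd.DataFrame, path) -> None:
    validate_outcome_table(table).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_outcome_table(path) -> pd.DataFrame:
    frame = _read_csv_checked(
        path, ["participant", "measure", "pre", "post"], numeric=["pre", "post"]
    )
    return validate_outcome_table(frame)


# -- session logs -----------------------------------------------------------

SESSION_COLUMNS = [
    "visit",
    "resistance_nmkg",
    "resistance_nm",
    "engagement",
    "soreness",
    "walk_min",
]


def write_session_log(records: list[SessionRecord], path) -> None:
    rows = [
        {
            "visit": r.visit,
            "resistance_nmkg": r.resistance_nmkg,
            "resistance_nm": r.resistance_nm,
            "engagement": r.engagement,
            "soreness": r.soreness.name,
            "walk_min": r.walk_minutes,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_session_log(path) -> list[SessionRecord]:
    frame = _read_csv_checked(
        path,
        SESSION_COLUMNS,
        numeric=["visit", "resistance_nmkg", "resistance_nm", "engagement", "walk_min"],
    )
    return [
        SessionRecord(
            visit=int(row.visit),
            resistance_nmkg=float(row.resistance_nmkg),
            resistance_nm=float(row.resistance_nm),
            engagement=float(row.engagement),
            soreness=row.soreness,
            walk_minutes=float(row.walk_min),
        )
        for row in frame.itertuples()
    ]


# -- run configuration ------------------------------------------------------


@dataclass
class RunConfig:
    """Every tunable of an end-to-end pipeline run, with defaults.

    Serialises losslessly to/from a plain-text YAML mapping; CLI flags
    override file values.
    """

    seed: int = 0
    n_participants: int = 6
    sessions: int = 10
    start_resistance_nmkg: float = 0.05
    increment_nm: float = 0.75
    engagement_tolerance: float = 0.95
    stance_threshold_n: float = 20.0
    lever_arm_m: float = 0.15
    metabolic_window: int = 20
    metabolic_alpha: float = 0.05
    alpha: float = 0.05
    d_variant: str = "dz"
    iqr_k: float = 1.5
    lilliefors_sims: int = 10_000
    effects: dict = field(default_factory=dict)  # overrides of EffectConfig.effects

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
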