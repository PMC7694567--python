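"""Core domain containers.

These are plain dataclasses around numpy arrays / pandas frames rather than
bespoke array classes: a gait trial is a set of per-limb sampled traces, a
breath series is an irregularly-timed gas-exchange record, and an outcome
table is a tidy participant x measure x {pre, post} frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Any

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Canonical outcome measure names, in reporting order.
MEASURES = ("mvc", "speed", "cot", "tug", "sixmwt")

#: Units of each outcome measure, for reports.
MEASURE_UNITS = {
    "mvc": "N/kg",
    "speed": "m/s",
    "cot": "J/(kg*m)",
    "tug": "s",
    "sixmwt": "m",
}

LIMBS = ("left", "right")


class SorenessLevel(IntEnum):
    """Ordinal post-session muscle soreness rating (0-4)."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    VERY_SEVERE = 4

    @classmethod
    def from_value(cls, value: "SorenessLevel | int | str") -> "SorenessLevel":
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, np.integer)):
            return cls(int(value))
        key = str(value).strip().upper().replace(" ", "_")
        try:
            return cls[key]
        except KeyError as exc:
            raise ValidationError(f"unknown soreness level: {value!r}") from exc


@dataclass(frozen=True)
class ParticipantProfile:
    """Static description of one study participant.

    ``asymmetry`` scales the more-affected limb's peak plantar-flexion
    moment relative to the less-affected limb (1.0 means symmetric).
    """

    id: str
    body_mass: float  # kg
    affected_side: str = "left"  # {"left", "right", "both"}
    asymmetry: float = 1.0  # (0, 1]
    baseline_mvc: float = 2.0  # N/kg
    baseline_speed: float = 0.9  # m/s
    baseline_cot: float = 7.0  # J/(kg*m)
    baseline_tug: float = 8.5  # s
    baseline_6mwt: float = 450.0  # m
    soreness_propensity: float = 1.0  # unitless >= 0

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValidationError("body_mass must be > 0")
        if self.baseline_speed <= 0:
            raise ValidationError("baseline_speed must be > 0")
        if self.baseline_cot <= 0:
            raise ValidationError("baseline_cot must be > 0")
        if not (0 < self.asymmetry <= 1):
            raise ValidationError("asymmetry must lie in (0, 1]")
        if self.affected_side not in ("left", "right", "both"):
            raise ValidationError("affected_side must be 'left', 'right' or 'both'")
        if self.soreness_propensity < 0:
            raise ValidationError("soreness_propensity must be >= 0")

    def limb_scale(self, limb: str) -> float:
        """Peak-moment scale factor for ``limb`` given the affected side."""
        if self.affected_side == "both" or limb == self.affected_side:
            return self.asymmetry
        return 1.0


@dataclass
class GaitTrial:
    """Per-limb forefoot force and ankle moment traces for one walking bout.

    ``forefoot_force`` holds nonnegative sensor force in N; ``ankle_moment``
    holds the (simulated ground-truth) biological plantar-flexion moment in
    Nm. All traces of a trial share the sampling grid.
    """

    sample_rate: float  # Hz
    forefoot_force: dict[str, np.ndarray]  # limb -> N
    ankle_moment: dict[str, np.ndarray]  # limb -> Nm
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be > 0")
        if set(self.forefoot_force) != set(self.ankle_moment):
            raise ValidationError("force and moment must cover the same limbs")
        n = None
        for limb, f in self.forefoot_force.items():
            f = np.asarray(f, dtype=float)
            m = np.asarray(self.ankle_moment[limb], dtype=float)
            if f.shape != m.shape:
                raise ValidationError(f"{limb}: force/moment length mismatch")
            if np.any(f < 0):
                raise ValidationError(f"{limb}: forefoot force must be >= 0")
            if n is None:
                n = f.size
            elif f.size != n:
                raise ValidationError("all limbs must share the sampling grid")
            self.forefoot_force[limb] = f
            self.ankle_moment[limb] = m

    @property
    def limbs(self) -> tuple[str, ...]:
        return tuple(sorted(self.forefoot_force))

    @property
    def n_samples(self) -> int:
        return next(iter(self.forefoot_force.values())).size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        """Tidy wide frame: time_s then per-limb force and moment columns."""
        data: dict[str, np.ndarray] = {"time_s": self.time}
        for limb in self.limbs:
            data[f"force_{limb}_n"] = self.forefoot_force[limb]
        for limb in self.limbs:
            data[f"moment_{limb}_nm"] = self.ankle_moment[limb]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GaitTrial":
        t = np.asarray(frame["time_s"], dtype=float)
        if t.size < 2:
            raise ValidationError("gait trial needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError("time_s must be strictly increasing")
        sample_rate = 1.0 / float(np.median(dt))
        force = {}
        moment = {}
        for col in frame.columns:
            if col.startswith("force_") and col.endswith("_n"):
                force[col[len("force_"):-len("_n")]] = np.asarray(frame[col], float)
            elif col.startswith("moment_") and col.endswith("_nm"):
                moment[col[len("moment_"):-len("_nm")]] = np.asarray(frame[col], float)
        if not force:
            raise ValidationError("no force_<limb>_n columns found")
        return cls(sample_rate=sample_rate, forefoot_force=force, ankle_moment=moment)


@dataclass
class BreathSeries:
    """Breath-by-breath gas exchange for one activity.

    Times are seconds from activity onset and strictly increasing; vo2/vco2
    are in ml/min.
    """

    time: np.ndarray  # s
    vo2: np.ndarray  # ml/min
    vco2: np.ndarray  # ml/min
    activity: str = "walk"  # {"sit", "stand", "walk"}
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        if not (self.time.size == self.vo2.size == self.vco2.size):
            raise ValidationError("time/vo2/vco2 must have equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValidationError("breath times must be strictly increasing")
        if np.any(self.vo2 < 0) or np.any(self.vco2 < 0):
            raise ValidationError("gas-exchange rates must be >= 0")
        if self.activity not in ("sit", "stand", "walk"):
            raise ValidationError("activity must be 'sit', 'stand' or 'walk'")

    @property
    def n_breaths(self) -> int:
        return self.time.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "vo2_mlmin": self.vo2,
                "vco2_mlmin": self.vco2,
                "activity": self.activity,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BreathSeries":
        activity = "walk"
        if "activity" in frame.columns and len(frame):
            activity = str(frame["activity"].iloc[0])
        return cls(
            time=np.asarray(frame["time_s"], float),
            vo2=np.asarray(frame["vo2_mlmin"], float),
            vco2=np.asarray(frame["vco2_mlmin"], float),
            activity=activity,
        )


@dataclass(frozen=True)
class CalibrationResult:
    """Average peak biological ankle moment per limb from a calibration bout."""

    mean_peak_moment: dict[str, float]  # limb -> Nm
    strides_used: dict[str, int]

    def __post_init__(self) -> None:
        for limb, peak in self.mean_peak_moment.items():
            if peak <= 0:
                raise ValidationError(f"{limb}: mean peak moment must be > 0")
            if self.strides_used.get(limb, 0) < 1:
                raise ValidationError(f"{limb}: calibration needs >= 1 stride")

    @property
    def limbs(self) -> tuple[str, ...]:
        return tuple(sorted(self.mean_peak_moment))


@dataclass(frozen=True)
class ControllerConfig:
    """Parameters of the proportional resistance controller.

    ``resistance_nmkg`` is the prescribed resistance level r in Nm/kg: the
    torque commanded when the instantaneous estimated ankle moment reaches
    the calibrated peak. Output is clipped to [0, r * body_mass] Nm.
    """

    resistance_nmkg: float  # Nm/kg
    body_mass: float  # kg
    stance_force_threshold: float = 20.0  # N
    lever_arm_m: float = 0.15  # m, forefoot force -> ankle moment
    debounce_s: float = 0.1  # min stance duration for interval segmentation

    def __post_init__(self) -> None:
        if self.resistance_nmkg < 0:
            raise ValidationError("resistance_nmkg must be >= 0")
        if self.body_mass <= 0:
            raise ValidationError("body_mass must be > 0")
        if self.stance_force_threshold < 0:
            raise ValidationError("stance_force_threshold must be >= 0")
        if self.lever_arm_m <= 0:
            raise ValidationError("lever_arm_m must be > 0")

    @property
    def resistance_nm(self) -> float:
        return self.resistance_nmkg * self.body_mass


@dataclass
class SessionRecord:
    """One training visit of the ten-session protocol."""

    visit: int  # 1-10
    resistance_nmkg: float
    resistance_nm: float
    engagement: float  # fraction of strides reaching prescribed resistance
    soreness: SorenessLevel
    walk_minutes: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.engagement <= 1.0):
            raise ValidationError("engagement must lie in [0, 1]")
        if self.resistance_nmkg < 0 or self.resistance_nm < 0:
            raise ValidationError("resistance must be >= 0")
        self.soreness = SorenessLevel.from_value(self.soreness)


def validate_outcome_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy outcome table (participant, measure, pre, post).

    At most one row per participant x measure; missing post values are
    allowed (a participant may fail to complete a test) and handled by
    listwise deletion downstream.
    """
    required = {"participant", "measure", "pre", "post"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"outcome table missing columns: {sorted(missing)}")
    bad = set(table["measure"]) - set(MEASURES)
    if bad:
        raise ValidationError(f"unknown measures: {sorted(bad)}; expected {MEASURES}")
    dup = table.duplicated(subset=["participant", "measure"])
    if dup.any():
        raise ValidationError("duplicate participant x measure rows")
    out = table.copy()
    out["pre"] = pd.to_numeric(out["pre"], errors="raise")
    out["post"] = pd.to_numeric(out["post"], errors="raise")
    return out
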