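"""Ten-session training-progression engine.

After each 20-minute training visit the participant reports an ordinal
soreness level and the session log yields an engagement fraction — the
proportion of gait cycles whose peak applied torque reached the prescribed
resistance. Resistance is incremented by a fixed amount (0.5-1 Nm, default
0.75 Nm) for the next visit only when both gates pass:

1. engagement > 50% of gait cycles, and
2. soreness no worse than Moderate.

Otherwise resistance stays where it is; it never decreases.
"""

from __future__ import annotations

import warnings

import numpy as np

from .controller import ProportionalResistanceController
from .datatypes import ParticipantProfile, SessionRecord, SorenessLevel
from .errors import ValidationError
from .synth import draw_soreness, generate_gait_trial, stream_rng

__all__ = [
    "engagement_fraction",
    "next_resistance",
    "simulate_training_course",
]

START_R_RANGE = (0.025, 0.075)  # documented initial resistance range, Nm/kg
INCREMENT_RANGE = (0.5, 1.0)  # allowed per-session increment, Nm


def engagement_fraction(
    stride_peak_torque_nm: np.ndarray,
    prescribed_nm: float,
    tolerance: float = 0.95,
) -> float:
    """Fraction of strides whose peak applied torque reached the
    prescription, within ``tolerance`` (peak >= tolerance * prescribed)."""
    peaks = np.asarray(stride_peak_torque_nm, dtype=float)
    if peaks.size == 0:
        raise ValidationError("stride peak list is empty")
    if prescribed_nm <= 0:
        raise ValidationError("prescribed torque must be > 0")
    if not (0 < tolerance <= 1):
        raise ValidationError("tolerance must lie in (0, 1]")
    return float(np.mean(peaks >= tolerance * prescribed_nm))


def next_resistance(
    record: SessionRecord, increment_nm: float, body_mass: float
) -> tuple[float, float]:
    """Resistance for the following visit, as ``(nmkg, nm)``.

    Incremented by ``increment_nm`` iff engagement > 0.5 and soreness is at
    most Moderate; unchanged otherwise.
    """
    if not (INCREMENT_RANGE[0] <= increment_nm <= INCREMENT_RANGE[1]):
        raise ValidationError(
            f"increment must lie in [{INCREMENT_RANGE[0]}, {INCREMENT_RANGE[1]}] Nm"
        )
    if body_mass <= 0:
        raise ValidationError("body_mass must be > 0")
    if record.engagement > 0.5 and record.soreness <= SorenessLevel.MODERATE:
        new_nm = record.resistance_nm + increment_nm
    else:
        new_nm = record.resistance_nm
    return new_nm / body_mass, new_nm


def simulate_training_course(
    profile: ParticipantProfile,
    start_r: float = 0.05,
    sessions: int = 10,
    seed: int = 0,
    *,
    increment_nm: float = 0.75,
    engagement_tolerance: float = 0.95,
    walk_minutes: float = 20.0,
    bout_duration_s: float = 60.0,
    cadence: float = 100.0,
    peak_cv: float = 0.2,
    forced_soreness: SorenessLevel | None = None,
) -> list[SessionRecord]:
    """Simulate a full training course for one participant.

    Each visit chains: simulate a walking bout -> apply the proportional
    controller at the current resistance -> score engagement from per-stride
    peak applied torque -> draw an ordinal soreness response -> gate the
    next visit's resistance. Calibration is performed once, on a bout
    walked before the first session.

    A representative ``bout_duration_s`` bout stands in for the full
    ``walk_minutes`` of walking (the controller is stationary within a
    session, so stride statistics from a shorter bout are unbiased);
    ``walk_minutes`` is recorded on every session log.
    ``forced_soreness`` overrides the stochastic soreness response (useful
    for protocol what-if runs).
    """
    if sessions < 1:
        raise ValidationError("sessions must be >= 1")
    if not (START_R_RANGE[0] <= start_r <= START_R_RANGE[1]):
        warnings.warn(
            f"start_r={start_r} Nm/kg outside the documented range "
            f"{START_R_RANGE}; proceeding",
            stacklevel=2,
        )

    rng = stream_rng(seed, "session")
    controller = ProportionalResistanceController(
        resistance_nmkg=start_r, body_mass=profile.body_mass
    )
    cal_trial = generate_gait_trial(
        profile,
        duration=bout_duration_s,
        cadence=cadence,
        seed=int(rng.integers(2**31)),
        peak_cv=peak_cv,
    )
    controller.fit(cal_trial)

    records: list[SessionRecord] = []
    r_nmkg = start_r
    r_nm = start_r * profile.body_mass
    for visit in range(1, sessions + 1):
        controller.set_params(resistance_nmkg=r_nmkg)
        trial = generate_gait_trial(
            profile,
            duration=bout_duration_s,
            cadence=cadence,
            seed=int(rng.integers(2**31)),
            peak_cv=peak_cv,
        )
        result = controller.transform(trial)
        engagement = engagement_fraction(
            result.all_stride_peaks_nm(), r_nm, tolerance=engagement_tolerance
        )
        if forced_soreness is not None:
            soreness = forced_soreness
        else:
            soreness = draw_soreness(
                r_nmkg, engagement, profile.soreness_propensity, rng
            )
        record = SessionRecord(
            visit=visit,
            resistance_nmkg=r_nmkg,
            resistance_nm=r_nm,
            engagement=engagement,
            soreness=soreness,
            walk_minutes=walk_minutes,
        )
        records.append(record)
        r_nmkg, r_nm = next_resistance(record, increment_nm, profile.body_mass)
    return records
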