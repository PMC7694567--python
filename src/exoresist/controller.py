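"""Discrete-time simulation of the adaptive proportional resistance
controller.

The control law is deliberately simple and mirrors what runs on the device:
during each stance phase the biological ankle moment M̂(t) is estimated from
forefoot force through a lever-arm proportionality, expressed as a fraction
of the calibrated average peak moment M_peak, and a resistive plantar-flexion
torque

    tau(t) = r * clip(M̂(t) / M_peak, 0, 1) * body_mass      [Nm]

is commanded, where r is the prescribed resistance level in Nm/kg. At 100%
of the calibrated peak the full prescribed resistance is applied, at 50%
half of it, and during swing (zero estimated moment) none. The command at
sample k depends only on samples <= k (causal, no lookahead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import CalibrationResult, ControllerConfig, GaitTrial
from .errors import CalibrationError, ConfigurationError, ValidationError

__all__ = [
    "detect_stance",
    "estimate_ankle_moment",
    "calibrate_peak_moment",
    "compute_resistance_torque",
    "run_session",
    "SessionResult",
    "ProportionalResistanceController",
]


def detect_stance(
    forefoot_force: np.ndarray,
    threshold: float,
    *,
    sample_rate: float | None = None,
    min_duration_s: float = 0.0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Threshold-based stance detection on a forefoot force trace.

    A sample is stance iff force > threshold; stance intervals are the
    maximal runs of stance samples, returned as half-open ``(start, stop)``
    index pairs. With ``min_duration_s > 0`` (requires ``sample_rate``),
    runs shorter than that are discarded from the interval list — a
    debounce against sensor chatter — but the per-sample flags are left as
    the raw threshold comparison.
    """
    force = np.asarray(forefoot_force, dtype=float)
    if force.size == 0:
        raise ValidationError("force series is empty")
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    stance = force > threshold

    padded = np.concatenate(([False], stance, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    intervals = list(zip(starts.tolist(), stops.tolist()))
    if min_duration_s > 0:
        if sample_rate is None:
            raise ValidationError("debounce requires sample_rate")
        min_n = int(round(min_duration_s * sample_rate))
        intervals = [(a, b) for a, b in intervals if b - a >= min_n]
    return stance, intervals


def estimate_ankle_moment(
    forefoot_force: np.ndarray | float, lever_arm: float
) -> np.ndarray | float:
    """Estimate biological ankle moment (Nm) from forefoot force (N)."""
    if lever_arm <= 0:
        raise ValidationError("lever_arm must be > 0")
    force = np.asarray(forefoot_force, dtype=float)
    if np.any(force < 0):
        raise ValidationError("forefoot force must be >= 0")
    moment = force * lever_arm
    return float(moment) if moment.ndim == 0 else moment


def calibrate_peak_moment(
    trial: GaitTrial,
    threshold: float,
    *,
    lever_arm: float = 0.15,
    debounce_s: float = 0.1,
) -> CalibrationResult:
    """Average peak estimated ankle moment per limb over a calibration bout.

    For each limb, each stance interval contributes its within-interval
    maximum estimated moment; M_peak is the mean of those per-stride peaks.
    """
    mean_peak: dict[str, float] = {}
    strides: dict[str, int] = {}
    for limb in trial.limbs:
        _, intervals = detect_stance(
            trial.forefoot_force[limb],
            threshold,
            sample_rate=trial.sample_rate,
            min_duration_s=debounce_s,
        )
        if not intervals:
            raise CalibrationError(f"{limb}: no stance intervals found")
        moment = estimate_ankle_moment(trial.forefoot_force[limb], lever_arm)
        peaks = [float(np.max(moment[a:b])) for a, b in intervals]
        mean_peak[limb] = float(np.mean(peaks))
        strides[limb] = len(peaks)
    return CalibrationResult(mean_peak_moment=mean_peak, strides_used=strides)


def compute_resistance_torque(
    moment_fraction: np.ndarray | float, config: ControllerConfig
) -> np.ndarray | float:
    """Normalized resistance torque (Nm/kg) for a given moment fraction.

    ``moment_fraction`` is M̂(t)/M_peak and may exceed 1 (stronger-than-
    calibration strides); it is clipped to [0, 1], so the output lies in
    [0, r].
    """
    frac = np.clip(np.asarray(moment_fraction, dtype=float), 0.0, 1.0)
    tau_nmkg = config.resistance_nmkg * frac
    return float(tau_nmkg) if tau_nmkg.ndim == 0 else tau_nmkg


@dataclass
class SessionResult:
    """Applied-torque traces and per-stride peaks for one simulated bout."""

    torque_nm: dict[str, np.ndarray]
    torque_nmkg: dict[str, np.ndarray]
    stance: dict[str, np.ndarray]
    stride_peak_torque_nm: dict[str, np.ndarray]
    config: ControllerConfig

    @property
    def limbs(self) -> tuple[str, ...]:
        return tuple(sorted(self.torque_nm))

    def all_stride_peaks_nm(self) -> np.ndarray:
        return np.concatenate([self.stride_peak_torque_nm[l] for l in self.limbs])


def run_session(
    trial: GaitTrial, calibration: CalibrationResult, config: ControllerConfig
) -> SessionResult:
    """Apply the proportional controller over a full trial.

    The torque at each sample is computed from that sample's force alone
    (causal); swing samples (force <= threshold) command exactly zero.
    Per-stride peak applied torque is reported over debounced stance
    intervals for engagement scoring.
    """
    if set(calibration.limbs) != set(trial.limbs):
        raise ConfigurationError(
            f"calibration limbs {calibration.limbs} do not match trial limbs "
            f"{trial.limbs}"
        )
    torque_nm: dict[str, np.ndarray] = {}
    torque_nmkg: dict[str, np.ndarray] = {}
    stance_flags: dict[str, np.ndarray] = {}
    stride_peaks: dict[str, np.ndarray] = {}
    for limb in trial.limbs:
        force = trial.forefoot_force[limb]
        stance, intervals = detect_stance(
            force,
            config.stance_force_threshold,
            sample_rate=trial.sample_rate,
            min_duration_s=config.debounce_s,
        )
        moment = estimate_ankle_moment(force, config.lever_arm_m)
        fraction = moment / calibration.mean_peak_moment[limb]
        tau_nmkg = np.where(
            stance, compute_resistance_torque(fraction, config), 0.0
        )
        tau_nm = tau_nmkg * config.body_mass
        torque_nmkg[limb] = tau_nmkg
        torque_nm[limb] = tau_nm
        stance_flags[limb] = stance
        stride_peaks[limb] = np.array(
            [float(np.max(tau_nm[a:b])) for a, b in intervals]
        )
    return SessionResult(
        torque_nm=torque_nm,
        torque_nmkg=torque_nmkg,
        stance=stance_flags,
        stride_peak_torque_nm=stride_peaks,
        config=config,
    )


class ProportionalResistanceController(BaseEstimator):
    """Scikit-learn-style wrapper around calibration + torque generation.

    ``fit(trial)`` runs the peak-moment calibration on a walking bout;
    ``transform(trial)`` applies the proportional control law to a (possibly
    different) bout and returns the applied-torque traces.

    Parameters
    ----------
    resistance_nmkg : float
        Prescribed resistance level r, Nm per kg body mass.
    body_mass : float
        Participant body mass, kg.
    stance_threshold_n : float
        Forefoot-force threshold separating stance from swing, N.
    lever_arm_m : float
        Lever arm converting forefoot force to estimated ankle moment, m.
    debounce_s : float
        Minimum stance-interval duration for stride segmentation, s.

    Attributes
    ----------
    calibration_ : CalibrationResult
        Per-limb average peak estimated ankle moment after ``fit``.
    """

    def __init__(
        self,
        resistance_nmkg: float = 0.1,
        body_mass: float = 50.0,
        stance_threshold_n: float = 20.0,
        lever_arm_m: float = 0.15,
        debounce_s: float = 0.1,
    ):
        self.resistance_nmkg = resistance_nmkg
        self.body_mass = body_mass
        self.stance_threshold_n = stance_threshold_n
        self.lever_arm_m = lever_arm_m
        self.debounce_s = debounce_s

    def _config(self) -> ControllerConfig:
        return ControllerConfig(
            resistance_nmkg=self.resistance_nmkg,
            body_mass=self.body_mass,
            stance_force_threshold=self.stance_threshold_n,
            lever_arm_m=self.lever_arm_m,
            debounce_s=self.debounce_s,
        )

    def fit(self, trial: GaitTrial, y=None) -> "ProportionalResistanceController":
        self.calibration_ = calibrate_peak_moment(
            trial,
            self.stance_threshold_n,
            lever_arm=self.lever_arm_m,
            debounce_s=self.debounce_s,
        )
        return self

    def transform(self, trial: GaitTrial) -> SessionResult:
        if not hasattr(self, "calibration_"):
            raise CalibrationError("controller is not calibrated; call fit() first")
        return run_session(trial, self.calibration_, self._config())

    def fit_transform(self, trial: GaitTrial, y=None) -> SessionResult:
        return self.fit(trial).transform(trial)
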