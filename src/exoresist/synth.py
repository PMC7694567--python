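"""Seeded generators for gait trials, breath series, soreness responses and
whole pre/post cohorts.

All generators are pure functions of their arguments and a seed. A single
global seed is split deterministically into independent per-stream
substreams via :class:`numpy.random.SeedSequence`, so regenerating one
artifact never perturbs another.

The gait generator produces, per limb, a quasi-periodic stance/swing
pattern: forefoot force is exactly zero throughout swing and follows a
smooth single-peak plantar-flexion profile during stance, with the peak at
a configurable fraction of stance (late stance by default). Stride-to-stride
peak magnitudes vary with a configurable coefficient of variation, and the
more-affected limb's peaks are scaled down by the profile's asymmetry
ratio.

The breath generator emulates breath-by-breath indirect calorimetry: an
exponential on-transient from a resting rate to a steady rate, additive
Gaussian noise, log-normally jittered inter-breath intervals, and
quantisation at the instrument's reporting resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    MEASURES,
    BreathSeries,
    GaitTrial,
    ParticipantProfile,
    SorenessLevel,
)
from .errors import ValidationError

# Stream labels -> fixed offsets mixed into the SeedSequence, so each kind of
# artifact draws from an independent, reproducible substream.
_STREAMS = {"gait": 11, "breath": 23, "cohort": 37, "soreness": 53, "session": 71}


def stream_rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    """Deterministic per-stream generator derived from one global seed."""
    if stream not in _STREAMS:
        raise ValidationError(f"unknown stream {stream!r}")
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[stream], *map(int, extra)])
    )


# ---------------------------------------------------------------------------
# Gait trials


def _stance_shape(phase: np.ndarray, peak_frac: float) -> np.ndarray:
    """Smooth unimodal raised-cosine stance profile on phase in [0, 1].

    Rises 0 -> 1 over [0, peak_frac] and falls 1 -> 0 over [peak_frac, 1],
    each as a half raised cosine; C1-continuous at the peak.
    """
    up = 0.5 * (1.0 - np.cos(np.pi * phase / peak_frac))
    down = 0.5 * (1.0 - np.cos(np.pi * (1.0 - phase) / (1.0 - peak_frac)))
    return np.where(phase <= peak_frac, up, down)


def generate_gait_trial(
    profile: ParticipantProfile,
    duration: float = 60.0,
    cadence: float = 100.0,
    sample_rate: float = 100.0,
    seed: int = 0,
    *,
    stance_fraction: float = 0.6,
    peak_moment_nmkg: float = 0.9,
    peak_cv: float = 0.1,
    peak_timing: float = 0.75,
    lever_arm_m: float = 0.15,
) -> GaitTrial:
    """Simulate a walking bout for one participant.

    Parameters
    ----------
    duration : s; cadence : steps/min (both limbs combined);
    sample_rate : Hz (>= 50); stance_fraction : stance share of the stride;
    peak_moment_nmkg : mean peak plantar-flexion moment of the less-affected
    limb, Nm per kg body mass; peak_cv : stride-to-stride coefficient of
    variation of the peak; peak_timing : stance fraction at which the peak
    occurs; lever_arm_m : forefoot-sensor lever arm linking force and moment.

    The generated ankle moment is the simulation's ground truth; forefoot
    force is moment / lever_arm, so force and moment are coherent.
    """
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    if cadence <= 0:
        raise ValidationError("cadence must be > 0")
    if sample_rate < 50:
        raise ValidationError("sample_rate must be >= 50 Hz")
    if not (0 < stance_fraction < 1):
        raise ValidationError("stance_fraction must lie in (0, 1)")
    if not (0 < peak_timing < 1):
        raise ValidationError("peak_timing must lie in (0, 1)")
    if peak_cv < 0:
        raise ValidationError("peak_cv must be >= 0")

    rng = stream_rng(seed, "gait")
    stride_period = 120.0 / cadence  # two steps per stride
    stance_dur = stance_fraction * stride_period
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate

    force: dict[str, np.ndarray] = {}
    moment: dict[str, np.ndarray] = {}
    peaks_meta: dict[str, np.ndarray] = {}
    offsets = {"left": 0.0, "right": stride_period / 2.0}
    for limb, offset in offsets.items():
        base_peak = peak_moment_nmkg * profile.body_mass * profile.limb_scale(limb)
        n_strides = int(np.ceil((duration + offset) / stride_period)) + 1
        stride_peaks = base_peak * (1.0 + peak_cv * rng.standard_normal(n_strides))
        stride_peaks = np.maximum(stride_peaks, 0.05 * base_peak)

        rel = t - offset
        idx = np.floor(rel / stride_period).astype(int)
        phase = (rel - idx * stride_period) / stance_dur
        in_stance = (rel >= 0) & (phase >= 0.0) & (phase <= 1.0)
        m = np.zeros(n)
        ph = np.clip(phase[in_stance], 0.0, 1.0)
        m[in_stance] = stride_peaks[idx[in_stance]] * _stance_shape(ph, peak_timing)
        moment[limb] = m
        force[limb] = m / lever_arm_m
        peaks_meta[limb] = stride_peaks

    return GaitTrial(
        sample_rate=sample_rate,
        forefoot_force=force,
        ankle_moment=moment,
        meta={
            "seed": seed,
            "cadence": cadence,
            "stride_period_s": stride_period,
            "stance_fraction": stance_fraction,
            "peak_timing": peak_timing,
            "lever_arm_m": lever_arm_m,
            "peak_cv": peak_cv,
            "configured_peaks_nm": {
                limb: peak_moment_nmkg * profile.body_mass * profile.limb_scale(limb)
                for limb in offsets
            },
            "stride_peaks_nm": peaks_meta,
        },
    )


# ---------------------------------------------------------------------------
# Breath-by-breath gas exchange


def generate_breath_series(
    activity: str,
    steady_rate_vo2: float,
    steady_rate_vco2: float,
    tau_on: float = 30.0,
    noise_sd: float = 0.0,
    duration: float = 360.0,
    seed: int = 0,
    *,
    rest_fraction: float = 0.35,
    mean_ibi: float = 3.0,
    ibi_sigma: float = 0.25,
    quantum: float = 1.0,
) -> BreathSeries:
    """Simulate breath-by-breath V̇O2/V̇CO2 for one activity bout.

    The expected trace follows ``rest + (steady - rest) * (1 - exp(-t/tau))``
    with resting rate ``rest_fraction * steady``, additive Gaussian noise of
    SD ``noise_sd`` (ml/min), log-normally jittered inter-breath intervals
    with mean ``mean_ibi`` seconds, and values reported at the instrument
    resolution ``quantum`` (ml/min; default 1.0 = a 0.001 L/min cart readout; 0 disables
    quantisation).
    """
    if steady_rate_vo2 <= 0 or steady_rate_vco2 <= 0:
        raise ValidationError("steady rates must be > 0")
    if tau_on <= 0:
        raise ValidationError("tau_on must be > 0")
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if not (0 <= rest_fraction < 1):
        raise ValidationError("rest_fraction must lie in [0, 1)")

    rng = stream_rng(seed, "breath")
    # log-normal IBIs with mean `mean_ibi`: mu = ln(mean) - sigma^2/2
    mu = np.log(mean_ibi) - 0.5 * ibi_sigma**2
    n_max = int(np.ceil(duration / mean_ibi * 2)) + 10
    ibis = rng.lognormal(mean=mu, sigma=ibi_sigma, size=n_max)
    times = np.cumsum(ibis)
    times = times[times <= duration]
    if times.size == 0:
        raise ValidationError("duration too short for a single breath")

    def trace(steady: float) -> np.ndarray:
        rest = rest_fraction * steady
        expected = rest + (steady - rest) * (1.0 - np.exp(-times / tau_on))
        noisy = expected + noise_sd * rng.standard_normal(times.size)
        noisy = np.maximum(noisy, 0.0)
        if quantum > 0:
            noisy = np.round(noisy / quantum) * quantum
        return noisy

    return BreathSeries(
        time=times,
        vo2=trace(steady_rate_vo2),
        vco2=trace(steady_rate_vco2),
        activity=activity,
        meta={
            "seed": seed,
            "steady_rate_vo2": steady_rate_vo2,
            "steady_rate_vco2": steady_rate_vco2,
            "rest_fraction": rest_fraction,
            "tau_on": tau_on,
            "noise_sd": noise_sd,
            "quantum": quantum,
        },
    )


# ---------------------------------------------------------------------------
# Soreness


def draw_soreness(
    resistance_nmkg: float,
    engagement: float,
    propensity: float,
    rng: np.random.Generator,
    *,
    cuts: tuple[float, ...] = (0.015, 0.05, 0.11, 0.22),
    scale: float = 0.03,
) -> SorenessLevel:
    """Draw an ordinal soreness rating from a cumulative-logistic model.

    The latent drive is ``resistance * engagement * propensity``; ordinal
    category k is reached when drive plus logistic noise exceeds ``cuts[k-1]``.
    Defaults are chosen so that mid-protocol resistance with typical
    engagement most often yields Mild-Moderate soreness, Severe is rare and
    Very Severe is exceptional.
    """
    drive = resistance_nmkg * engagement * propensity
    latent = drive + scale * rng.logistic()
    return SorenessLevel(int(np.searchsorted(np.asarray(cuts), latent, side="left")))


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class EffectConfig:
    """Configured pre -> post effects of training, per outcome measure.

    Effects are fractional multiplicative changes (e.g. +0.17 for a 17%
    increase); ``effect_sd`` is the between-participant SD of the effect and
    ``noise_sd`` the fractional measurement noise added to the post score.
    Defaults mirror the group-level changes the training study reported:
    strength +17+/-8%, treadmill speed +39+/-25%, cost of transport
    -33+/-9%, TUG -11+/-9%, 6MWT +13+/-9%.
    """

    effects: dict[str, float] = field(
        default_factory=lambda: {
            "mvc": 0.17,
            "speed": 0.39,
            "cot": -0.33,
            "tug": -0.11,
            "sixmwt": 0.13,
        }
    )
    effect_sd: dict[str, float] = field(
        default_factory=lambda: {
            "mvc": 0.08,
            "speed": 0.25,
            "cot": 0.09,
            "tug": 0.09,
            "sixmwt": 0.09,
        }
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {m: 0.02 for m in MEASURES}
    )

    def __post_init__(self) -> None:
        for name, table in (("effect_sd", self.effect_sd), ("noise_sd", self.noise_sd)):
            for m, v in table.items():
                if v < 0:
                    raise ValidationError(f"{name}[{m}] must be >= 0")

    @classmethod
    def null(cls) -> "EffectConfig":
        """No training effect, no between-participant spread; noise kept."""
        zeros = {m: 0.0 for m in MEASURES}
        return cls(effects=dict(zeros), effect_sd=dict(zeros))

    @classmethod
    def null_noiseless(cls) -> "EffectConfig":
        """No effect and no measurement noise: post must equal pre."""
        zeros = {m: 0.0 for m in MEASURES}
        return cls(effects=dict(zeros), effect_sd=dict(zeros), noise_sd=dict(zeros))


def generate_profiles(n: int, seed: int = 0) -> list[ParticipantProfile]:
    """Draw ``n`` participant profiles typical of independently ambulant
    adolescents with spastic cerebral palsy."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = stream_rng(seed, "cohort", 0)
    profiles = []
    for i in range(n):
        side = rng.choice(["left", "right", "both"])
        profiles.append(
            ParticipantProfile(
                id=f"S{i + 1}",
                body_mass=float(np.clip(rng.normal(52, 12), 25, 90)),
                affected_side=str(side),
                asymmetry=float(rng.uniform(0.6, 1.0)),
                baseline_mvc=float(np.clip(rng.normal(2.0, 0.5), 0.5, None)),
                baseline_speed=float(np.clip(rng.normal(0.9, 0.25), 0.3, None)),
                baseline_cot=float(np.clip(rng.normal(7.0, 1.8), 2.5, None)),
                baseline_tug=float(np.clip(rng.normal(8.5, 2.0), 4.0, None)),
                baseline_6mwt=float(np.clip(rng.normal(450, 80), 150, None)),
                soreness_propensity=float(rng.lognormal(0.0, 0.3)),
            )
        )
    return profiles


_BASELINE_FIELD = {
    "mvc": "baseline_mvc",
    "speed": "baseline_speed",
    "cot": "baseline_cot",
    "tug": "baseline_tug",
    "sixmwt": "baseline_6mwt",
}


def generate_cohort(
    n: int,
    effects: EffectConfig | None = None,
    seed: int = 0,
    *,
    profiles: list[ParticipantProfile] | None = None,
    pre_noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, list[ParticipantProfile]]:
    """Generate a pre/post outcome table for a cohort of ``n`` participants.

    Pre scores are the profile baselines perturbed by fractional noise
    ``pre_noise_sd``; post scores are
    ``pre * (1 + effect + participant_deviate) + measurement_noise`` where
    the deviate is N(0, effect_sd) per participant and measure, and the
    measurement noise is N(0, noise_sd * baseline).

    Returns the tidy OutcomeTable (participant, measure, pre, post) and the
    profiles used.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    effects = effects or EffectConfig()
    if profiles is None:
        profiles = generate_profiles(n, seed)
    elif len(profiles) != n:
        raise ValidationError("profiles length must equal n")
    rng = stream_rng(seed, "cohort", 1)

    rows = []
    for prof in profiles:
        for measure in MEASURES:
            base = getattr(prof, _BASELINE_FIELD[measure])
            pre = base * (1.0 + pre_noise_sd * rng.standard_normal())
            deviate = effects.effect_sd[measure] * rng.standard_normal()
            eps = effects.noise_sd[measure] * base * rng.standard_normal()
            post = pre * (1.0 + effects.effects[measure] + deviate) + eps
            rows.append(
                {"participant": prof.id, "measure": measure, "pre": pre, "post": post}
            )
    return pd.DataFrame(rows), profiles
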