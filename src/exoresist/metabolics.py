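"""Steady-state detection and metabolic energy computation for
breath-by-breath indirect calorimetry.

A windowed Kendall tau-b trend test classifies each point of a metabolic
power trace as rising, falling or stable: within each sliding window the
rank correlation of power against time is tested against the null of no
monotone trend, and a point is steady when its window shows no significant
trend (a stricter every-covering-window rule is available). Metabolic power is obtained per breath from
gas-exchange rates with the standard indirect-calorimetry energy
equivalents (16.58 kJ per litre O2 consumed and 4.51 kJ per litre CO2
produced), averaged over the selected steady-state window, net of quiet
standing, and normalised by body mass and speed to a cost of transport in
J/(kg*m).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import BreathSeries
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "KendallResult",
    "kendall_tau_b",
    "SteadyStateResult",
    "classify_steady_state",
    "SteadyStateClassifier",
    "brockway_power",
    "net_metabolic_power",
    "cost_of_transport",
    "MetabolicSummary",
    "analyze_metabolic_pair",
]

# Energy equivalents, kJ per litre of gas exchanged.
KJ_PER_L_O2 = 16.58
KJ_PER_L_CO2 = 4.51

#: Largest n for which the permutation null of tau-b is enumerated exactly.
EXACT_N_MAX = 8


class KendallResult(NamedTuple):
    tau: float
    p: float
    degenerate: bool = False


def _pair_counts(x: np.ndarray, t: np.ndarray):
    """Concordant-minus-discordant sum S and tie corrections for tau-b."""
    dx = np.sign(x[:, None] - x[None, :])
    dt = np.sign(t[:, None] - t[None, :])
    iu = np.triu_indices(x.size, k=1)
    s = float(np.sum(dx[iu] * dt[iu]))
    # tie-group sizes in each variable
    _, cx = np.unique(x, return_counts=True)
    _, ct = np.unique(t, return_counts=True)
    return s, cx, ct


def _tau_b_from_counts(s: float, n: int, cx: np.ndarray, ct: np.ndarray) -> float:
    n0 = n * (n - 1) / 2.0
    n1 = float(np.sum(cx * (cx - 1) / 2.0))
    n2 = float(np.sum(ct * (ct - 1) / 2.0))
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    return s / denom


def kendall_tau_b(x, t) -> KendallResult:
    """Kendall's tau-b of ``x`` against ``t`` with tie corrections.

    The two-sided p-value uses the tie-adjusted normal approximation of the
    S statistic; for n <= 8 the permutation null is enumerated exactly
    instead. When either variable is entirely tied tau is undefined: the
    result is (tau=0, p=1) with ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.size != t.size:
        raise ValidationError("x and t must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("kendall_tau_b needs n >= 3")

    s, cx, ct = _pair_counts(x, t)
    n0 = n * (n - 1) / 2.0
    n1 = float(np.sum(cx * (cx - 1) / 2.0))
    n2 = float(np.sum(ct * (ct - 1) / 2.0))
    if n1 >= n0 or n2 >= n0:  # one variable constant
        return KendallResult(tau=0.0, p=1.0, degenerate=True)
    tau = _tau_b_from_counts(s, n, cx, ct)

    if n <= EXACT_N_MAX:
        p = _exact_perm_p(x, t, abs(tau))
    else:
        # tie-adjusted variance of S (normal approximation)
        v0 = n * (n - 1) * (2 * n + 5)
        vt = float(np.sum(cx * (cx - 1) * (2 * cx + 5)))
        vu = float(np.sum(ct * (ct - 1) * (2 * ct + 5)))
        st1 = float(np.sum(cx * (cx - 1)))
        su1 = float(np.sum(ct * (ct - 1)))
        st2 = float(np.sum(cx * (cx - 1) * (cx - 2)))
        su2 = float(np.sum(ct * (ct - 1) * (ct - 2)))
        var_s = (
            (v0 - vt - vu) / 18.0
            + st1 * su1 / (2.0 * n * (n - 1))
            + st2 * su2 / (9.0 * n * (n - 1) * (n - 2))
        )
        if var_s <= 0:
            return KendallResult(tau=tau, p=1.0, degenerate=True)
        z = s / np.sqrt(var_s)
        p = 2.0 * stats.norm.sf(abs(z))
    return KendallResult(tau=float(tau), p=float(min(p, 1.0)), degenerate=False)


def _exact_perm_p(x: np.ndarray, t: np.ndarray, abs_tau: float) -> float:
    """Two-sided permutation p-value of tau-b by full enumeration.

    All n! arrangements of x against the fixed t are enumerated (duplicate
    arrangements of tied values carry their natural multiplicity), and the
    batch of S statistics is evaluated vectorised over the pair index.
    """
    n = x.size
    dx = np.sign(x[:, None] - x[None, :])
    dt = np.sign(t[:, None] - t[None, :])
    _, cx = np.unique(x, return_counts=True)
    _, ct = np.unique(t, return_counts=True)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    s = np.zeros(perms.shape[0])
    for i in range(n - 1):
        for j in range(i + 1, n):
            if dt[i, j] != 0:
                s += dx[perms[:, i], perms[:, j]] * dt[i, j]
    taus = np.abs(_tau_b_from_counts(s, n, cx, ct))
    return float(np.mean(taus >= abs_tau - 1e-12))


# ---------------------------------------------------------------------------
# Steady-state classification

LABELS = ("rising", "falling", "stable")


@dataclass
class SteadyStateResult:
    """Per-point trend labels and selected steady-state windows."""

    labels: np.ndarray  # str array, one of LABELS per point
    steady: np.ndarray  # bool mask: point is steady
    windows: list[tuple[int, int]]  # maximal steady runs, half-open indices
    window_means: list[float]  # mean of the trace over each window
    window_label: np.ndarray  # per sliding window (n - w + 1) labels
    params: dict

    def best_window(self) -> tuple[int, int]:
        """Longest steady window; ties broken toward the latest."""
        if not self.windows:
            raise InsufficientDataError("no steady-state window found")
        lengths = [b - a for a, b in self.windows]
        best = max(range(len(self.windows)), key=lambda i: (lengths[i], i))
        return self.windows[best]

    def best_window_mean(self) -> float:
        a, b = self.best_window()
        return self.window_means[self.windows.index((a, b))]


def classify_steady_state(
    values: np.ndarray,
    time: np.ndarray | None = None,
    *,
    window: int = 20,
    alpha: float = 0.05,
    rule: str = "centered",
) -> SteadyStateResult:
    """Label each point of a trace rising / falling / stable by windowed
    Kendall tau-b against time, and extract steady-state windows.

    Within every length-``window`` sliding window the trend of the trace
    against time is tested; a significant positive (negative) tau marks the
    window rising (falling). Under ``rule='centered'`` (default) a point is
    classified by the window centred on it — the usual windowed-trend point
    label; ``rule='all'`` additionally demands that every window covering
    the point is stable, a conservative variant that can return no steady
    window at realistic noise levels because a single false-positive trend
    window vetoes its whole neighbourhood. Steady windows are the maximal
    runs of steady points at least ``window`` long.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if window < 5:
        raise ValidationError("window must be >= 5 breaths")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    if rule not in ("all", "centered"):
        raise ValidationError("rule must be 'all' or 'centered'")
    if n < window:
        raise InsufficientDataError(
            f"series of {n} points is shorter than window={window}"
        )
    if time is None:
        time = np.arange(n, dtype=float)
    else:
        time = np.asarray(time, dtype=float)
        if time.size != n:
            raise ValidationError("time and values must have equal length")

    n_win = n - window + 1
    win_label = np.empty(n_win, dtype=object)
    for i in range(n_win):
        res = kendall_tau_b(values[i : i + window], time[i : i + window])
        if res.p < alpha and res.tau > 0:
            win_label[i] = "rising"
        elif res.p < alpha and res.tau < 0:
            win_label[i] = "falling"
        else:
            win_label[i] = "stable"

    labels = np.empty(n, dtype=object)
    steady = np.zeros(n, dtype=bool)
    for k in range(n):
        if rule == "centered":
            c = int(np.clip(k - window // 2, 0, n_win - 1))
            covering = win_label[c : c + 1]
        else:
            lo = max(0, k - window + 1)
            hi = min(n_win - 1, k)
            covering = win_label[lo : hi + 1]
        n_rise = int(np.sum(covering == "rising"))
        n_fall = int(np.sum(covering == "falling"))
        if n_rise == 0 and n_fall == 0:
            labels[k] = "stable"
            steady[k] = True
        elif n_rise >= n_fall:
            labels[k] = "rising"
        else:
            labels[k] = "falling"

    # maximal steady runs of length >= window
    windows: list[tuple[int, int]] = []
    means: list[float] = []
    padded = np.concatenate(([False], steady, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for a, b in zip(edges[0::2], edges[1::2]):
        if b - a >= window:
            windows.append((int(a), int(b)))
            means.append(float(np.mean(values[a:b])))
    return SteadyStateResult(
        labels=labels,
        steady=steady,
        windows=windows,
        window_means=means,
        window_label=win_label,
        params={"window": window, "alpha": alpha, "rule": rule},
    )


class SteadyStateClassifier(BaseEstimator):
    """Scikit-learn-style interface to windowed tau-b steady-state labelling.

    ``fit(values)`` computes per-point labels; fitted attributes are
    ``labels_``, ``steady_``, ``windows_`` and ``result_``. ``fit_predict``
    returns the label array, clustering-style.

    Parameters
    ----------
    window : int
        Sliding-window length in breaths (default 20).
    alpha : float
        Significance level of the per-window trend test (default 0.05).
    rule : {"all", "centered"}
        Whether a point must be stable in every covering window or only in
        its centred window.
    median_filter : int
        Odd width of an optional median prefilter on the trace; 0 or 1
        disables it (default 0 — breath-by-breath values are used raw).
    """

    def __init__(
        self,
        window: int = 20,
        alpha: float = 0.05,
        rule: str = "centered",
        median_filter: int = 0,
    ):
        self.window = window
        self.alpha = alpha
        self.rule = rule
        self.median_filter = median_filter

    def _prep(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.median_filter and self.median_filter > 1:
            from scipy.signal import medfilt

            values = medfilt(values, kernel_size=int(self.median_filter) | 1)
        return values

    def fit(self, values, time=None) -> "SteadyStateClassifier":
        self.result_ = classify_steady_state(
            self._prep(values),
            time,
            window=self.window,
            alpha=self.alpha,
            rule=self.rule,
        )
        self.labels_ = self.result_.labels
        self.steady_ = self.result_.steady
        self.windows_ = self.result_.windows
        return self

    def fit_predict(self, values, time=None) -> np.ndarray:
        return self.fit(values, time).labels_


# ---------------------------------------------------------------------------
# Energy expenditure


def brockway_power(vo2, vco2):
    """Metabolic power (W) from V̇O2 and V̇CO2 in ml/min.

    Uses 16.58 kJ/L O2 and 4.51 kJ/L CO2; ml/min -> L/s conversion is
    internal, so 1000 ml/min of O2 alone is 16.58 kJ/min = 276.33 W.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValidationError("gas-exchange rates must be >= 0")
    power = (KJ_PER_L_O2 * vo2 + KJ_PER_L_CO2 * vco2) / 60.0  # ml/min*kJ/L -> W
    return float(power) if power.ndim == 0 else power


def net_metabolic_power(walk_power: float, stand_power: float) -> float:
    """Walking power net of quiet standing, W. Negative results are allowed
    but flagged with a warning."""
    net = float(walk_power) - float(stand_power)
    if net < 0:
        warnings.warn(
            f"net metabolic power is negative ({net:.1f} W); "
            "check steady-state selection",
            stacklevel=2,
        )
    return net


def cost_of_transport(net_power: float, body_mass: float, speed: float) -> float:
    """Mass- and speed-normalised energy per unit distance, J/(kg*m)."""
    if body_mass <= 0:
        raise ValidationError("body_mass must be > 0")
    if speed <= 0:
        raise ValidationError("speed must be > 0")
    return float(net_power) / (body_mass * speed)


@dataclass
class MetabolicSummary:
    """End-to-end result of the walk/stand metabolic pipeline."""

    walk_power_w: float
    stand_power_w: float
    net_power_w: float
    cot_jkgm: float
    walk_window_s: tuple[float, float]
    stand_window_s: tuple[float, float]
    params: dict


def analyze_metabolic_pair(
    walk: BreathSeries,
    stand: BreathSeries,
    body_mass: float,
    speed: float,
    *,
    window: int = 20,
    alpha: float = 0.05,
    rule: str = "centered",
) -> MetabolicSummary:
    """Full pipeline: per-breath power, steady-state selection on walking
    and standing, net power and cost of transport.

    The mean power of the longest (ties -> latest) steady window of each
    activity enters the net subtraction.
    """
    if walk.activity != "walk" or stand.activity != "stand":
        raise ValidationError(
            "expected a 'walk' and a 'stand' series, got "
            f"{walk.activity!r} and {stand.activity!r}"
        )
    powers = {}
    spans = {}
    for series in (walk, stand):
        power = brockway_power(series.vo2, series.vco2)
        res = classify_steady_state(
            power, series.time, window=window, alpha=alpha, rule=rule
        )
        a, b = res.best_window()
        powers[series.activity] = float(np.mean(power[a:b]))
        spans[series.activity] = (float(series.time[a]), float(series.time[b - 1]))
    net = net_metabolic_power(powers["walk"], powers["stand"])
    return MetabolicSummary(
        walk_power_w=powers["walk"],
        stand_power_w=powers["stand"],
        net_power_w=net,
        cot_jkgm=cost_of_transport(net, body_mass, speed),
        walk_window_s=spans["walk"],
        stand_window_s=spans["stand"],
        params={"window": window, "alpha": alpha, "rule": rule},
    )
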