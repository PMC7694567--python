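"""Pre/post statistical battery for the five trial outcome measures.

Per measure: 1.5 x IQR outlier screening (pre and post separately, listwise
removal), a Monte-Carlo Lilliefors normality check (reported, not gating),
a two-tailed paired t-test, step-down Holm-Bonferroni adjustment across the
measure family, Cohen's d effect size, and percent change summarised as the
mean +/- SD of per-participant percent changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import MEASURE_UNITS, MEASURES, validate_outcome_table
from .errors import ValidationError

__all__ = [
    "average_mvc",
    "iqr_outliers",
    "lilliefors_normality",
    "paired_t",
    "holm_bonferroni",
    "cohens_d",
    "StatResult",
    "analyze_trial",
    "TrialAnalyzer",
]


def average_mvc(left_n: list[float], right_n: list[float], body_mass: float) -> float:
    """Body-mass-normalised plantar-flexor strength (N/kg).

    Per limb, the mean of (nominally three) maximum-voluntary-contraction
    trials; limb means are averaged and divided by body mass. Fewer or more
    than three trials per limb triggers a protocol warning but the value is
    still computed on what is available.
    """
    if body_mass <= 0:
        raise ValidationError("body_mass must be > 0")
    left = np.asarray(left_n, dtype=float)
    right = np.asarray(right_n, dtype=float)
    if left.size == 0 or right.size == 0:
        raise ValidationError("each limb needs at least one MVC trial")
    if left.size != 3 or right.size != 3:
        warnings.warn(
            "MVC protocol expects exactly 3 trials per limb; computing on "
            f"{left.size}/{right.size}",
            stacklevel=2,
        )
    return float((left.mean() + right.mean()) / 2.0 / body_mass)


def iqr_outliers(values, k: float = 1.5) -> tuple[np.ndarray, tuple[float, float]]:
    """1.5 x IQR fence outlier mask with the fences used.

    Quartiles use linear interpolation between order statistics (numpy's
    default), a convention fixed here for reproducibility. For n < 4 no
    screening is performed (empty mask, NaN fences) with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("n < 4: outlier screening skipped", stacklevel=2)
        return np.zeros(values.size, dtype=bool), (np.nan, np.nan)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return (values < lo) | (values > hi), (float(lo), float(hi))


@lru_cache(maxsize=64)
def _lilliefors_null(n: int, n_sims: int, seed: int) -> np.ndarray:
    """Simulated null distribution of the Lilliefors KS statistic for
    sample size n (standard-normal draws, parameters re-estimated)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97, n]))
    samples = rng.standard_normal((n_sims, n))
    samples.sort(axis=1)
    means = samples.mean(axis=1, keepdims=True)
    sds = samples.std(axis=1, ddof=1, keepdims=True)
    z = (samples - means) / sds
    cdf = stats.norm.cdf(z)
    grid = (np.arange(1, n + 1)) / n
    d_plus = np.max(grid - cdf, axis=1)
    d_minus = np.max(cdf - (np.arange(n)) / n, axis=1)
    return np.maximum(d_plus, d_minus)


def lilliefors_statistic(values: np.ndarray) -> float:
    """KS distance of the sample from a normal with estimated mean/SD."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = stats.norm.cdf(z)
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(n) / n)
    return float(max(d_plus, d_minus))


def lilliefors_normality(
    values, n_sims: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with the small-sample Lilliefors
    correction, p-value by seeded Monte-Carlo simulation of the null.

    Returns ``(statistic, p)``. The null distribution is cached per sample
    size, so repeated calls at the same n are cheap. A zero-variance sample
    is degenerate: returns p = 0 with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValidationError("lilliefors_normality needs n >= 4")
    if np.ptp(values) == 0:
        warnings.warn("zero-variance sample: normality degenerate", stacklevel=2)
        return np.inf, 0.0
    d = lilliefors_statistic(values)
    null = _lilliefors_null(values.size, n_sims, seed)
    p = (np.sum(null >= d) + 1.0) / (null.size + 1.0)
    return d, float(p)


def paired_t(pre, post) -> tuple[float, float, int]:
    """Two-tailed paired t-test on post - pre differences.

    Returns ``(t, p, df)`` with df = n - 1. Constant nonzero differences
    give infinite t with p = 0 (flagged by warning); identically zero
    differences give t = 0, p = 1.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValidationError("pre and post must have equal length")
    n = pre.size
    if n < 2:
        raise ValidationError("paired_t needs n >= 2")
    diff = post - pre
    df = n - 1
    if np.std(diff, ddof=1) == 0.0:
        if np.all(diff == 0):
            return 0.0, 1.0, df
        warnings.warn("zero-variance differences: t is infinite", stacklevel=2)
        return float(np.sign(diff.mean()) * np.inf), 0.0, df
    res = stats.ttest_rel(post, pre)
    return float(res.statistic), float(res.pvalue), df


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm-Bonferroni adjusted p-values, in input order.

    Sorted ascending, adjusted_i = max_{j<=i} (m - j + 1) * p_(j), capped
    at 1 — the classical family-wise-error-controlling step-down scheme.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def cohens_d(pre, post, variant: str = "dz") -> float:
    """Paired effect size; sign follows post - pre.

    ``dz`` divides the mean difference by the SD of the differences;
    ``dav`` divides by the mean of the pre and post SDs. A zero denominator
    yields NaN with a warning.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size or pre.size < 2:
        raise ValidationError("cohens_d needs paired samples with n >= 2")
    diff = post - pre
    if np.all(diff == 0):
        return 0.0  # no change at all: zero effect by convention
    if variant == "dz":
        denom = np.std(diff, ddof=1)
    elif variant == "dav":
        denom = 0.5 * (np.std(pre, ddof=1) + np.std(post, ddof=1))
    else:
        raise ValidationError("variant must be 'dz' or 'dav'")
    if denom == 0:
        warnings.warn("zero-variance denominator: d undefined", stacklevel=2)
        return float("nan")
    return float(diff.mean() / denom)


@dataclass
class StatResult:
    """Per-measure summary emitted by the trial battery."""

    measure: str
    n_used: int
    mean_pre: float
    mean_post: float
    pct_change_mean: float
    pct_change_sd: float
    t: float
    p_raw: float
    p_adjusted: float
    d: float
    normality_p_pre: float
    normality_p_post: float
    outliers_removed: list[str] = field(default_factory=list)
    note: str = ""


def analyze_trial(
    table: pd.DataFrame,
    alpha: float = 0.05,
    d_variant: str = "dz",
    *,
    iqr_k: float = 1.5,
    lilliefors_sims: int = 10_000,
    seed: int = 0,
) -> list[StatResult]:
    """Run the full statistical battery on a tidy pre/post outcome table.

    Per measure: rows with missing pre or post are dropped (listwise);
    outlier screening is applied to pre and post values separately and a
    flagged participant is removed from that measure; normality of the
    remaining pre and post values is reported; a two-tailed paired t-test
    and Cohen's d are computed; Holm-Bonferroni adjusts the raw p-values
    across all analysed measures. Percent change is the mean +/- SD over
    participants of (post - pre) / pre. Measures with fewer than two
    complete pairs after screening are skipped with a note.
    """
    table = validate_outcome_table(table)
    results: list[StatResult] = []
    raw_ps: list[float] = []
    for measure in MEASURES:
        sub = table[table["measure"] == measure].dropna(subset=["pre", "post"])
        if len(sub) == 0:
            continue
        outliers: list[str] = []
        if len(sub) >= 4:
            for col in ("pre", "post"):
                mask, _ = iqr_outliers(sub[col].to_numpy(), k=iqr_k)
                outliers.extend(sub.loc[mask, "participant"].tolist())
        outliers = sorted(set(outliers))
        kept = sub[~sub["participant"].isin(outliers)]
        if len(kept) < 2:
            results.append(
                StatResult(
                    measure=measure,
                    n_used=len(kept),
                    mean_pre=np.nan,
                    mean_post=np.nan,
                    pct_change_mean=np.nan,
                    pct_change_sd=np.nan,
                    t=np.nan,
                    p_raw=np.nan,
                    p_adjusted=np.nan,
                    d=np.nan,
                    normality_p_pre=np.nan,
                    normality_p_post=np.nan,
                    outliers_removed=outliers,
                    note="skipped: fewer than 2 complete pairs",
                )
            )
            continue
        pre = kept["pre"].to_numpy()
        post = kept["post"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(kept) >= 4:
                _, p_norm_pre = lilliefors_normality(
                    pre, n_sims=lilliefors_sims, seed=seed
                )
                _, p_norm_post = lilliefors_normality(
                    post, n_sims=lilliefors_sims, seed=seed
                )
            else:
                p_norm_pre = p_norm_post = np.nan
            t, p, _ = paired_t(pre, post)
            d = cohens_d(pre, post, variant=d_variant)
        pct = (post - pre) / pre
        results.append(
            StatResult(
                measure=measure,
                n_used=len(kept),
                mean_pre=float(pre.mean()),
                mean_post=float(post.mean()),
                pct_change_mean=float(pct.mean()),
                pct_change_sd=float(pct.std(ddof=1)),
                t=t,
                p_raw=p,
                p_adjusted=np.nan,
                d=d,
                normality_p_pre=float(p_norm_pre),
                normality_p_post=float(p_norm_post),
                outliers_removed=outliers,
            )
        )
        raw_ps.append(p)
    analysed = [r for r in results if not r.note]
    if raw_ps:
        adj = holm_bonferroni(raw_ps)
        for r, a in zip(analysed, adj):
            r.p_adjusted = float(a)
    return results


def results_frame(results: list[StatResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = r.__dict__.copy()
        row["outliers_removed"] = ";".join(row["outliers_removed"])
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(results: list[StatResult], alpha: float = 0.05) -> str:
    """Plain-text outcome report: one line per measure, pre/post means,
    percent change mean +/- SD, raw and adjusted p, effect size."""
    lines = [
        f"{'measure':<8}{'unit':<10}{'n':>3}{'pre':>10}{'post':>10}"
        f"{'% change':>16}{'p':>8}{'p_adj':>8}{'d':>8}"
    ]
    for r in results:
        if r.note:
            lines.append(f"{r.measure:<8}-- {r.note}")
            continue
        star = "*" if r.p_adjusted < alpha else " "
        lines.append(
            f"{r.measure:<8}{MEASURE_UNITS[r.measure]:<10}{r.n_used:>3}"
            f"{r.mean_pre:>10.3f}{r.mean_post:>10.3f}"
            f"{100 * r.pct_change_mean:>+8.1f} +/- {100 * r.pct_change_sd:<4.1f}"
            f"{r.p_raw:>8.3f}{r.p_adjusted:>7.3f}{star}{r.d:>8.2f}"
        )
        if r.outliers_removed:
            lines.append(f"         outliers removed: {', '.join(r.outliers_removed)}")
    return "\n".join(lines)


class TrialAnalyzer(BaseEstimator):
    """Estimator-style wrapper around :func:`analyze_trial`.

    ``fit(table)`` runs the battery; fitted attributes are ``results_``
    (list of :class:`StatResult`), ``frame_`` (tidy DataFrame) and
    ``report_`` (formatted text).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        d_variant: str = "dz",
        iqr_k: float = 1.5,
        lilliefors_sims: int = 10_000,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.d_variant = d_variant
        self.iqr_k = iqr_k
        self.lilliefors_sims = lilliefors_sims
        self.random_state = random_state

    def fit(self, table: pd.DataFrame, y=None) -> "TrialAnalyzer":
        self.results_ = analyze_trial(
            table,
            alpha=self.alpha,
            d_variant=self.d_variant,
            iqr_k=self.iqr_k,
            lilliefors_sims=self.lilliefors_sims,
            seed=self.random_state,
        )
        self.frame_ = results_frame(self.results_)
        self.report_ = format_report(self.results_, alpha=self.alpha)
        return self
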