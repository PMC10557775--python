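"""Fixed-period single-component cosinor regression and group statistics.

The cosinor model for a series sampled at times :math:`t_i` (hours) is

.. math::  y_i = M + A\\cos(\\omega (t_i - \\phi)) + \\varepsilon_i,
           \\qquad \\omega = 2\\pi/\\tau,

fit by ordinary least squares in the linear basis
:math:`y = M + \\beta\\cos(\\omega t) + \\gamma\\sin(\\omega t)`, from which
the amplitude :math:`A = \\sqrt{\\beta^2+\\gamma^2}` and the acrophase (peak
hour) :math:`\\phi = \\operatorname{atan2}(\\gamma, \\beta)/\\omega \\bmod
\\tau` follow.  Rhythmicity is tested with the F-test of the joint null
:math:`\\beta=\\gamma=0`.

Also provided: aggregation of raw wearable streams into time bins, the
exact two-sided Wilcoxon rank-sum test, and a bootstrap two-sample Kuiper
test for circular phase comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CosinorFit",
    "cosinor_fit",
    "aggregate_bins",
    "RankSumResult",
    "ranksum_exact",
    "KuiperResult",
    "kuiper_two_sample",
    "wrap_signed",
]


def wrap_signed(delta: np.ndarray | float, period: float = 24.0):
    """Wrap an hour difference to the signed interval (-period/2, period/2]."""
    r = np.mod(delta, period)
    return np.where(r > period / 2, r - period, r) if np.ndim(r) else (r - period if r > period / 2 else r)


@dataclass(frozen=True)
class CosinorFit:
    """Least-squares cosinor estimates for one series."""

    mesor: float
    amplitude: float
    peak_hour: float
    beta: float
    gamma: float
    residual_sd: float
    p_rhythm: float
    n_obs: int
    period: float = 24.0


def cosinor_design(times: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi / period
    return np.column_stack([np.ones_like(times), np.cos(w * times), np.sin(w * times)])


def cosinor_fit(times, values, period: float = 24.0) -> CosinorFit:
    """Fit a fixed-period cosinor by OLS.

    Requires at least 4 observations at >= 3 distinct times modulo the
    period.  A zero-variance series returns a flat fit (A = 0, p = 1).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    n = len(t)
    if n < 4:
        raise ValueError(f"cosinor fit needs >= 4 observations, got {n}")
    distinct = np.unique(np.round(np.mod(t, period), 9))
    if len(distinct) < 3:
        raise ValueError(
            "degenerate design: fewer than 3 distinct times modulo the period"
        )
    if np.ptp(y) == 0.0:
        return CosinorFit(
            mesor=float(y[0]), amplitude=0.0, peak_hour=0.0, beta=0.0, gamma=0.0,
            residual_sd=0.0, p_rhythm=1.0, n_obs=n, period=period,
        )
    X = cosinor_design(t, period)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = (float(c) for c in coef)
    resid = y - X @ coef
    sse1 = float(resid @ resid)
    sse0 = float(np.sum((y - y.mean()) ** 2))
    df = n - 3
    if sse1 <= 1e-30 * max(sse0, 1.0):
        p = 0.0
        residual_sd = 0.0
        sse1 = 0.0
    else:
        F = ((sse0 - sse1) / 2.0) / (sse1 / df)
        p = float(stats.f.sf(F, 2, df))
        residual_sd = float(np.sqrt(sse1 / df))
    w = 2.0 * np.pi / period
    amplitude = float(np.hypot(beta, gamma))
    peak = float(np.mod(np.arctan2(gamma, beta) / w, period))
    return CosinorFit(
        mesor=mesor, amplitude=amplitude, peak_hour=peak, beta=beta, gamma=gamma,
        residual_sd=residual_sd, p_rhythm=p, n_obs=n, period=period,
    )


def aggregate_bins(timestamps, values, bin_minutes: int = 1, reducer="sum"):
    """Aggregate an irregular stream into fixed time bins.

    ``timestamps`` are hours since an arbitrary origin.  Returns bin-midpoint
    times (hours) and the reduced value per non-empty bin, in time order.
    ``reducer`` is ``"sum"`` (activity counts), ``"mean"`` (HR/RR), or any
    callable accepted by pandas groupby-aggregate.
    """
    if bin_minutes <= 0:
        raise ValueError("bin_minutes must be positive")
    t = np.asarray(timestamps, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) == 0:
        return np.array([]), np.array([])
    bins = np.floor(t * 60.0 / bin_minutes).astype(np.int64)
    agg = pd.Series(y).groupby(bins).agg(reducer)
    mid = (agg.index.to_numpy() + 0.5) * bin_minutes / 60.0
    return mid, agg.to_numpy(dtype=float)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    p: float
    method: str  # "exact" | "normal-approx" | "degenerate"


def ranksum_exact(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact p by enumeration of the null distribution when there are no ties
    and min(n, m) <= 10; tie-corrected normal approximation (with continuity
    correction) otherwise.  The branch taken is recorded in ``method``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        return RankSumResult(statistic=len(x) * len(y) / 2.0, p=1.0, method="degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and min(len(x), len(y)) <= 10:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankSumResult(statistic=float(res.statistic), p=float(res.pvalue), method="exact")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return RankSumResult(statistic=float(res.statistic), p=float(res.pvalue), method="normal-approx")


@dataclass(frozen=True)
class KuiperResult:
    statistic: float  # V = D+ + D-
    p: float
    n_boot: int


def _kuiper_v_from_labels(labels: np.ndarray, n: int, m: int, last: np.ndarray) -> np.ndarray:
    """V for each row of ``labels`` (1 = first sample), aligned to the sorted
    pooled values; ``last`` marks the final position of each distinct value."""
    cf = np.cumsum(labels, axis=-1) / n
    cg = np.cumsum(1.0 - labels, axis=-1) / m
    d = (cf - cg)[..., last]
    # the last position always contributes d = 0, so max >= 0 and min <= 0
    return d.max(axis=-1) - d.min(axis=-1)


def kuiper_statistic(x, y, period: float = 24.0) -> float:
    """Rotation-invariant two-sample Kuiper statistic V = D+ + D- on values
    reduced modulo the period."""
    x = np.mod(np.asarray(x, dtype=float), period)
    y = np.mod(np.asarray(y, dtype=float), period)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="stable")
    sv = pooled[order]
    last = np.r_[sv[1:] != sv[:-1], True]
    labels = (order < n).astype(float)
    return float(_kuiper_v_from_labels(labels, n, m, last))


def kuiper_two_sample(x, y, period: float = 24.0, n_boot: int = 10000, seed=None) -> KuiperResult:
    """Two-sample Kuiper test for circular data with a permutation p-value.

    V is the Kuiper statistic on the pooled empirical CDFs of the samples
    reduced modulo the period; p is estimated from ``n_boot`` random
    relabelings of the pooled sample (sizes preserved) with the +1
    continuity correction (b+1)/(n_boot+1), reproducible under ``seed``.
    """
    x = np.mod(np.asarray(x, dtype=float), period)
    y = np.mod(np.asarray(y, dtype=float), period)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="stable")
    sv = pooled[order]
    last = np.r_[sv[1:] != sv[:-1], True]
    labels = (order < n).astype(float)
    v_obs = float(_kuiper_v_from_labels(labels, n, m, last))
    rng = np.random.default_rng(seed)
    base = np.zeros(n + m)
    base[:n] = 1.0
    perms = rng.permuted(np.tile(base, (n_boot, 1)), axis=1)
    v_boot = _kuiper_v_from_labels(perms, n, m, last)
    b = int(np.count_nonzero(v_boot >= v_obs - 1e-12))
    p = (b + 1) / (n_boot + 1)
    return KuiperResult(statistic=v_obs, p=float(p), n_boot=n_boot)
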