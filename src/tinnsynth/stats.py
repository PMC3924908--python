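"""Paired-comparison statistics for the two-method tinnitus study.

The pipeline mirrors how paired audiometer-vs-synthesizer outcomes are
evaluated: Shapiro-Wilk normality screening of each column at α = 0.05,
then — because the synthesizer columns are non-normal — the Wilcoxon
signed-rank test on the pairs, with the exact conventions of the source
analysis software:

* zero differences are dropped ("if two scores are the same the pair is
  ignored"); tied absolute differences receive mid-ranks;
* T is the smaller of the positive/negative rank sums;
* Z = (μ_T − T)/σ_T with μ_T = n(n+1)/4 and σ_T = √(n(n+1)(2n+1)/24),
  with **no** continuity correction and **no** tie-variance correction
  (only this convention reproduces the published Z values);
* the two-sided p comes from the normal tail;
* the effect size is r = Z/√(n₁+n₂) with n₁+n₂ the total observation count
  of both columns (not the post-zero-removal pair count).

An exact enumeration of all sign assignments (:func:`wilcoxon_exact_p`)
serves as the oracle for the normal approximation at small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

ALPHA = 0.05


@dataclass(frozen=True)
class PairedSample:
    """Two paired measurement columns (same variable, two conditions)."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    ids: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.x) != len(self.y):
            raise ValueError("paired columns must have equal length")
        if len(self.x) < 5:
            raise ValueError("need at least 5 pairs")
        if not all(map(math.isfinite, (*self.x, *self.y))):
            raise ValueError("paired values must be finite")
        if self.ids and len(self.ids) != len(self.x):
            raise ValueError("ids must match the number of pairs")


@dataclass(frozen=True)
class WilcoxonResult:
    T: float
    Z: float
    p_two_sided: float
    r: float
    n_effective: int
    n_total: int


@dataclass(frozen=True)
class ShapiroResult:
    W: float
    p_value: float


@dataclass(frozen=True)
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


def _signed_ranks(sample: PairedSample) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(sample.x, dtype=float) - np.asarray(sample.y, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError(
            "all pairwise differences are zero: the sample carries no "
            "information about a difference between conditions"
        )
    ranks = _sps.rankdata(np.abs(d))  # mid-ranks for ties
    return d, ranks


def wilcoxon_signed_rank(sample: PairedSample) -> WilcoxonResult:
    """Wilcoxon signed-rank test with normal approximation (see module doc)."""
    d, ranks = _signed_ranks(sample)
    t_pos = float(ranks[d > 0].sum())
    t_neg = float(ranks[d < 0].sum())
    T = min(t_pos, t_neg)
    n = d.size
    mu = n * (n + 1) / 4.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    Z = (mu - T) / sigma
    p = 2.0 * float(_sps.norm.sf(Z))
    n_total = len(sample.x) + len(sample.y)
    return WilcoxonResult(
        T=T,
        Z=Z,
        p_two_sided=min(1.0, p),
        r=Z / math.sqrt(n_total),
        n_effective=n,
        n_total=n_total,
    )


def wilcoxon_exact_p(sample: PairedSample, two_sided: bool = True) -> float:
    """Exact permutation p by full enumeration of sign assignments.

    Enumerates all 2^n assignments of signs to the observed (mid-)ranks and
    computes the tail probability of a positive-rank sum at least as extreme
    as observed.  Oracle for the normal approximation; limited to n ≤ 20.
    """
    d, ranks = _signed_ranks(sample)
    n = d.size
    if n > 20:
        raise ValueError(f"exact enumeration limited to n ≤ 20 (got {n})")
    T = min(float(ranks[d > 0].sum()), float(ranks[d < 0].sum()))
    total = float(ranks.sum())
    count = 0
    for signs in itertools.product((0.0, 1.0), repeat=n):
        s = float(np.dot(signs, ranks))
        if s <= T + 1e-9:
            count += 1
    p_low = count / 2.0**n
    if not two_sided:
        return p_low
    # the sign-assignment distribution is symmetric about total/2
    return min(1.0, 2.0 * p_low)


def shapiro_wilk(values: Sequence[float]) -> ShapiroResult:
    """Shapiro-Wilk W and p (Royston's approximation, via scipy)."""
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 ≤ n ≤ 5000")
    if np.ptp(arr) == 0.0:
        raise ValueError("constant input has zero variance; W is undefined")
    W, p = _sps.shapiro(arr)
    return ShapiroResult(W=float(W), p_value=float(p))


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Median, median-exclusive quartiles, whiskers at the extremes."""
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("need at least one value")

    def _median(a: np.ndarray) -> float:
        m = a.size
        mid = m // 2
        return float(a[mid]) if m % 2 else float((a[mid - 1] + a[mid]) / 2.0)

    half = n // 2
    lower = arr[:half] if half else arr
    upper = arr[-half:] if half else arr
    return BoxSummary(
        median=_median(arr),
        q1=_median(lower),
        q3=_median(upper),
        whisker_low=float(arr[0]),
        whisker_high=float(arr[-1]),
    )


def analyze_paired_study(
    columns: dict[str, Sequence[float]],
    pairs: dict[str, tuple[str, str]],
    alpha: float = ALPHA,
) -> dict:
    """Full study report: per-column Shapiro-Wilk and box summaries, plus a
    Wilcoxon signed-rank comparison (with effect size) per named pair.

    ``columns`` maps column name to values; ``pairs`` maps a measure name to
    the (first, second) column names to compare.
    """
    report: dict = {"alpha": alpha, "columns": {}, "comparisons": {}}
    for name, vals in columns.items():
        sw = shapiro_wilk(vals)
        box = box_summary(vals)
        report["columns"][name] = {
            "n": len(list(vals)),
            "shapiro_W": sw.W,
            "shapiro_p": sw.p_value,
            "normal_at_alpha": sw.p_value > alpha,
            "box": box.__dict__,
        }
    for measure, (a, b) in pairs.items():
        sample = PairedSample(x=tuple(columns[a]), y=tuple(columns[b]))
        try:
            res = wilcoxon_signed_rank(sample)
        except ValueError as exc:
            # e.g. identical columns: normality screening above still stands
            report["comparisons"][measure] = {"first": a, "second": b, "error": str(exc)}
            continue
        report["comparisons"][measure] = {
            "first": a,
            "second": b,
            "T": res.T,
            "Z": res.Z,
            "p_two_sided": res.p_two_sided,
            "r": res.r,
            "n_effective": res.n_effective,
            "significant_at_alpha": res.p_two_sided < alpha,
        }
    return report
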