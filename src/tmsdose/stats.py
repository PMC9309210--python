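"""Paired statistics and multiplicity adjustment for the dosing pipeline.

The pipeline's comparisons are paired by participant (the same head is
stimulated at both cortical targets): scalp-to-cortex depths are compared
with a two-sided paired t-test and percent-activated values with the
Wilcoxon signed-rank test.  The Wilcoxon null distribution is enumerated
exactly (dynamic program over signed midranks) for n <= 25 because the
cohort sizes here are small and ties are common after quantization to
whole cells; the normal approximation with tie correction is used beyond
that.  All p-values are two-sided and reported after Bonferroni-Holm
step-down adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedTestResult",
    "paired_t",
    "wilcoxon_signed_rank",
    "holm_adjust",
    "variability_summary",
]


@dataclass(frozen=True)
class PairedTestResult:
    test: str
    statistic: float
    df: int | None
    p_two_sided: float
    n: int


def paired_t(x, y) -> PairedTestResult:
    """Two-sided paired-samples t-test, t = mean(d) / (sd(d)/sqrt(n))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTestResult(test="paired_t", statistic=float(t), df=n - 1,
                            p_two_sided=float(p), n=n)


def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p for the signed-rank sum by enumeration.

    ``ranks2`` are midranks doubled to make them integers; the DP walks
    the distribution of the positive-rank sum over all 2^n sign
    assignments.  p = 2 * min(P(W <= w), P(W >= w)), capped at 1.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    counts /= counts.sum()
    w2i = int(round(w2))
    p_le = counts[: w2i + 1].sum()
    p_ge = counts[w2i:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y, exact_n_max: int = 25) -> PairedTestResult:
    """Paired signed-rank test; W = sum of positive midranks.

    Zero differences are dropped (Wilcoxon's original convention).  Exact
    enumeration for n <= ``exact_n_max``; otherwise a normal approximation
    with tie correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n < 1:
        raise ValueError("all paired differences are zero; W undefined")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_n_max:
        p = _exact_signed_rank_p(np.round(2 * ranks).astype(int), 2 * w_pos)
    else:
        mu = n * (n + 1) / 4.0
        # tie correction on the variance of the rank sum
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_pos - mu) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return PairedTestResult(test="wilcoxon_signed_rank", statistic=w_pos, df=None,
                            p_two_sided=p, n=n)


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, returned in input order."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, j in enumerate(order):
        running = max(running, (m - i) * p[j])
        adj[j] = min(1.0, running)
    return adj


def variability_summary(groups: dict) -> pd.DataFrame:
    """Min / max / mean / sd / range per group (sd absent for n = 1)."""
    rows = []
    for name, vals in groups.items():
        v = np.asarray(vals, float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        rows.append({
            "group": name,
            "n": v.size,
            "min": float(v.min()),
            "max": float(v.max()),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
            "range": float(v.max() - v.min()),
        })
    return pd.DataFrame(rows)
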