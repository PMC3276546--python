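"""Distinguishability, power / false-positive-rate curves, and correlations.

The identification statistic throughout is the lower 95% confidence limit
(LCL) of ln LR.  Given simulated LCL samples for truly related and truly
unrelated pairs, distinguishability

    D = (m_R - m_U)^2 / (s2_R + s2_U)

(sample means and unbiased variances of the finite LCL values) quantifies how
separated the two distributions are; it is analogous to the non-centrality
parameter of the LR test statistic under the alternative.  Power and false
positive rate at a decision threshold t are the fractions of related and
unrelated LCLs strictly above t; -inf (degenerate) LCLs count as below every
threshold and are excluded from the D moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LCLSample",
    "CurvePoint",
    "NotEstimable",
    "distinguishability",
    "power_fpr_curve",
    "pearson_correlation",
    "default_threshold_grid",
]


class NotEstimable(ValueError):
    """A statistic cannot be computed from the given sample (by design)."""


@dataclass
class LCLSample:
    """Finite LCL values for one (relationship, true pop, assumed pop) cell.

    Degenerate -inf LCLs (zero-probability numerator, e.g. parent-offspring
    on non-sharing pairs) are tallied separately: they carry no moment
    information but count as non-detections in power/FPR.
    """

    values: np.ndarray
    n_degenerate: int = 0

    @classmethod
    def from_values(cls, values) -> "LCLSample":
        arr = np.asarray(list(values), dtype=float)
        finite = arr[np.isfinite(arr)]
        n_deg = int(np.sum(np.isneginf(arr)))
        if np.any(np.isposinf(arr)) or np.any(np.isnan(arr)):
            raise ValueError("LCL values must be finite or -inf")
        return cls(values=finite, n_degenerate=n_deg)

    @property
    def n_total(self) -> int:
        return len(self.values) + self.n_degenerate


@dataclass(frozen=True)
class CurvePoint:
    threshold: float
    power: float
    fpr: float


def distinguishability(related: LCLSample, unrelated: LCLSample) -> float:
    """Distinguishability D between related and unrelated LCL samples.

    Raises
    ------
    NotEstimable
        If either sample has fewer than 2 finite values (as for
        parent-offspring hypotheses on unrelated pairs, where nearly every
        ln LR is -inf and the distribution is undefined).
    """
    if len(related.values) < 2 or len(unrelated.values) < 2:
        raise NotEstimable("need >= 2 finite LCL values in each sample")
    m_r, m_u = float(np.mean(related.values)), float(np.mean(unrelated.values))
    v_r = float(np.var(related.values, ddof=1))
    v_u = float(np.var(unrelated.values, ddof=1))
    if v_r + v_u == 0.0:
        raise NotEstimable("both samples have zero variance")
    return (m_r - m_u) ** 2 / (v_r + v_u)


def power_fpr_curve(related: LCLSample, unrelated: LCLSample, thresholds) -> list[CurvePoint]:
    """Empirical power and false-positive-rate over a grid of LCL thresholds.

    A pair is called related when its LCL is strictly above the threshold
    (ties are non-detections); degenerate -inf LCLs fall below every
    threshold.  Both curves are non-increasing in t.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold grid is empty")
    if related.n_total == 0 or unrelated.n_total == 0:
        raise ValueError("both samples must be non-empty")
    rel = np.sort(related.values)
    unr = np.sort(unrelated.values)
    out = []
    for t in thresholds:
        if math.isinf(t) and t < 0:
            power = fpr = 1.0
        else:
            power = float(len(rel) - np.searchsorted(rel, t, side="right")) / related.n_total
            fpr = float(len(unr) - np.searchsorted(unr, t, side="right")) / unrelated.n_total
        out.append(CurvePoint(threshold=float(t), power=power, fpr=fpr))
    return out


def default_threshold_grid(related: LCLSample, unrelated: LCLSample, n_points: int = 101):
    """101 evenly spaced thresholds over the pooled finite LCL range, plus -inf."""
    pooled = np.concatenate([related.values, unrelated.values])
    if len(pooled) == 0:
        return [float("-inf")]
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        grid = [lo]
    else:
        grid = list(np.linspace(lo, hi, n_points))
    return [float("-inf")] + grid


def pearson_correlation(x, y) -> float:
    """Pearson correlation coefficient; raises NotEstimable on zero variance."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise NotEstimable("zero variance in one of the inputs")
    r, _ = stats.pearsonr(x, y)
    return float(r)
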