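"""Small shared statistics helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TrendResult:
    """Two-variable OLS fit with the usual two-sided slope test."""

    slope: float
    intercept: float
    r2: float
    pvalue: float
    n: int

    @property
    def r(self) -> float:
        return float(np.sign(self.slope) * np.sqrt(self.r2))


def linear_trend(x, y) -> TrendResult:
    """OLS of ``y`` on ``x`` (two-sided slope test).

    Raises ``ValueError`` for fewer than two points or a constant ``x``
    (slope undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two points for a trend")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    if np.ptp(y) == 0:
        # flat response: slope exactly 0, nothing explained
        return TrendResult(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    res = stats.linregress(x, y)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        pvalue=float(res.pvalue),
        n=int(x.size),
    )


def sem(values) -> float:
    """Standard error of the mean with ddof=1; NaN for n < 2."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))
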