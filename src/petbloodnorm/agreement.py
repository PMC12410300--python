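"""Scalar agreement statistics between two measurement methods.

Used to compare image-derived blood levels against the ex vivo
gamma-counter reference (and, generically, any paired method
comparison): ordinary linear regression with R² and a parametric 95% CI
on the slope, Bland–Altman bias and limits of agreement, and Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    ci95_slope: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


@dataclass
class BlandAltman:
    """Mean difference (bias), SD of differences, 1.96-SD limits.

    Differences are reference − test, so a positive bias means the test
    method underestimates the reference.
    """

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self) -> None:
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValueError("limits of agreement must bracket the bias")


def _as_arrays(x: Sequence[float], y: Sequence[float], min_n: int):
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if len(xa) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(xa)}")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("inputs contain non-finite values")
    return xa, ya


def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """OLS of y on x with R², two-sided p for slope ≠ 0, and a t-based
    95% CI on the slope (n − 2 dof)."""
    xa, ya = _as_arrays(x, y, min_n=3)
    if np.var(xa) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(xa, ya)
    n = len(xa)
    tq = stats.t.ppf(0.975, n - 2)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        ci95_slope=(float(res.slope - tq * res.stderr), float(res.slope + tq * res.stderr)),
        n=n,
    )


def bland_altman(reference: Sequence[float], test: Sequence[float]) -> BlandAltman:
    """Bland–Altman agreement of a test method against a reference."""
    ra, ta = _as_arrays(reference, test, min_n=2)
    d = ra - ta
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=len(d),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson r, r² and the two-sided p from t = r·sqrt((n−2)/(1−r²))."""
    xa, ya = _as_arrays(x, y, min_n=3)
    if np.var(xa) == 0 or np.var(ya) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(xa, ya)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)
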