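"""Small inferential helpers shared across analyses.

All printed statistics in this package (slopes, t/F values, R^2) are produced
by the functions here so that degrees of freedom and p-values are computed in
one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["StatResult", "ols_slope", "unpaired_t", "one_sample_t"]


@dataclass(frozen=True)
class StatResult:
    """A named test statistic with its effect size and reference distribution.

    Parameters
    ----------
    beta : float
        Effect size: regression slope, mean difference, etc.
    statistic : float
        The t or F value.
    df : int | tuple[int, int]
        Degrees of freedom (a pair for F tests).
    p : float
        Two-sided p-value under the named reference distribution.
    kind : str
        One of ``unpaired_t``, ``paired_t``, ``ols_slope_t``, ``ols_slope_F``.
    r_squared : float, optional
        Coefficient of determination, where a regression was fitted.
    intercept : float, optional
        Regression intercept, where applicable.
    """

    beta: float
    statistic: float
    df: object
    p: float
    kind: str
    r_squared: float | None = None
    intercept: float | None = None
    extras: dict = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if isinstance(self.df, tuple):
            dftxt = f"({self.df[0]},{self.df[1]})"
            name = "F"
        else:
            dftxt = f"({self.df})"
            name = "t"
        parts = [f"beta={self.beta:.3f}", f"{name}{dftxt}={self.statistic:.2f}", f"P={self.p:.3g}"]
        if self.r_squared is not None:
            parts.insert(0, f"R2={self.r_squared:.2f}")
        return ", ".join(parts)


def ols_slope(x, y, statistic: str = "t") -> StatResult:
    """Ordinary least squares of ``y`` on ``x`` with intercept; test the slope.

    ``statistic='t'`` reports the slope t with df ``n-2``; ``statistic='F'``
    reports F = t^2 with df ``(1, n-2)``.  R^2 is the coefficient of
    determination of the fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points to test a slope")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = sps.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    r2 = res.rvalue**2
    if statistic == "t":
        p = 2.0 * sps.t.sf(abs(t), n - 2)
        return StatResult(res.slope, t, n - 2, p, "ols_slope_t", r_squared=r2, intercept=res.intercept)
    if statistic == "F":
        F = t**2
        p = sps.f.sf(F, 1, n - 2)
        return StatResult(res.slope, F, (1, n - 2), p, "ols_slope_F", r_squared=r2, intercept=res.intercept)
    raise ValueError(f"unknown statistic {statistic!r}")


def unpaired_t(a, b) -> StatResult:
    """Two-sample unpaired t-test (equal variances), df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = float(np.mean(a) - np.mean(b))
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: no within-group variance
        t, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
    else:
        t, p = sps.ttest_ind(a, b)
    return StatResult(diff, float(t), a.size + b.size - 2, float(p), "unpaired_t")


def one_sample_t(diffs, popmean: float = 0.0) -> StatResult:
    """One-sample t-test of a vector of differences, df = n - 1."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 observations")
    mean = float(np.mean(d))
    if np.var(d) == 0:
        t, p = (0.0, 1.0) if mean == popmean else (np.inf * np.sign(mean - popmean), 0.0)
    else:
        t, p = sps.ttest_1samp(d, popmean)
    return StatResult(mean, float(t), d.size - 1, float(p), "paired_t")
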