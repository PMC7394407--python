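"""Associational and comparison statistics used by the analysis.

Spearman rank correlation (PP vs AP position across cycles), one-sample
and paired Student's t-tests (adaptation index vs zero; steady-state vs
initial positions), and Fisher z utilities for averaging correlation
coefficients.  Repeated-measures ANOVA and post-hoc machinery are
deliberately out of scope: the results tables are tidy long-format so
those can be run with any statistics package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "TestResult",
    "spearman",
    "one_sample_t",
    "paired_t",
    "fisher_z",
    "fisher_z_inv",
]

_CLIP = 1.0 - 1e-12  # |r| clipped here before atanh


@dataclass
class RegressionResult:
    """Association summary: Spearman rho or an OLS line with R^2."""

    slope: float | None
    intercept: float | None
    coefficient: float  # rho (spearman) or R^2 (ols)
    p: float
    n: int
    kind: str = "spearman"


@dataclass
class TestResult:
    """A t-test outcome: statistic, degrees of freedom, p, point estimate."""

    statistic: float
    df: int
    p: float
    estimate: float
    flagged: bool = False  # zero-variance input: statistic unbounded


def spearman(x, y) -> RegressionResult:
    """Spearman rank correlation with average-rank ties.

    p uses the t-approximation on n - 2 df; requires n >= 4.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("spearman undefined for a constant input")
    rho, p = sps.spearmanr(x, y)
    return RegressionResult(
        slope=None,
        intercept=None,
        coefficient=float(rho),
        p=float(p),
        n=int(x.size),
        kind="spearman",
    )


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """One-sample Student's t-test of the mean against ``mu0``, two-tailed."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in sample")
    mean = float(np.mean(v))
    if np.std(v, ddof=1) == 0:
        t = 0.0 if mean == mu0 else float(np.inf) * np.sign(mean - mu0)
        p = 1.0 if mean == mu0 else 0.0
        return TestResult(t, int(v.size - 1), p, mean - mu0, flagged=True)
    res = sps.ttest_1samp(v, mu0)
    return TestResult(
        statistic=float(res.statistic),
        df=int(v.size - 1),
        p=float(res.pvalue),
        estimate=mean - mu0,
    )


def paired_t(a, b) -> TestResult:
    """Paired Student's t-test, identical to a one-sample t on a - b vs 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have the same length")
    return one_sample_t(a - b, 0.0)


def fisher_z(r):
    """Fisher z-transform atanh(r); |r| = 1 clipped just inside (-1, 1)."""
    r = np.clip(np.asarray(r, dtype=float), -_CLIP, _CLIP)
    return np.arctanh(r)


def fisher_z_inv(z):
    """Inverse Fisher transform tanh(z)."""
    return np.tanh(np.asarray(z, dtype=float))
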