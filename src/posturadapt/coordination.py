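"""Head–pelvis spatio-temporal coordination via lag-0 cross-correlation.

For each translation cycle the coordination between head and pelvis is
the lag-0 normalized cross-covariance of the two within-cycle traces
after mean-centering — i.e. the Pearson r of the two windows.  Positive
values mean the segments move in the same direction, negative in
opposite directions.  The course of the coefficient across cycles is
fitted with the same exponential model used for the PP series, and the
per-cycle coefficient is regressed against the head PP displacement.

Group-level CC summaries average Fisher-z values and back-transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .adaptation import ExponentialFit, fit_exponential
from .cycles import CycleSeries, CycleWindow
from .io import TrialRecording
from .stats import RegressionResult, fisher_z, fisher_z_inv

__all__ = ["CCSeries", "cc_per_cycle", "fit_cc_course", "cc_vs_pp_regression"]


@dataclass
class CCSeries:
    """Per-cycle lag-0 head–pelvis correlation and its Fisher transform.

    ``cc`` entries are NaN where a within-cycle trace had zero variance
    (correlation undefined); ``defined`` marks the valid cycles.
    """

    cc: np.ndarray
    z: np.ndarray
    n_cycles: int

    def __post_init__(self) -> None:
        self.cc = np.asarray(self.cc, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.cc.size != self.n_cycles:
            raise ValueError("cc must have n_cycles entries")
        valid = self.cc[np.isfinite(self.cc)]
        if valid.size and (np.any(valid < -1) or np.any(valid > 1)):
            raise ValueError("correlation coefficients must lie in [-1, 1]")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.cc)

    def mean_cc(self) -> float:
        """Mean coefficient via Fisher z: average z, back-transform."""
        z = self.z[self.defined]
        if z.size == 0:
            return float("nan")
        return float(fisher_z_inv(np.mean(z)))


def cc_per_cycle(rec: TrialRecording, windows: list[CycleWindow]) -> CCSeries:
    """Lag-0 correlation of head and pelvis within each cycle window."""
    head = rec.head_ap
    pelvis = rec.pelvis_ap
    cc = np.empty(len(windows))
    for i, win in enumerate(windows):
        h = head[win.slice()]
        p = pelvis[win.slice()]
        if h.size == 0:
            raise ValueError(f"empty cycle window {win.index}")
        h = h - h.mean()
        p = p - p.mean()
        sh = np.sqrt(np.dot(h, h))
        sp = np.sqrt(np.dot(p, p))
        if sh == 0 or sp == 0:
            cc[i] = np.nan  # zero-variance trace: correlation undefined
        else:
            cc[i] = float(np.clip(np.dot(h, p) / (sh * sp), -1.0, 1.0))
    return CCSeries(cc=cc, z=fisher_z(cc), n_cycles=len(windows))


def fit_cc_course(ccs: CCSeries, frequency: float | None = None) -> ExponentialFit:
    """Fit the exponential adaptation model to the per-cycle CC course."""
    mask = ccs.defined
    if int(mask.sum()) < 5:
        raise ValueError("need at least 5 defined CC cycles to fit the course")
    n = np.arange(1, ccs.n_cycles + 1)[mask]
    return fit_exponential(ccs.cc[mask], n=n, frequency=frequency)


def cc_vs_pp_regression(ccs: CCSeries, pps: CycleSeries | np.ndarray) -> RegressionResult:
    """OLS regression of the per-cycle CC coefficient on head PP displacement.

    Returns the fitted line, the coefficient of determination R² and the
    two-tailed p of the slope.
    """
    pp = np.asarray(getattr(pps, "pp", pps), dtype=float)
    if pp.size != ccs.n_cycles:
        raise ValueError("CC and PP series must cover the same cycles")
    mask = ccs.defined & np.isfinite(pp)
    x = pp[mask]
    y = ccs.cc[mask]
    if x.size < 3:
        raise ValueError("need at least 3 cycles for the regression")
    if np.std(x) == 0:
        raise ValueError("undefined slope: PP has zero variance")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        coefficient=float(res.rvalue) ** 2,
        p=float(res.pvalue),
        n=int(x.size),
        kind="ols",
    )
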