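"""Exponential adaptation model for per-cycle series.

The course of a per-cycle quantity y_n (peak-to-peak displacement, or the
head–pelvis correlation coefficient) across consecutive perturbation
cycles n = 1, 2, ... is modelled as

    y_n = A + B * exp(-C * (n - 1))

with ``A`` the steady-state asymptote, ``A + B = I`` the intercept at the
first cycle and ``C`` the rate per cycle.  The time constant is
``tau = 1/|C|`` cycles (converted to seconds by the cycle duration), and
the extent of adaptation is summarized by the adaptation index

    AI = (A - I) / (A + I)

which is negative when the amplitude shrinks over the trial and near zero
when adaptation is negligible (AI ~ -0.3 when the asymptote is about half
the intercept).  The model is fitted by damped least squares with
multi-start initialization; goodness of fit is the Pearson correlation
between observed and fitted values.

The estimator follows the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes), so
it composes with sklearn model-selection tooling; the module-level
functions are thin wrappers for pipeline use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ExponentialAdaptationModel",
    "ExponentialFit",
    "SteadyStateSummary",
    "fit_exponential",
    "derive_indices",
    "goodness_of_fit",
    "steady_state",
    "average_trials",
]


@dataclass
class ExponentialFit:
    """Result of an exponential adaptation fit."""

    A: float  # asymptote, units of the fitted series
    B: float  # amplitude term; I - A
    C: float  # rate per cycle
    tau_cycles: float
    tau_seconds: float | None
    I: float  # intercept at the first cycle, = A + B
    AI: float  # adaptation index, (A - I)/(A + I)
    R: float  # Pearson goodness of fit
    p_R: float
    rss: float
    converged: bool
    degenerate: bool
    n_cycles: int

    def predict(self, n: np.ndarray | float) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return self.A + self.B * np.exp(-self.C * (n - 1.0))


@dataclass
class SteadyStateSummary:
    """Steady-state means over a late-cycle window (default cycles 15-27)."""

    window: tuple[int, int]
    mean_pp: float
    mean_ap: float
    initial_ap: float  # mean over the first k cycles of the referenced series
    n_cycles_averaged: int


def _model(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    a, b, c = theta
    return a + b * np.exp(-c * t)


class ExponentialAdaptationModel(RegressorMixin, BaseEstimator):
    """Three-parameter exponential decay/rise fitted to a per-cycle series.

    Parameters
    ----------
    frequency : float or None
        Platform translation frequency in Hz; when given, the fitted time
        constant is also expressed in seconds (``tau_seconds_``).
    tau_min : float
        Lower bound on the time constant, in cycles.  Fits pinned at a
        bound are flagged degenerate.
    tau_max_factor : float
        Upper bound on tau as a multiple of the series length; beyond it
        the curve is indistinguishable from a line at data resolution.
    tol_b : float
        Degeneracy threshold: |B| below ``tol_b * |A|`` means the fitted
        curve is flat at data resolution.
    tol : float
        Convergence tolerance on parameters for the inner solver.
    max_iter : int
        Iteration cap per start.

    Attributes
    ----------
    asymptote_, amplitude_, rate_ : float
        Fitted A, B and C.
    intercept_ : float
        Model value at the first cycle, ``A + B``.
    tau_cycles_, tau_seconds_ : float
        Time constant ``1/|C|`` in cycles and (if ``frequency`` is set)
        in seconds.
    adaptation_index_ : float
        ``(A - I)/(A + I)``.
    r_, p_r_ : float
        Pearson correlation between observed and fitted values and its
        two-tailed p (t distribution, n - 2 df).
    rss_ : float
        Residual sum of squares.
    converged_, degenerate_ : bool
    """

    #: multi-start rate initializations, in units of 1/cycles
    _C_STARTS = (1.0, 0.5, 0.25, 0.125)

    def __init__(
        self,
        frequency: float | None = None,
        tau_min: float = 0.2,
        tau_max_factor: float = 3.0,
        tol_b: float = 0.02,
        tol: float = 1e-9,
        max_iter: int = 10_000,
    ):
        self.frequency = frequency
        self.tau_min = tau_min
        self.tau_max_factor = tau_max_factor
        self.tol_b = tol_b
        self.tol = tol
        self.max_iter = max_iter

    # ------------------------------------------------------------------
    @staticmethod
    def _as_cycles(X) -> np.ndarray:
        n = np.asarray(X, dtype=float)
        if n.ndim == 2:
            if n.shape[1] != 1:
                raise ValueError("X must be a single column of cycle indices")
            n = n[:, 0]
        elif n.ndim != 1:
            raise ValueError("X must be 1-D cycle indices or a single column")
        return n

    def fit(self, X, y):
        """Fit the model to per-cycle values.

        Parameters
        ----------
        X : array-like
            1-based cycle indices (1-D, or a single 2-D column).
        y : array-like
            The per-cycle series (same length, >= 5 finite values).
        """
        n = self._as_cycles(X)
        y = np.asarray(y, dtype=float)
        if n.size != y.size:
            raise ValueError("X and y must have the same length")
        if n.size < 5:
            raise ValueError("need at least 5 cycles to fit the exponential model")
        if not (np.all(np.isfinite(n)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in the per-cycle series")

        t = n - 1.0  # first cycle at t = 0, so the intercept is exactly A + B
        c_lo = 1.0 / (self.tau_max_factor * n.size)
        c_hi = 1.0 / self.tau_min

        a0 = float(np.mean(y[-min(5, y.size):]))
        b0 = float(y[0] - a0)
        b_mag = abs(b0)
        if b_mag < 1e-12:
            b_mag = max(float(np.std(y)), 1e-3)

        sign0 = 1.0 if b0 >= 0 else -1.0
        best = None
        any_converged = False
        for c0 in self._C_STARTS:
            c0 = float(np.clip(c0, c_lo, c_hi))
            for b_sign in (sign0, -sign0):
                theta0 = np.array([a0, b_sign * b_mag, c0])
                sol = optimize.least_squares(
                    lambda th: _model(th, t) - y,
                    theta0,
                    jac=lambda th: np.column_stack(
                        [
                            np.ones_like(t),
                            np.exp(-th[2] * t),
                            -th[1] * t * np.exp(-th[2] * t),
                        ]
                    ),
                    bounds=([-np.inf, -np.inf, c_lo], [np.inf, np.inf, c_hi]),
                    xtol=self.tol,
                    ftol=self.tol,
                    gtol=self.tol,
                    max_nfev=self.max_iter,
                )
                rss = float(2.0 * sol.cost)
                any_converged = any_converged or sol.success
                if best is None or rss < best[0]:
                    best = (rss, sol.x, sol.success)
            if best[0] < 1e-18 * max(1.0, float(np.dot(y, y))):
                break  # exact fit found; further starts cannot improve
        if best is None or not any_converged:
            diag = None if best is None else best[1]
            raise RuntimeError(
                f"exponential fit failed to converge from any start; best-so-far {diag}"
            )

        rss, theta, success = best
        a, b, c = (float(v) for v in theta)

        self.n_cycles_ = int(n.size)
        self.asymptote_ = a
        self.amplitude_ = b
        self.rate_ = c
        self.intercept_ = a + b
        self.tau_cycles_ = 1.0 / abs(c)
        self.tau_seconds_ = (
            self.tau_cycles_ / self.frequency if self.frequency else None
        )
        denom = a + self.intercept_
        self.adaptation_index_ = (
            (a - self.intercept_) / denom if denom != 0 else np.nan
        )
        self.rss_ = rss
        self.converged_ = bool(success)

        at_bound = (
            c <= c_lo * (1 + 1e-6)
            or c >= c_hi * (1 - 1e-6)
            or self.tau_cycles_ > self.tau_max_factor * n.size * (1 - 1e-9)
        )
        self.degenerate_ = bool(abs(b) < self.tol_b * abs(a) or at_bound)

        fitted = _model(theta, t)
        self.r_, self.p_r_ = _pearson_goodness(y, fitted)
        return self

    def predict(self, X) -> np.ndarray:
        n = self._as_cycles(X)
        return _model(
            np.array([self.asymptote_, self.amplitude_, self.rate_]), n - 1.0
        )

    # ------------------------------------------------------------------
    def to_result(self) -> ExponentialFit:
        return ExponentialFit(
            A=self.asymptote_,
            B=self.amplitude_,
            C=self.rate_,
            tau_cycles=self.tau_cycles_,
            tau_seconds=self.tau_seconds_,
            I=self.intercept_,
            AI=self.adaptation_index_,
            R=self.r_,
            p_R=self.p_r_,
            rss=self.rss_,
            converged=self.converged_,
            degenerate=self.degenerate_,
            n_cycles=self.n_cycles_,
        )


def _pearson_goodness(observed: np.ndarray, fitted: np.ndarray) -> tuple[float, float]:
    """Pearson R between observed and fitted values, two-tailed p on n-2 df.

    Returns (nan, nan) when either series has zero variance (e.g. a
    degenerate constant fit), which callers flag rather than fail on.
    """
    if np.std(observed) == 0 or np.std(fitted) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(observed, fitted)[0, 1])
    r = min(1.0, max(-1.0, r))
    n = observed.size
    if n <= 2:
        return r, float("nan")
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(tstat), df=n - 2))
    return r, p


# ---------------------------------------------------------------------------
# functional wrappers


def fit_exponential(
    series,
    n=None,
    frequency: float | None = None,
    **model_params,
) -> ExponentialFit:
    """Fit ``y_n = A + B exp(-C (n-1))`` to a per-cycle series.

    ``series`` may be an array of per-cycle values or a
    :class:`~posturadapt.cycles.CycleSeries` (its ``pp`` field is fitted).
    ``n`` defaults to 1..len(series).
    """
    y = np.asarray(getattr(series, "pp", series), dtype=float)
    if n is None:
        n = np.arange(1, y.size + 1)
    model = ExponentialAdaptationModel(frequency=frequency, **model_params)
    model.fit(n, y)
    return model.to_result()


def derive_indices(fit: ExponentialFit, frequency: float) -> ExponentialFit:
    """Complete a fit with tau (cycles and seconds), I and AI.

    ``tau_cycles = 1/|C|`` (time constants are reported positive; the
    direction of adaptation is carried by the sign of AI), and
    ``tau_seconds = tau_cycles / frequency`` — one cycle lasts 5.6 s at
    0.18 Hz and 1.8 s at 0.56 Hz.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    fit.I = fit.A + fit.B
    fit.tau_cycles = 1.0 / abs(fit.C)
    fit.tau_seconds = fit.tau_cycles / frequency
    denom = fit.A + fit.I
    if denom == 0:
        raise ValueError("AI undefined: A + I = 0")
    fit.AI = (fit.A - fit.I) / denom
    return fit


def goodness_of_fit(series, fit: ExponentialFit, n=None) -> tuple[float, float]:
    """Pearson R between observed and fitted values and its two-tailed p."""
    y = np.asarray(getattr(series, "pp", series), dtype=float)
    if n is None:
        n = np.arange(1, y.size + 1)
    return _pearson_goodness(y, fit.predict(np.asarray(n, dtype=float)))


def steady_state(series, window: tuple[int, int] = (15, 27), initial_k: int = 1) -> SteadyStateSummary:
    """Mean PP and mean AP position over the steady-state cycle window.

    Default window is cycles 15–27, the adapted regime (3 tau < 15 cycles
    for all conditions).  ``initial_k`` controls how many early cycles
    form the initial-position reference stored for paired comparisons.
    """
    lo, hi = int(window[0]), int(window[1])
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid steady-state window {window}")
    if hi > series.n_cycles:
        raise ValueError(
            f"window {window} outside the available {series.n_cycles} cycles"
        )
    sl = slice(lo - 1, hi)
    return SteadyStateSummary(
        window=(lo, hi),
        mean_pp=float(np.mean(series.pp[sl])),
        mean_ap=float(np.mean(series.mean_ap[sl])),
        initial_ap=float(np.mean(series.mean_ap[:initial_k])),
        n_cycles_averaged=hi - lo + 1,
    )


def average_trials(series_list) -> "CycleSeries":
    """Element-wise mean of per-cycle series across repeated trials.

    The two trials of each condition are averaged on the per-cycle series
    before fitting, not on fitted parameters.
    """
    from .cycles import CycleSeries

    if not series_list:
        raise ValueError("no series to average")
    n = series_list[0].n_cycles
    segment = series_list[0].segment
    for s in series_list[1:]:
        if s.n_cycles != n:
            raise ValueError(
                f"mismatched cycle counts: {s.n_cycles} vs {n}; truncate first"
            )
    pp = np.mean([s.pp for s in series_list], axis=0)
    mean_ap = np.mean([s.mean_ap for s in series_list], axis=0)
    return CycleSeries(segment=segment, pp=pp, mean_ap=mean_ap, n_cycles=n)
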