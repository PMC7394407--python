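"""Perturbation onset detection, cycle segmentation and per-cycle metrics.

A trial is cut into translation cycles from the platform trace: onset is
the first departure from the quiet-stance baseline, and cycle boundaries
are the successive positive-going crossings of the post-onset midline
(phase-unambiguous for a sinusoid).  Within each cycle window the
peak-to-peak (PP) displacement and the mean AP position of a segment are
computed; mean positions are referenced to the first cycle so cycle 1
maps to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TrialRecording

__all__ = [
    "CycleWindow",
    "CycleSeries",
    "detect_onset",
    "segment_cycles",
    "per_cycle_metrics",
]


@dataclass(frozen=True)
class CycleWindow:
    """One translation cycle as a half-open sample interval."""

    index: int  # 1-based cycle number
    start_sample: int
    end_sample: int
    start_time: float
    end_time: float

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample

    def slice(self) -> slice:
        return slice(self.start_sample, self.end_sample)


@dataclass
class CycleSeries:
    """Per-cycle PP displacement and cycle-1-referenced mean AP position."""

    segment: str
    pp: np.ndarray  # cm, >= 0
    mean_ap: np.ndarray  # cm, mean_ap[0] == 0 after referencing
    n_cycles: int

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        self.mean_ap = np.asarray(self.mean_ap, dtype=float)
        if self.pp.size != self.n_cycles or self.mean_ap.size != self.n_cycles:
            raise ValueError("pp and mean_ap must both have n_cycles entries")
        if np.any(self.pp < 0):
            raise ValueError("per-cycle PP cannot be negative")

    def truncate(self, max_cycles: int) -> "CycleSeries":
        """Keep the first ``max_cycles`` cycles (analysis convention: 27)."""
        k = min(self.n_cycles, max_cycles)
        return CycleSeries(self.segment, self.pp[:k], self.mean_ap[:k], k)

    @property
    def cycle_index(self) -> np.ndarray:
        return np.arange(1, self.n_cycles + 1)


def detect_onset(
    rec: TrialRecording,
    k: float = 5.0,
    baseline_window: float = 1.0,
    eps_floor: float = 1e-4,
) -> int:
    """Locate the perturbation onset sample from the platform trace.

    The baseline mean and SD are estimated over the first
    ``baseline_window`` seconds.  Onset is the first sample deviating from
    the baseline mean by more than ``k * max(SD, eps_floor)``, backtracked
    to the last sample still at baseline level.  ``eps_floor`` (cm) guards
    noiseless traces whose baseline SD is exactly zero.
    """
    x = rec.platform_ap
    n_base = max(2, int(round(baseline_window * rec.sampling_rate)))
    if n_base >= x.size:
        raise ValueError("recording shorter than the baseline window")
    base = x[:n_base]
    mean = float(np.mean(base))
    sd = float(np.std(base))
    level = max(sd, eps_floor)
    dev = np.abs(x - mean)
    above = np.nonzero(dev > k * level)[0]
    if above.size == 0:
        raise ValueError("no perturbation detected: platform never leaves baseline")
    first = int(above[0])
    # backtrack to the last sample still within the baseline band
    onset = first
    while onset > 0 and dev[onset - 1] > level:
        onset -= 1
    return onset


def segment_cycles(
    rec: TrialRecording,
    onset: int,
    frequency: float | None = None,
    hysteresis_frac: float = 0.05,
) -> list[CycleWindow]:
    """Segment the post-onset platform trace into translation cycles.

    Boundaries are the positive-going crossings of the post-onset midline
    (the mean of the post-onset platform trace), detected with a
    hysteresis band of ``hysteresis_frac`` of the platform PP to reject
    noise.  The onset itself seeds the first boundary.  A trailing stretch
    is kept as the final cycle only if it spans a full period (within one
    sample); partial cycles are discarded.
    """
    if frequency is None:
        frequency = rec.frequency
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    x = rec.platform_ap[onset:]
    if x.size < 2:
        raise ValueError("cannot segment: no samples after onset")
    mid = float(np.mean(x))
    pp = float(np.max(x) - np.min(x))
    if pp == 0:
        raise ValueError("cannot segment: platform trace is constant after onset")
    hyst = hysteresis_frac * pp

    # positive-going midline crossings, accepted only after the trace has
    # visited the lower hysteresis band since the previous boundary
    cross = np.nonzero((x[:-1] < mid) & (x[1:] >= mid))[0] + 1
    below = np.nonzero(x < mid - hyst)[0]
    boundaries = [0]
    for i in cross:
        pos = int(np.searchsorted(below, i))
        if pos > 0 and below[pos - 1] > boundaries[-1]:
            boundaries.append(int(i))

    period_samples = rec.sampling_rate / frequency
    tail = x.size - boundaries[-1]
    if tail >= int(round(period_samples)) - 1:
        boundaries.append(min(boundaries[-1] + int(round(period_samples)), x.size))

    if len(boundaries) < 2:
        raise ValueError("cannot segment: fewer than two cycle boundaries found")

    windows = []
    for idx in range(len(boundaries) - 1):
        start = boundaries[idx]
        end = boundaries[idx + 1]
        # reject windows that do not span roughly one platform period,
        # e.g. from residual noise crossings; crossing jitter on noisy
        # traces shifts boundaries by a few samples, hence the 5% slack
        if abs((end - start) - period_samples) > max(1.5, 0.05 * period_samples):
            continue
        windows.append(
            CycleWindow(
                index=len(windows) + 1,
                start_sample=onset + start,
                end_sample=onset + end,
                start_time=rec.time[onset + start],
                end_time=rec.time[min(onset + end, rec.n_samples - 1)],
            )
        )
    if not windows:
        raise ValueError("cannot segment: no full cycle found after onset")
    return windows


def per_cycle_metrics(
    rec: TrialRecording,
    windows: list[CycleWindow],
    segment: str,
) -> CycleSeries:
    """Per-cycle PP displacement and cycle-1-referenced mean AP position.

    ``pp[n]`` is max - min of the segment trace within window ``n``;
    ``mean_ap[n]`` is the within-window mean minus the window-1 mean, so
    the first cycle is exactly zero.
    """
    trace = rec.segment_trace(segment)
    pp = np.empty(len(windows))
    mean_ap = np.empty(len(windows))
    for i, win in enumerate(windows):
        chunk = trace[win.slice()]
        if chunk.size == 0:
            raise ValueError(f"empty cycle window {win.index}")
        pp[i] = float(np.max(chunk) - np.min(chunk))
        mean_ap[i] = float(np.mean(chunk))
    mean_ap -= mean_ap[0]
    return CycleSeries(segment=segment, pp=pp, mean_ap=mean_ap, n_cycles=len(windows))
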