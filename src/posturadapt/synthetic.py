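"""Synthetic trial generator for continuous support-surface translations.

The generator emulates the structure that the cycle-by-cycle analysis
assumes: a sinusoidal platform translation (10 cm peak-to-peak at 0.18 Hz
or 0.56 Hz, sampled at 140 Hz) preceded by a quiet-stance pre-period, and
head/pelvis AP traces whose per-cycle peak-to-peak amplitude follows a
three-parameter exponential envelope

    G(n) = A + (I - A) * exp(-(n - 1) / tau)

with ``A`` the steady-state amplitude (cm), ``I`` the amplitude at the
first cycle (cm) and ``tau`` the time constant in cycles.  Head–pelvis
coordination is controlled by a shared/independent variance mixture: both
segments carry a common oscillatory waveform with weight sqrt(lambda) and
an independent component with weight sqrt(1 - lambda), so the expected
lag-0 per-cycle correlation equals ``lambda`` itself.  ``lambda`` may be
constant or follow its own exponential course across cycles.

With ``noise_sd = 0`` and ``lambda = 1`` the measured per-cycle PP of each
segment reproduces G(n) exactly up to sampling discretization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import TrialRecording

__all__ = [
    "Envelope",
    "CCCourse",
    "SynthConfig",
    "generate_platform",
    "generate_trial",
    "generate_cohort",
]

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class Envelope:
    """Exponential per-cycle peak-to-peak envelope (A, I, tau in cm, cm, cycles)."""

    asymptote: float
    intercept: float
    tau: float

    def __post_init__(self) -> None:
        if self.asymptote <= 0 or self.intercept <= 0:
            raise ValueError("envelope asymptote and intercept must be positive")
        if self.tau <= 0:
            raise ValueError("envelope tau must be positive")

    def value(self, n: np.ndarray | float) -> np.ndarray:
        """Envelope G(n) at 1-based cycle index n."""
        n = np.asarray(n, dtype=float)
        return self.asymptote + (self.intercept - self.asymptote) * np.exp(
            -(n - 1.0) / self.tau
        )

    @property
    def adaptation_index(self) -> float:
        return (self.asymptote - self.intercept) / (self.asymptote + self.intercept)


@dataclass(frozen=True)
class CCCourse:
    """Exponential course of the shared-variance fraction lambda across cycles."""

    asymptote: float
    intercept: float
    tau: float

    def __post_init__(self) -> None:
        for v in (self.asymptote, self.intercept):
            if not 0.0 <= v <= 1.0:
                raise ValueError("lambda course values must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("lambda course tau must be positive")

    def value(self, n: np.ndarray | float) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        lam = self.asymptote + (self.intercept - self.asymptote) * np.exp(
            -(n - 1.0) / self.tau
        )
        return np.clip(lam, 0.0, 1.0)


@dataclass(frozen=True)
class SynthConfig:
    """Full generative parameterization of one synthetic trial.

    Defaults follow the low-frequency protocol: 0.18 Hz sinusoidal
    translation, 10 cm peak-to-peak, 27 cycles, 140 Hz sampling, 5 s quiet
    stance before onset.  Envelope defaults place the steady-state
    amplitudes near the platform amplitude with time constants in the
    range observed for young adults (1.5–3.5 cycles), the head adapting
    more slowly than the pelvis.
    """

    frequency: float = 0.18
    n_cycles: int = 27
    sampling_rate: float = 140.0
    platform_pp: float = 10.0
    pre_period: float = 5.0
    head: Envelope = field(default_factory=lambda: Envelope(12.0, 8.0, 3.0))
    pelvis: Envelope = field(default_factory=lambda: Envelope(10.0, 8.0, 2.0))
    head_phase: float = 0.0
    pelvis_phase: float = 0.0
    mean_drift: float = 0.0
    coordination: float | CCCourse = 1.0
    noise_sd: float | None = None  # cm; None -> 5% of each segment's asymptote
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.sampling_rate <= 2.0 * self.frequency:
            raise ValueError("sampling_rate must exceed twice the frequency (Nyquist)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")
        if self.platform_pp <= 0:
            raise ValueError("platform_pp must be positive")
        if self.pre_period < 0:
            raise ValueError("pre_period must be non-negative")
        if isinstance(self.coordination, (int, float)):
            if not 0.0 <= float(self.coordination) <= 1.0:
                raise ValueError("coordination lambda must lie in [0, 1]")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    # protocol presets -------------------------------------------------
    @classmethod
    def lf(cls, **overrides) -> "SynthConfig":
        """Low-frequency protocol: 0.18 Hz, 27 cycles (amplitudes rise)."""
        return cls(**overrides)

    @classmethod
    def hf(cls, **overrides) -> "SynthConfig":
        """High-frequency protocol: 0.56 Hz, 31 cycles (head amplitude decays)."""
        defaults = dict(
            frequency=0.56,
            n_cycles=31,
            head=Envelope(5.0, 8.0, 1.5),
            pelvis=Envelope(6.0, 7.0, 1.0),
        )
        defaults.update(overrides)
        return cls(**defaults)

    def replace(self, **changes) -> "SynthConfig":
        return replace(self, **changes)

    # timing helpers ---------------------------------------------------
    @property
    def n_pre_samples(self) -> int:
        return int(round(self.pre_period * self.sampling_rate))

    @property
    def n_perturb_samples(self) -> int:
        return int(round(self.n_cycles / self.frequency * self.sampling_rate))

    @property
    def n_samples(self) -> int:
        return self.n_pre_samples + self.n_perturb_samples

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def lambda_per_cycle(self) -> np.ndarray:
        n = np.arange(1, self.n_cycles + 1, dtype=float)
        if isinstance(self.coordination, CCCourse):
            return self.coordination.value(n)
        return np.full(self.n_cycles, float(self.coordination))


def _cycle_index(cfg: SynthConfig, t: np.ndarray) -> np.ndarray:
    """1-based cycle index per sample; 0 marks the pre-period."""
    rel = (t - cfg.pre_period) * cfg.frequency
    idx = np.floor(rel).astype(int) + 1
    idx[rel < 0] = 0
    return np.clip(idx, 0, cfg.n_cycles)


def _platform_trace(cfg: SynthConfig, t: np.ndarray) -> np.ndarray:
    x = np.zeros_like(t)
    moving = t >= cfg.pre_period
    phase = 2.0 * np.pi * cfg.frequency * (t[moving] - cfg.pre_period)
    x[moving] = 0.5 * cfg.platform_pp * np.sin(phase)
    return x


def generate_platform(cfg: SynthConfig) -> TrialRecording:
    """Generate the noiseless platform translation alone.

    Zeros during the pre-period, then ``n_cycles`` full sinusoidal periods
    of peak-to-peak amplitude ``platform_pp`` starting at the midline with
    positive-going onset.  Head and pelvis traces are zero.
    """
    t = cfg.time()
    platform = _platform_trace(cfg, t)
    zeros = np.zeros_like(t)
    return TrialRecording(
        time=t,
        platform_ap=platform,
        head_ap=zeros,
        pelvis_ap=zeros.copy(),
        sampling_rate=cfg.sampling_rate,
        frequency=cfg.frequency,
        meta={"synthetic": "platform-only"},
    )


def _segment_trace(
    cfg: SynthConfig,
    envelope: Envelope,
    phase_offset: float,
    harmonic: int,
    t: np.ndarray,
    cycle_idx: np.ndarray,
    lam_per_cycle: np.ndarray,
    common: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float,
) -> np.ndarray:
    moving = cycle_idx > 0
    n = cycle_idx[moving].astype(float)
    amp = 0.5 * envelope.value(n)

    # shared waveform: unit-amplitude sinusoid with this segment's phase
    theta = 2.0 * np.pi * cfg.frequency * (t[moving] - cfg.pre_period)
    shared = np.sin(theta + phase_offset) if phase_offset != 0.0 else common[moving]

    lam = lam_per_cycle[cycle_idx[moving] - 1]
    # independent component: a segment-specific harmonic of the platform
    # frequency with a fresh random phase each cycle.  Harmonics are
    # orthogonal to the fundamental (and to each other) over a full
    # period and carry the same variance as a unit sinusoid, so lambda is
    # the shared fraction of oscillatory variance and the within-cycle
    # Pearson correlation of two segments equals lambda exactly in the
    # noiseless limit, while the per-cycle PP stays close to G(n).
    psi_per_cycle = rng.uniform(0.0, 2.0 * np.pi, size=cfg.n_cycles)
    own = np.sin(harmonic * theta + psi_per_cycle[cycle_idx[moving] - 1])
    osc = amp * (np.sqrt(lam) * shared + np.sqrt(1.0 - lam) * own)

    x = np.zeros_like(t)
    if cfg.mean_drift != 0.0:
        duration = cfg.n_cycles / cfg.frequency
        x[moving] += cfg.mean_drift * (t[moving] - cfg.pre_period) / duration
    x[moving] += osc
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=t.size)
    return x


def generate_trial(cfg: SynthConfig) -> TrialRecording:
    """Generate one synthetic trial (platform, head and pelvis AP traces).

    Identical ``cfg`` (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.time()
    platform = _platform_trace(cfg, t)
    cycle_idx = _cycle_index(cfg, t)
    lam = cfg.lambda_per_cycle()
    common = np.sin(2.0 * np.pi * cfg.frequency * (t - cfg.pre_period))

    traces = {}
    for name, envelope, phase, harmonic in (
        ("head", cfg.head, cfg.head_phase, 2),
        ("pelvis", cfg.pelvis, cfg.pelvis_phase, 3),
    ):
        noise_sd = (
            0.05 * envelope.asymptote if cfg.noise_sd is None else float(cfg.noise_sd)
        )
        traces[name] = _segment_trace(
            cfg, envelope, phase, harmonic, t, cycle_idx, lam, common, rng, noise_sd
        )

    return TrialRecording(
        time=t,
        platform_ap=platform,
        head_ap=traces["head"],
        pelvis_ap=traces["pelvis"],
        sampling_rate=cfg.sampling_rate,
        frequency=cfg.frequency,
        meta={"synthetic": "trial", "seed": cfg.seed},
    )


def _jitter_envelope(env: Envelope, rng: np.random.Generator, sd: float) -> Envelope:
    if sd == 0:
        return env
    factors = np.exp(rng.normal(0.0, sd, size=3))  # lognormal keeps params positive
    return Envelope(
        asymptote=env.asymptote * factors[0],
        intercept=env.intercept * factors[1],
        tau=env.tau * factors[2],
    )


def generate_cohort(
    configs: Mapping[str, SynthConfig],
    n_subjects: int,
    n_trials: int = 2,
    seed: int = 0,
    jitter_sd: float = 0.1,
) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Generate a cohort of trials with per-subject envelope jitter.

    Parameters
    ----------
    configs : mapping
        One :class:`SynthConfig` per condition, keyed by a condition label
        such as ``"EO@LF"`` (``visual_condition@frequency_label``).
    n_subjects, n_trials : int
        Cohort size; the protocol uses 20 subjects and 2 trials per
        condition.
    jitter_sd : float
        Log-scale SD of the multiplicative per-subject jitter applied to
        each envelope parameter (A, I, tau), emulating inter-individual
        variability.

    Returns
    -------
    recordings, truth
        The trial recordings and a ground-truth sidecar table with the
        per-subject true A, I, tau, AI and lambda for each segment,
        for parameter-recovery reports.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rng = np.random.default_rng(seed)
    recordings: list[TrialRecording] = []
    truth_rows: list[dict] = []
    for subj in range(1, n_subjects + 1):
        subject_id = f"S{subj:02d}"
        for label, base in configs.items():
            visual, _, freq_label = label.partition("@")
            head = _jitter_envelope(base.head, rng, jitter_sd)
            pelvis = _jitter_envelope(base.pelvis, rng, jitter_sd)
            lam_mean = float(np.mean(base.lambda_per_cycle()))
            for segment, env in (("head", head), ("pelvis", pelvis)):
                truth_rows.append(
                    {
                        "subject": subject_id,
                        "condition": visual,
                        "frequency": freq_label or f"{base.frequency:g}Hz",
                        "segment": segment,
                        "true_A": env.asymptote,
                        "true_I": env.intercept,
                        "true_tau": env.tau,
                        "true_AI": env.adaptation_index,
                        "true_lambda": lam_mean,
                    }
                )
            for trial_idx in range(1, n_trials + 1):
                trial_seed = int(rng.integers(0, 2**31 - 1))
                cfg = base.replace(head=head, pelvis=pelvis, seed=trial_seed)
                rec = generate_trial(cfg)
                recordings.append(
                    rec.copy(
                        subject_id=subject_id,
                        visual_condition=visual,
                        trial_index=trial_idx,
                        meta=dict(
                            rec.meta,
                            condition_label=label,
                            frequency_label=freq_label or f"{base.frequency:g}Hz",
                        ),
                    )
                )
    truth = pd.DataFrame(truth_rows)
    return recordings, truth
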