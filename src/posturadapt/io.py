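"""Reading and writing trial recordings and tidy results tables.

Trial files are plain UTF-8 tab-separated tables with one header line
naming the columns ``time_s``, ``platform_ap_cm``, ``head_ap_cm`` and
``pelvis_ap_cm``.  Metadata travel as ``#key=value`` comment lines before
the header.  Displacements are in centimetres (positive = forward), time
in seconds.  The format is deliberately lossless and diff-friendly;
proprietary motion-capture formats are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecording",
    "read_trial",
    "write_trial",
    "write_results",
    "TRIAL_COLUMNS",
    "RESULTS_KEY",
]

#: canonical column order of a trial file
TRIAL_COLUMNS = ("time_s", "platform_ap_cm", "head_ap_cm", "pelvis_ap_cm")

#: key columns of a tidy results table, in order
RESULTS_KEY = ("subject", "condition", "frequency", "segment")

VISUAL_CONDITIONS = ("EO", "EO-TP", "EO-TG", "EC")

#: scale factors into centimetres for supported length units
_UNIT_TO_CM = {"cm": 1.0, "m": 100.0, "mm": 0.1}

_TIME_STEP_TOL = 1e-9  # s; allowed deviation from a constant sampling step


@dataclass
class TrialRecording:
    """One trial: uniformly sampled AP traces of platform, head and pelvis.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing with constant step
        ``1 / sampling_rate``.
    platform_ap, head_ap, pelvis_ap : ndarray
        Antero-posterior displacement in cm; positive is forward.
    sampling_rate : float
        Sampling frequency in Hz.
    subject_id : str
        Participant label.
    visual_condition : str
        One of ``EO``, ``EO-TP``, ``EO-TG``, ``EC``.
    frequency : float
        Platform translation frequency in Hz (0.18 for LF, 0.56 for HF).
    trial_index : int
        Trial repetition number within the condition.
    """

    time: np.ndarray
    platform_ap: np.ndarray
    head_ap: np.ndarray
    pelvis_ap: np.ndarray
    sampling_rate: float
    subject_id: str = "S00"
    visual_condition: str = "EO"
    frequency: float = 0.18
    trial_index: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("time", "platform_ap", "head_ap", "pelvis_ap"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        n = self.time.size
        if n == 0:
            raise ValueError("empty recording: no samples")
        for name in ("platform_ap", "head_ap", "pelvis_ap"):
            if getattr(self, name).size != n:
                raise ValueError(
                    f"trace length mismatch: {name} has "
                    f"{getattr(self, name).size} samples, time has {n}"
                )
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite samples in {name}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if n >= 2:
            steps = np.diff(self.time)
            expected = 1.0 / self.sampling_rate
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            if np.max(np.abs(steps - expected)) > _TIME_STEP_TOL:
                raise ValueError(
                    "non-uniform time step: deviation from "
                    f"1/sampling_rate = {expected:g} s exceeds {_TIME_STEP_TOL:g} s"
                )
        if self.frequency > 0 and self.sampling_rate <= 2.0 * self.frequency:
            raise ValueError(
                "sampling_rate must exceed twice the perturbation frequency "
                f"(Nyquist): {self.sampling_rate} Hz vs {self.frequency} Hz"
            )

    # -- conveniences ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    def segment_trace(self, segment: str) -> np.ndarray:
        """Return the AP trace for ``segment`` in {platform, head, pelvis}."""
        try:
            return {
                "platform": self.platform_ap,
                "head": self.head_ap,
                "pelvis": self.pelvis_ap,
            }[segment]
        except KeyError:
            raise ValueError(f"unknown segment {segment!r}") from None

    def copy(self, **changes) -> "TrialRecording":
        return replace(self, **changes)


def _parse_metadata(lines: list[str]) -> dict:
    meta: dict = {}
    for raw in lines:
        body = raw.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_trial(path: str | os.PathLike, metadata: dict | None = None) -> TrialRecording:
    """Read a tab-separated trial file into a validated :class:`TrialRecording`.

    ``#key=value`` comment lines before the header populate the recording
    metadata; the ``metadata`` argument overrides values from the file.
    A ``unit`` entry of ``m`` or ``mm`` converts displacement columns to cm.
    """
    comment_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                comment_lines.append(line)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        try:
            frame = pd.read_csv(fh, sep="\t")
        except pd.errors.EmptyDataError:
            raise ValueError(f"empty trial file: {path}") from None
    if frame.empty:
        raise ValueError(f"empty trial file: {path}")

    meta = _parse_metadata(comment_lines)
    if metadata:
        meta.update(metadata)

    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")

    unit = str(meta.get("unit", "cm"))
    if unit not in _UNIT_TO_CM:
        raise ValueError(f"unsupported displacement unit {unit!r}")
    scale = _UNIT_TO_CM[unit]

    time = frame["time_s"].to_numpy(float)
    if "sampling_rate_hz" in meta:
        rate = float(meta["sampling_rate_hz"])
    elif time.size >= 2:
        rate = 1.0 / float(np.median(np.diff(time)))
    else:
        raise ValueError("sampling rate neither declared nor inferable")

    return TrialRecording(
        time=time,
        platform_ap=frame["platform_ap_cm"].to_numpy(float) * scale,
        head_ap=frame["head_ap_cm"].to_numpy(float) * scale,
        pelvis_ap=frame["pelvis_ap_cm"].to_numpy(float) * scale,
        sampling_rate=rate,
        subject_id=str(meta.get("subject_id", "S00")),
        visual_condition=str(meta.get("visual_condition", "EO")),
        frequency=float(meta.get("frequency_hz", 0.18)),
        trial_index=int(meta.get("trial_index", 1)),
        meta=meta,
    )


def write_trial(rec: TrialRecording, path: str | os.PathLike) -> str:
    """Write a recording as a TSV that :func:`read_trial` inverts losslessly.

    Floats are serialized with 17 significant digits, so the write→read
    round trip reproduces traces bit-compatibly.
    """
    rec.validate()
    header_meta = {
        "subject_id": rec.subject_id,
        "visual_condition": rec.visual_condition,
        "frequency_hz": repr(float(rec.frequency)),
        "trial_index": rec.trial_index,
        "sampling_rate_hz": repr(float(rec.sampling_rate)),
        "unit": "cm",
    }
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in header_meta.items():
            fh.write(f"#{key}={value}\n")
        fh.write("\t".join(TRIAL_COLUMNS) + "\n")
        data = np.column_stack(
            [rec.time, rec.platform_ap, rec.head_ap, rec.pelvis_ap]
        )
        np.savetxt(fh, data, fmt="%.17g", delimiter="\t")
    return os.fspath(path)


def write_results(tables: pd.DataFrame | list[pd.DataFrame], path: str | os.PathLike) -> str:
    """Write a tidy results table, one row per (subject, condition, frequency, segment).

    Raises on duplicate keys so downstream joins stay unambiguous.
    """
    if isinstance(tables, pd.DataFrame):
        frame = tables
    else:
        if not tables:
            raise ValueError("no results to write")
        frame = pd.concat(list(tables), ignore_index=True)
    if frame.empty:
        raise ValueError("no results to write")
    key_cols = [c for c in RESULTS_KEY if c in frame.columns]
    if key_cols:
        dup = frame.duplicated(subset=key_cols)
        if dup.any():
            bad = frame.loc[dup, key_cols].iloc[0].to_dict()
            raise ValueError(f"duplicate results key: {bad}")
        ordered = key_cols + [c for c in frame.columns if c not in key_cols]
        frame = frame[ordered]
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return os.fspath(path)
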