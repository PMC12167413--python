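"""Core domain types for dynamic PET quantification.

Canonical conventions used throughout the package:

* time is expressed in **minutes** post-injection (all kinetic rate
  constants are per minute); frame definitions are stored in seconds as
  acquired and converted on demand,
* activity concentration is expressed in **kBq/cc**; standardized uptake
  values (SUV) are computed on demand and never stored as the canonical
  curve,
* frames are half-open intervals ``[start, start + duration)`` so that a
  contiguous schedule tiles the scan without double counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

SEC_PER_MIN = 60.0

#: Region labels in conventional reporting order (high-binding first).
REGION_ORDER = ("pons", "thalamus", "putamen", "frontal_cortex", "cerebellum")


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition time grid of a dynamic PET measurement.

    Parameters
    ----------
    frame_start_s
        Start time of each frame in seconds post-injection, ordered.
    frame_duration_s
        Duration of each frame in seconds; frames must be contiguous,
        i.e. ``start[i+1] == start[i] + duration[i]``.
    """

    frame_start_s: np.ndarray
    frame_duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start_s, dtype=float)
        dur = np.asarray(self.frame_duration_s, dtype=float)
        object.__setattr__(self, "frame_start_s", start)
        object.__setattr__(self, "frame_duration_s", dur)
        if start.ndim != 1 or start.size == 0 or start.shape != dur.shape:
            raise InvalidArgumentError("schedule needs matching non-empty start/duration arrays")
        if np.any(dur <= 0):
            raise InvalidArgumentError("all frame durations must be > 0")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], rtol=0, atol=1e-9):
            raise InvalidArgumentError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start_s.size)

    @property
    def frame_end_s(self) -> np.ndarray:
        return self.frame_start_s + self.frame_duration_s

    @property
    def total_duration_s(self) -> float:
        return float(self.frame_end_s[-1] - self.frame_start_s[0])

    @property
    def midpoints_min(self) -> np.ndarray:
        """Frame midpoints in minutes (the time points of a TAC)."""
        return (self.frame_start_s + self.frame_duration_s / 2.0) / SEC_PER_MIN

    @property
    def frame_start_min(self) -> np.ndarray:
        return self.frame_start_s / SEC_PER_MIN

    @property
    def frame_end_min(self) -> np.ndarray:
        return self.frame_end_s / SEC_PER_MIN

    @property
    def frame_duration_min(self) -> np.ndarray:
        return self.frame_duration_s / SEC_PER_MIN

    def truncated(self, duration_min: float) -> "FrameSchedule":
        """Keep only frames that end at or before ``duration_min``."""
        keep = self.frame_end_min <= duration_min + 1e-9
        if not np.any(keep):
            raise InvalidArgumentError(f"no frames end within {duration_min} min")
        return FrameSchedule(self.frame_start_s[keep], self.frame_duration_s[keep])


#: The 38-frame, 93-minute HRRT acquisition used throughout the package:
#: 9x10 s + 2x15 s + 3x20 s + 4x30 s + 4x60 s + 4x180 s + 12x360 s = 5580 s.
HRRT_38_FRAME_SPEC: tuple[tuple[int, float], ...] = (
    (9, 10), (2, 15), (3, 20), (4, 30), (4, 60), (4, 180), (12, 360),
)


def build_frame_schedule(spec: Sequence[tuple[int, float]]) -> FrameSchedule:
    """Expand a run-length schedule spec into a contiguous :class:`FrameSchedule`.

    ``spec`` is an ordered list of ``(count, duration_seconds)`` blocks,
    e.g. ``[(9, 10), (2, 15), ...]``.  The schedule starts at t = 0.
    """
    if len(spec) == 0:
        raise InvalidArgumentError("empty schedule spec")
    durations: list[float] = []
    for count, dur in spec:
        if count < 1:
            raise InvalidArgumentError(f"block count must be >= 1, got {count}")
        if dur <= 0:
            raise InvalidArgumentError(f"frame duration must be > 0, got {dur}")
        durations.extend([float(dur)] * int(count))
    dur_arr = np.asarray(durations)
    start = np.concatenate([[0.0], np.cumsum(dur_arr)[:-1]])
    return FrameSchedule(start, dur_arr)


def hrrt_38_frame_schedule() -> FrameSchedule:
    """The default 38-frame 93-min schedule."""
    return build_frame_schedule(HRRT_38_FRAME_SPEC)


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Frame midpoints in minutes: ``start + duration/2``."""
    return schedule.midpoints_min


@dataclass(frozen=True)
class TimeActivityCurve:
    """Regional tissue activity per frame.

    ``activity`` is the frame-averaged activity concentration in
    ``units`` (default kBq/cc) and must have one value per frame.
    Negative values can occur in noisy late frames and are permitted.
    """

    schedule: FrameSchedule
    activity: np.ndarray
    region_label: str = ""
    units: str = "kBq/cc"

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.shape != (self.schedule.n_frames,):
            raise InvalidArgumentError(
                f"activity length {act.size} != frame count {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(act)):
            raise InvalidArgumentError("activity values must be finite")

    @property
    def midpoints_min(self) -> np.ndarray:
        return self.schedule.midpoints_min

    def truncated(self, duration_min: float) -> "TimeActivityCurve":
        sched = self.schedule.truncated(duration_min)
        return replace(self, schedule=sched, activity=self.activity[: sched.n_frames])


@dataclass(frozen=True)
class SubjectMeta:
    """Injection and subject bookkeeping for one PET session."""

    subject_id: str
    session: str  # "test" or "retest"
    injected_activity_mbq: float
    body_weight_kg: float

    def __post_init__(self) -> None:
        if self.session not in ("test", "retest"):
            raise InvalidArgumentError(f"session must be 'test' or 'retest', got {self.session!r}")
        if not self.injected_activity_mbq > 0:
            raise InvalidArgumentError("injected activity must be > 0")
        if not self.body_weight_kg > 0:
            raise InvalidArgumentError("body weight must be > 0")


def to_suv(tac: TimeActivityCurve, meta: SubjectMeta) -> TimeActivityCurve:
    """Convert a kBq/cc TAC to standardized uptake values.

    SUV = tissue concentration (kBq/cc) / (injected activity (MBq) /
    body weight (kg)).  With the conventional 1 g/mL tissue density the
    result is dimensionless.
    """
    dose_per_weight = meta.injected_activity_mbq / meta.body_weight_kg  # MBq/kg == kBq/g
    return replace(tac, activity=tac.activity / dose_per_weight, units="SUV")


def _check_monotone(t: np.ndarray, what: str) -> None:
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError(f"{what} sample times must be strictly increasing")


@dataclass(frozen=True)
class BloodSampleTable:
    """Discrete arterial blood samples from one source.

    ``plasma_kbq_cc`` may contain NaN where plasma was not separated
    (the automatic sampler measures whole blood only).
    """

    time_min: np.ndarray
    whole_blood_kbq_cc: np.ndarray
    plasma_kbq_cc: np.ndarray | None = None
    source: str = "manual"  # "automatic" (ABSS) or "manual"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        wb = np.asarray(self.whole_blood_kbq_cc, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "whole_blood_kbq_cc", wb)
        if self.plasma_kbq_cc is not None:
            pl = np.asarray(self.plasma_kbq_cc, dtype=float)
            object.__setattr__(self, "plasma_kbq_cc", pl)
            if pl.shape != t.shape:
                raise InvalidArgumentError("plasma column length mismatch")
        if t.shape != wb.shape or t.ndim != 1:
            raise InvalidArgumentError("time and whole-blood arrays must match")
        if self.source not in ("automatic", "manual"):
            raise InvalidArgumentError(f"unknown blood source {self.source!r}")
        _check_monotone(t, "blood")


@dataclass(frozen=True)
class ParentFractionTable:
    """Measured fraction of plasma activity that is unchanged parent tracer."""

    time_min: np.ndarray
    parent_fraction: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        pf = np.asarray(self.parent_fraction, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "parent_fraction", pf)
        if t.shape != pf.shape or t.ndim != 1:
            raise InvalidArgumentError("time and fraction arrays must match")
        _check_monotone(t, "parent-fraction")
        if np.any(pf < 0) or np.any(pf > 1):
            raise InvalidArgumentError("parent fractions must lie in [0, 1]")
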