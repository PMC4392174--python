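"""Gait-cycle segmentation and walking/turning feature extraction.

The walking task is a fixed 25-foot (7.62 m) course with the phone strapped
to one ankle, so each dominant acceleration peak marks one gait cycle
(stride) of the instrumented leg. Features:

* CT — mean stride interval, freeze gaps excluded (s);
* SL — course length / stride count (m), no inertial double integration;
* SP — course length / ambulation time, first to last stride (m/s);
* AVG_ACC — mean absolute conditioned acceleration during ambulation (m/s^2).

Freezing-of-gait episodes appear as long gaps in the stride event train; any
inter-stride interval above a threshold (default 1.5 s, below the shortest
published freeze gap and above plausible slow strides) is reported as one
episode bounded by the flanking strides.

The 360-degree turning task yields the step count (NUM_TURN) and the turning
speed TURN_SP = 360 / active turn duration (degree/s), where the active
duration spans the first to last detected step padded by half the mean step
interval on each side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import InsufficientEventsError, ParameterError, TaskMismatchError
from .io import AccelerometerRecording, TestType
from .preprocessing import FilterSpec, condition_recording

__all__ = [
    "StrideEvents",
    "GaitFeatures",
    "TurnFeatures",
    "FreezeEpisode",
    "detect_strides",
    "detect_freeze_gaps",
    "extract_gait_features",
    "extract_turn_features",
    "WALK_DISTANCE_M",
    "FREEZE_THRESHOLD_S",
]

#: 25-foot walking course in metres.
WALK_DISTANCE_M = 7.62

#: Inter-stride interval above which a gap counts as a freezing episode (s).
FREEZE_THRESHOLD_S = 1.5

_MIN_STRIDE_DISTANCE_S = 0.6
_MIN_STEP_DISTANCE_S = 0.3
_PROMINENCE_FLOOR = 0.5
_PROMINENCE_FRAC = 0.2


@dataclass(frozen=True)
class StrideEvents:
    """Stride (or step) event times in seconds, strictly increasing."""

    event_times: np.ndarray

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.event_times)

    def __len__(self) -> int:
        return self.event_times.size


@dataclass(frozen=True)
class GaitFeatures:
    """Walking features: cycle time (s), stride length (m), speed (m/s), mean |a|."""

    ct: float
    sl: float
    sp: float
    avg_acc: float

    def as_dict(self) -> dict[str, float]:
        return {"CT": self.ct, "SL": self.sl, "SP": self.sp, "AVG_ACC": self.avg_acc}


@dataclass(frozen=True)
class TurnFeatures:
    """Turning features: step count and turning speed (degree/s)."""

    num_turn: int
    turn_sp: float

    def as_dict(self) -> dict[str, float]:
        return {"NUM_TURN": float(self.num_turn), "TURN_SP": self.turn_sp}


@dataclass(frozen=True)
class FreezeEpisode:
    """One freezing-of-gait episode bounded by the flanking stride events."""

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def _find_peaks(
    series: np.ndarray, fs: float, min_distance_s: float
) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    prominence = max(
        _PROMINENCE_FLOOR, _PROMINENCE_FRAC * float(np.percentile(np.abs(x), 90))
    )
    peaks, _ = signal.find_peaks(
        x, prominence=prominence, distance=max(1, int(round(min_distance_s * fs)))
    )
    return peaks / fs


def detect_strides(
    series: np.ndarray, fs: float, min_distance_s: float = _MIN_STRIDE_DISTANCE_S
) -> StrideEvents:
    """Locate stride events as prominent local maxima of the conditioned series.

    A peak counts when its prominence is at least max(0.5 m/s^2, 20 % of the
    90th-percentile amplitude) and it is at least ``min_distance_s`` from a
    larger peak. Fewer than two events raise :class:`InsufficientEventsError`.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2 * fs:
        raise ParameterError("detect_strides: need at least 2 s of data")
    times = _find_peaks(x, fs, min_distance_s)
    if times.size < 2:
        raise InsufficientEventsError(
            f"detect_strides: found {times.size} stride event(s), need at least 2"
        )
    return StrideEvents(event_times=times)


def detect_freeze_gaps(
    events: StrideEvents, threshold_s: float = FREEZE_THRESHOLD_S
) -> list[FreezeEpisode]:
    """Report one episode per inter-stride interval exceeding the threshold."""
    if len(events) < 2:
        raise ParameterError("detect_freeze_gaps: need at least 2 events")
    t = events.event_times
    gaps = np.flatnonzero(np.diff(t) > threshold_s)
    return [FreezeEpisode(start=float(t[i]), end=float(t[i + 1])) for i in gaps]


def extract_gait_features(
    rec: AccelerometerRecording,
    walk_distance: float = WALK_DISTANCE_M,
    freeze_threshold_s: float = FREEZE_THRESHOLD_S,
    include_freeze_in_ct: bool = False,
    filter_spec: FilterSpec | None = None,
) -> GaitFeatures:
    """Extract CT, SL, SP and AVG_ACC from a walking recording.

    CT averages the inter-stride intervals, excluding freeze gaps by default;
    SL divides the fixed course length by the stride count; SP divides it by
    the first-to-last-stride ambulation time; AVG_ACC averages the absolute
    conditioned series over the ambulation window.
    """
    if rec.metadata.test_type is not TestType.WALKING:
        raise TaskMismatchError(
            f"extract_gait_features: expected walking, got "
            f"{rec.metadata.test_type.value}"
        )
    if walk_distance <= 0:
        raise ParameterError("extract_gait_features: walk_distance must be positive")
    conditioned = condition_recording(rec, spec=filter_spec)
    events = detect_strides(conditioned, rec.fs)
    intervals = events.intervals
    if not include_freeze_in_ct:
        kept = intervals[intervals <= freeze_threshold_s]
        ct = float(kept.mean()) if kept.size else float(intervals.mean())
    else:
        ct = float(intervals.mean())
    span = float(events.event_times[-1] - events.event_times[0])
    i0 = int(round(events.event_times[0] * rec.fs))
    i1 = int(round(events.event_times[-1] * rec.fs)) + 1
    return GaitFeatures(
        ct=ct,
        sl=walk_distance / len(events),
        sp=walk_distance / span,
        avg_acc=float(np.abs(conditioned[i0:i1]).mean()),
    )


def extract_turn_features(
    rec: AccelerometerRecording, filter_spec: FilterSpec | None = None
) -> TurnFeatures:
    """Extract NUM_TURN and TURN_SP from a 360-degree turning recording.

    Step peaks are detected on the conditioned angular-rate magnitude
    (translational magnitude when angular rate is absent) with a 0.3 s
    minimum separation. The active turn duration is the first-to-last step
    span padded by half the mean step interval on each side; with a single
    detected step it falls back to the recording duration.
    """
    if rec.metadata.test_type is not TestType.TURNING:
        raise TaskMismatchError(
            f"extract_turn_features: expected turning, got "
            f"{rec.metadata.test_type.value}"
        )
    conditioned = condition_recording(rec, spec=filter_spec)
    times = _find_peaks(conditioned, rec.fs, _MIN_STEP_DISTANCE_S)
    if times.size == 0:
        raise InsufficientEventsError("extract_turn_features: no steps detected")
    if times.size == 1:
        active = rec.metadata.duration
    else:
        mean_interval = float(np.diff(times).mean())
        active = float(times[-1] - times[0]) + mean_interval
    if active <= 0:
        raise InsufficientEventsError("extract_turn_features: zero active duration")
    return TurnFeatures(num_turn=int(times.size), turn_sp=360.0 / active)
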