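"""Signal conditioning: low-pass filtering and zero-baseline calibration.

Every feature extractor works on a *conditioned* scalar series obtained by

1. collapsing the tri-axial samples to their Euclidean magnitude
   (orientation-robust for a strap-mounted phone),
2. zero-phase low-pass filtering (4th-order Butterworth, forward-backward),
3. subtracting the mean ("zero baseline"), which removes the gravity offset
   carried by the magnitude.

Default cutoffs are task-specific: 20 Hz for hand tremor (tremor content lies
below 20 Hz) and 10 Hz for walking/turning (gait content is concentrated at
2-5 Hz). A per-axis override is available for sensors with a known mounting
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ParameterError
from .io import AccelerometerRecording, TestType

__all__ = [
    "FilterSpec",
    "DEFAULT_CUTOFF_HZ",
    "lowpass_filter",
    "zero_baseline",
    "magnitude",
    "condition_recording",
]

#: Task-keyed default low-pass cutoff (Hz).
DEFAULT_CUTOFF_HZ = {
    TestType.HAND_TREMOR: 20.0,
    TestType.WALKING: 10.0,
    TestType.TURNING: 10.0,
}


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter specification (Butterworth only)."""

    cutoff_hz: float
    order: int = 4
    design: str = "butterworth"


def lowpass_filter(series: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase low-pass filter; output has the same length as the input.

    Applied forward and backward (``sosfiltfilt``) so the effective magnitude
    response is the squared Butterworth response and the phase is zero. Edge
    effects are handled by even (reflect) padding.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ParameterError("lowpass_filter: empty series")
    if not np.all(np.isfinite(x)):
        raise ParameterError("lowpass_filter: series contains non-finite values")
    if spec.design != "butterworth":
        raise ParameterError(f"lowpass_filter: unknown design '{spec.design}'")
    if not 0 < spec.cutoff_hz < fs / 2:
        raise ParameterError(
            f"lowpass_filter: cutoff {spec.cutoff_hz} Hz must lie in (0, fs/2={fs / 2})"
        )
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0, padtype="even")


def zero_baseline(series: np.ndarray) -> np.ndarray:
    """Subtract the mean so the output averages to zero (gravity calibration)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ParameterError("zero_baseline: empty series")
    if not np.all(np.isfinite(x)):
        raise ParameterError("zero_baseline: series contains non-finite values")
    return x - x.mean(axis=0)


def magnitude(samples: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of an ``(n, 3)`` tri-axial series."""
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ParameterError("magnitude: expected an (n, 3) array")
    return np.linalg.norm(arr, axis=1)


def condition_recording(
    rec: AccelerometerRecording,
    spec: FilterSpec | None = None,
    axis: int | None = None,
) -> np.ndarray:
    """Produce the conditioned scalar series for a recording.

    Turning recordings use the angular-rate magnitude when present (the
    turning task captures angular rate), all others the translational
    magnitude. ``axis`` selects a single raw axis instead of the magnitude.
    """
    if spec is None:
        spec = FilterSpec(cutoff_hz=DEFAULT_CUTOFF_HZ[rec.metadata.test_type])
    if rec.metadata.test_type is TestType.TURNING and rec.angular_rate is not None:
        source = rec.angular_rate
    else:
        source = rec.trans_acc
    series = source[:, axis] if axis is not None else magnitude(source)
    return zero_baseline(lowpass_filter(series, rec.fs, spec))
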