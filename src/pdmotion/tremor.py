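"""Hand-resting-tremor feature extraction.

Parkinsonian rest tremor is a 4-6 Hz oscillation of the relaxed limb, so the
feature set is spectral: power in the 4-6 Hz band (absolute and as a fraction
of 0-20 Hz power), the ratio of 3.5-15 Hz to 0.15-3.5 Hz power (tremor band
vs. voluntary/postural drift band), total 0-20 Hz power, the peak spectral
density, and the mean absolute acceleration.

The spectral estimate is a Welch periodogram: Hann window, 50 % overlap,
segment length min(10 s, record length). "Power" of a band is the trapezoidal
integral of the one-sided density over the band, in (m/s^2)^2; the peak power
is the maximum density value, in (m/s^2)^2/Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ParameterError, TaskMismatchError
from .io import AccelerometerRecording, TestType
from .preprocessing import FilterSpec, condition_recording

__all__ = [
    "SpectralEstimate",
    "TremorFeatures",
    "estimate_psd",
    "band_power",
    "extract_tremor_features",
    "tremor_features_from_series",
]

#: Floor on band-power denominators; avoids division by zero on band-free signals.
POWER_EPS = 1e-6

TREMOR_BAND = (4.0, 6.0)
TOTAL_BAND = (0.0, 20.0)
RATIO_NUM_BAND = (3.5, 15.0)
RATIO_DEN_BAND = (0.15, 3.5)


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided power spectral density: frequencies (Hz) and density values."""

    freqs: np.ndarray
    psd: np.ndarray


@dataclass(frozen=True)
class TremorFeatures:
    """The six tremor features.

    pf4_6
        Power in 4-6 Hz, (m/s^2)^2.
    pct_pf4_6
        Fraction of 0-20 Hz power lying in 4-6 Hz, in [0, 1].
    pr
        Power ratio 3.5-15 Hz over 0.15-3.5 Hz (dimensionless).
    pf0_20
        Total power 0-20 Hz, (m/s^2)^2.
    peak_power
        Maximum spectral density, (m/s^2)^2/Hz.
    avg_acc
        Mean absolute conditioned acceleration, m/s^2.
    """

    pf4_6: float
    pct_pf4_6: float
    pr: float
    pf0_20: float
    peak_power: float
    avg_acc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "PF4_6": self.pf4_6,
            "PCT_PF4_6": self.pct_pf4_6,
            "PR": self.pr,
            "PF0_20": self.pf0_20,
            "PEAK_POWER": self.peak_power,
            "AVG_ACC": self.avg_acc,
        }


def estimate_psd(series: np.ndarray, fs: float) -> SpectralEstimate:
    """Welch one-sided PSD with Hann window and 50 % overlap.

    Requires at least 2 s of data. The FFT length is padded to at least 4 s
    worth of samples so the frequency grid is never coarser than 0.25 Hz.
    The integral of the density over [0, fs/2] approximates the series
    variance (Parseval, within a few percent).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ParameterError("estimate_psd: expected a 1-D series")
    if x.size < 2 * fs:
        raise ParameterError("estimate_psd: need at least 2 s of data")
    nperseg = min(int(round(10 * fs)), x.size)
    nfft = max(nperseg, int(round(4 * fs)))
    freqs, psd = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=nfft,
        detrend="constant",
        scaling="density",
    )
    return SpectralEstimate(freqs=freqs, psd=psd)


def band_power(spec: SpectralEstimate, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi] Hz, endpoints inclusive.

    Boundary bins are split by linear interpolation of the density at the
    band edges.
    """
    fmax = float(spec.freqs[-1])
    if not (0 <= lo < hi <= fmax + 1e-9):
        raise ParameterError(
            f"band_power: band [{lo}, {hi}] must satisfy 0 <= lo < hi <= {fmax}"
        )
    hi = min(hi, fmax)
    inside = (spec.freqs > lo) & (spec.freqs < hi)
    grid = np.concatenate(([lo], spec.freqs[inside], [hi]))
    values = np.concatenate(
        (
            [np.interp(lo, spec.freqs, spec.psd)],
            spec.psd[inside],
            [np.interp(hi, spec.freqs, spec.psd)],
        )
    )
    return float(np.trapezoid(values, grid))


def tremor_features_from_series(series: np.ndarray, fs: float) -> TremorFeatures:
    """Compute the six features from an already-conditioned scalar series."""
    spec = estimate_psd(series, fs)
    pf4_6 = band_power(spec, *TREMOR_BAND)
    pf0_20 = band_power(spec, *TOTAL_BAND)
    pct = pf4_6 / pf0_20 if pf0_20 >= POWER_EPS else 0.0
    pr = band_power(spec, *RATIO_NUM_BAND) / max(
        band_power(spec, *RATIO_DEN_BAND), POWER_EPS
    )
    return TremorFeatures(
        pf4_6=pf4_6,
        pct_pf4_6=min(max(pct, 0.0), 1.0),
        pr=pr,
        pf0_20=pf0_20,
        peak_power=float(spec.psd.max()),
        avg_acc=float(np.abs(series).mean()),
    )


def extract_tremor_features(
    rec: AccelerometerRecording, filter_spec: FilterSpec | None = None
) -> TremorFeatures:
    """Condition a hand-tremor recording and extract the six tremor features."""
    if rec.metadata.test_type is not TestType.HAND_TREMOR:
        raise TaskMismatchError(
            f"extract_tremor_features: expected hand_tremor, got "
            f"{rec.metadata.test_type.value}"
        )
    if rec.metadata.duration < 5.0:
        raise ParameterError("extract_tremor_features: need at least 5 s of data")
    conditioned = condition_recording(rec, spec=filter_spec)
    return tremor_features_from_series(conditioned, rec.fs)
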