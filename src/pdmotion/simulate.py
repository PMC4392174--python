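"""Synthetic accelerometer recordings with ground truth.

Generates the three motor-task signals and a labeled 40-subject cohort so
the whole pipeline can be exercised and validated without patient data.

Signal models
-------------
* Hand tremor: a 4-6 Hz sinusoid riding on the gravity offset of the
  magnitude series, amplitude keyed to the UPDRS tremor item through
  published severity archetypes of mean absolute acceleration
  (0 / 0.47 / 1.7 / 4.0 / 6.0 m/s^2 for scores 0-4), intermittent bursts at
  moderate severity, plus white accelerometer noise.
* Walking: a quasi-periodic train of biphasic stride pulses (positive swing
  lobe, 1.5x larger negative stance lobe) on the vertical axis, with
  per-cycle timing jitter, optional silent freezing-of-gait gaps, and an
  optional calibration step that scales the pulse train so the conditioned
  mean absolute acceleration matches a requested target exactly.
* Turning: an angular-rate profile with a base yaw rate of 360/duration and
  one step pulse per pivot step, evenly placed so the extractor's padded
  active duration equals the true turn duration.

All generators are pure functions of (spec, seed). Ground-truth objects
carry the exact quantities the extractors are supposed to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError
from .gait import FREEZE_THRESHOLD_S
from .io import AccelerometerRecording, TestMetadata, TestType
from .preprocessing import (
    DEFAULT_CUTOFF_HZ,
    FilterSpec,
    lowpass_filter,
    magnitude,
    zero_baseline,
)

__all__ = [
    "GRAVITY",
    "TREMOR_AMPLITUDE_BY_SEVERITY",
    "WALK_PEAK_ACC_BY_SCORE",
    "TremorSimSpec",
    "GaitSimSpec",
    "TurnSimSpec",
    "CohortSpec",
    "TremorTruth",
    "WalkTruth",
    "TurnTruth",
    "Subject",
    "Cohort",
    "simulate_tremor",
    "simulate_walk",
    "simulate_turn",
    "simulate_cohort",
]

GRAVITY = 9.80665

#: Mean absolute tremor acceleration archetype per UPDRS tremor score 0-4 (m/s^2).
TREMOR_AMPLITUDE_BY_SEVERITY = (0.0, 0.47, 1.7, 4.0, 6.0)

#: Positive swing-peak acceleration archetype per UPDRS gait score 0-3 (m/s^2).
WALK_PEAK_ACC_BY_SCORE = (8.0, 5.0, 3.0, 3.0)

_STANCE_RATIO = 1.5  # negative stance lobe is 1.5x the positive swing lobe


# ---------------------------------------------------------------------------
# specs and ground truth


@dataclass(frozen=True)
class TremorSimSpec:
    """Hand-tremor generator parameters.

    ``amplitude`` is the target mean absolute tremor acceleration during
    active tremor (m/s^2); ``None`` selects the severity archetype.
    ``intermittency`` is the active fraction of the record (1.0 = continuous;
    moderate severity defaults to 0.5, emulating intermittent tremor).
    """

    severity: int = 0
    tremor_freq: Optional[float] = None  # Hz; None -> uniform in [4, 6]
    amplitude: Optional[float] = None
    intermittency: Optional[float] = None
    noise_sd: float = 0.1
    duration: float = 20.0
    fs: float = 100.0

    def resolved_amplitude(self) -> float:
        if self.amplitude is not None:
            return self.amplitude
        if not 0 <= self.severity <= 4:
            raise ParameterError("TremorSimSpec: severity must be in 0..4")
        return TREMOR_AMPLITUDE_BY_SEVERITY[self.severity]

    def resolved_intermittency(self) -> float:
        if self.intermittency is not None:
            if not 0 < self.intermittency <= 1:
                raise ParameterError("TremorSimSpec: intermittency must be in (0, 1]")
            return self.intermittency
        return 0.5 if self.severity == 2 else 1.0


@dataclass(frozen=True)
class GaitSimSpec:
    """Walking generator parameters.

    The walk-level cycle time is drawn from a normal distribution with mean
    ``ct_mean`` and SD ``ct_sd`` truncated symmetrically at 1.5 SD (so the
    draw keeps the nominal mean); per-cycle jitter is ``cycle_variability``
    (fractional SD). ``avg_acc_target`` requests calibration of the pulse
    amplitude so the conditioned mean absolute acceleration over the
    ambulation window equals the target.
    """

    ct_mean: float = 1.1
    ct_sd: float = 0.0
    peak_acc: float = 8.0
    cycle_variability: float = 0.05
    fog_gaps: Sequence[tuple[float, float]] = ()
    course_length: float = 7.62
    noise_sd: float = 0.2
    n_strides: Optional[int] = None
    avg_acc_target: Optional[float] = None
    fs: float = 100.0


@dataclass(frozen=True)
class TurnSimSpec:
    """360-degree turn generator parameters."""

    n_steps: int = 3
    total_duration: float = 4.55  # s; 360/4.55 ~ 79 degree/s
    step_peak: float = 80.0  # degree/s above base rate
    noise_sd: float = 3.0
    fs: float = 100.0


@dataclass(frozen=True)
class TremorTruth:
    mean_abs_acc: float  # over the full record, noise-free
    active_mean_abs_acc: float  # during tremor bursts
    tremor_freq: float
    active_fraction: float


@dataclass(frozen=True)
class WalkTruth:
    stride_times: np.ndarray
    ct: float  # mean inter-stride interval, freeze gaps excluded
    sl: float
    sp: float
    mean_abs_acc: float  # conditioned, noise-free, ambulation window
    fog_gaps: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class TurnTruth:
    n_steps: int
    total_duration: float
    turn_sp: float


def _metadata(test_type: TestType, n: int, fs: float, user_id: str) -> TestMetadata:
    return TestMetadata(
        sampling_rate=fs,
        duration=n / fs,
        date="2015-01-01T00:00:00",
        test_type=test_type,
        user_id=user_id,
    )


# ---------------------------------------------------------------------------
# tremor


def _tremor_gate(t: np.ndarray, active_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """0/1 burst envelope with the requested active fraction, smoothed 0.1 s."""
    if active_fraction >= 1.0:
        return np.ones_like(t)
    period = 4.0  # s per on/off cycle
    offset = rng.uniform(0, period)
    phase = ((t + offset) % period) / period
    gate = (phase < active_fraction).astype(float)
    # smooth the edges to keep the burst spectrum near the carrier frequency
    fs = 1.0 / (t[1] - t[0])
    width = max(3, int(round(0.1 * fs)))
    kernel = np.hanning(width)
    kernel /= kernel.sum()
    return np.convolve(gate, kernel, mode="same")


def simulate_tremor(
    spec: TremorSimSpec, seed: int, user_id: str = "sim"
) -> tuple[AccelerometerRecording, TremorTruth]:
    """Generate one hand-tremor recording plus exact ground truth."""
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    freq = spec.tremor_freq if spec.tremor_freq is not None else rng.uniform(4.0, 6.0)
    target = spec.resolved_amplitude()
    active = spec.resolved_intermittency()
    # mean |a sin| = 2a/pi, so the sinusoid peak for a mean-abs target is
    # target * pi / 2
    peak = target * np.pi / 2.0
    gate = _tremor_gate(t, active, rng)
    tremor = peak * gate * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    noise = rng.normal(0.0, spec.noise_sd, size=(n, 3)) if spec.noise_sd > 0 else np.zeros((n, 3))
    trans = np.zeros((n, 3))
    trans[:, 2] = GRAVITY + tremor
    trans += noise
    rec = AccelerometerRecording(
        metadata=_metadata(TestType.HAND_TREMOR, n, spec.fs, user_id),
        trans_acc=trans,
    )
    truth = TremorTruth(
        mean_abs_acc=float(np.abs(tremor).mean()),
        active_mean_abs_acc=target,
        tremor_freq=float(freq),
        active_fraction=active,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# walking


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n_sigma: float = 1.5
) -> float:
    """Normal draw truncated symmetrically at +-n_sigma (keeps the mean)."""
    if sd <= 0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= n_sigma * sd:
            return x


def _stride_times(
    rng: np.random.Generator, spec: GaitSimSpec, ct_walk: float
) -> np.ndarray:
    """Stride instants: walking bouts separated by silent freeze gaps.

    Each bout between gaps is spaced at near-ct intervals, re-normalized so a
    stride lands exactly on each gap boundary (the subject freezes right
    after a stride and resumes with one). Free walking continues after the
    last gap until the target stride count is reached.
    """
    n_target = spec.n_strides
    if n_target is None:
        n_target = max(3, int(round(spec.course_length / 1.26)))
    times = [1.0]

    def jittered_step() -> float:
        return ct_walk * max(
            1.0 + spec.cycle_variability * rng.standard_normal(), 0.3
        )

    def extend_to(end: float) -> None:
        span = end - times[-1]
        m = max(1, int(round(span / ct_walk)))
        steps = np.array([jittered_step() for _ in range(m)])
        steps *= span / steps.sum()
        for s in steps[:-1]:
            times.append(times[-1] + s)
        times.append(end)

    for gs, ge in sorted(spec.fog_gaps):
        if gs > times[-1]:
            extend_to(gs)
        times.append(ge)
    while len(times) < n_target:
        times.append(times[-1] + jittered_step())
    return np.asarray(times)


def _walk_pulse_train(
    t: np.ndarray, stride_times: np.ndarray, peak: float, ct_walk: float
) -> np.ndarray:
    """Biphasic stride pulses: swing lobe up, 1.5x stance lobe down."""
    s = np.zeros_like(t)
    stance_delay = min(0.3 * ct_walk, 0.5)
    for tau in stride_times:
        s += peak * np.exp(-0.5 * ((t - tau) / 0.07) ** 2)
        s -= _STANCE_RATIO * peak * np.exp(-0.5 * ((t - tau - stance_delay) / 0.09) ** 2)
    return s


def _conditioned_walk(series_z: np.ndarray, fs: float) -> np.ndarray:
    mag = np.abs(series_z)  # magnitude of (0, 0, z) is |z|
    spec = FilterSpec(cutoff_hz=DEFAULT_CUTOFF_HZ[TestType.WALKING])
    return zero_baseline(lowpass_filter(mag, fs, spec))


def simulate_walk(
    spec: GaitSimSpec, seed: int, user_id: str = "sim"
) -> tuple[AccelerometerRecording, WalkTruth]:
    """Generate one 25-foot-walk recording plus exact ground truth.

    When ``avg_acc_target`` is set, the noise-free pulse train is rescaled by
    root finding so that the conditioned mean absolute acceleration over the
    ambulation window equals the target (the same conditioning the extractor
    applies), then noise is added.
    """
    rng = np.random.default_rng(seed)
    ct_walk = max(_truncated_normal(rng, spec.ct_mean, spec.ct_sd), 0.5)
    stride_times = _stride_times(rng, spec, ct_walk)
    duration = stride_times[-1] + 1.0
    n = int(round(duration * spec.fs))
    t = np.arange(n) / spec.fs
    s = _walk_pulse_train(t, stride_times, spec.peak_acc, ct_walk)

    i0 = int(round(stride_times[0] * spec.fs))
    i1 = int(round(stride_times[-1] * spec.fs)) + 1

    def window_mean_abs(scale: float) -> float:
        cond = _conditioned_walk(GRAVITY + scale * s, spec.fs)
        return float(np.abs(cond[i0:i1]).mean())

    scale = 1.0
    if spec.avg_acc_target is not None:
        target = spec.avg_acc_target
        hi = 1.0
        while window_mean_abs(hi) < target and hi < 64.0:
            hi *= 2.0
        scale = brentq(lambda c: window_mean_abs(c) - target, 1e-6, hi, xtol=1e-6)
    signal_z = GRAVITY + scale * s
    mean_abs_clean = window_mean_abs(scale)

    trans = rng.normal(0.0, spec.noise_sd, size=(n, 3)) if spec.noise_sd > 0 else np.zeros((n, 3))
    trans[:, 2] += signal_z
    rec = AccelerometerRecording(
        metadata=_metadata(TestType.WALKING, n, spec.fs, user_id),
        trans_acc=trans,
    )
    intervals = np.diff(stride_times)
    kept = intervals[intervals <= FREEZE_THRESHOLD_S]
    ct_true = float(kept.mean()) if kept.size else float(intervals.mean())
    truth = WalkTruth(
        stride_times=stride_times,
        ct=ct_true,
        sl=spec.course_length / stride_times.size,
        sp=spec.course_length / float(stride_times[-1] - stride_times[0]),
        mean_abs_acc=mean_abs_clean,
        fog_gaps=tuple(tuple(g) for g in spec.fog_gaps),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# turning


def simulate_turn(
    spec: TurnSimSpec, seed: int, user_id: str = "sim"
) -> tuple[AccelerometerRecording, TurnTruth]:
    """Generate one 360-degree-turn recording plus exact ground truth.

    The ``n`` step pulses sit at the centres of ``n`` equal sub-intervals of
    the turn, so the extractor's padded active duration reproduces the true
    total duration and 360/duration the true turning speed.
    """
    if spec.n_steps < 1:
        raise ParameterError("simulate_turn: n_steps must be >= 1")
    if spec.total_duration <= 0:
        raise ParameterError("simulate_turn: total_duration must be positive")
    rng = np.random.default_rng(seed)
    start = 0.5
    T = spec.total_duration
    step_times = start + (np.arange(spec.n_steps) + 0.5) * T / spec.n_steps
    duration = T + 2 * start
    n = int(round(duration * spec.fs))
    t = np.arange(n) / spec.fs
    base_rate = 360.0 / T
    window = 1.0 / (1.0 + np.exp(-(t - start) / 0.05))
    window *= 1.0 / (1.0 + np.exp((t - start - T) / 0.05))
    yaw = base_rate * window
    for tau in step_times:
        yaw += spec.step_peak * np.exp(-0.5 * ((t - tau) / 0.05) ** 2)
    angular = rng.normal(0.0, spec.noise_sd, size=(n, 3)) if spec.noise_sd > 0 else np.zeros((n, 3))
    angular[:, 2] += yaw
    trans = np.zeros((n, 3))
    trans[:, 2] = GRAVITY
    trans += rng.normal(0.0, 0.05, size=(n, 3))
    rec = AccelerometerRecording(
        metadata=_metadata(TestType.TURNING, n, spec.fs, user_id),
        trans_acc=trans,
        angular_rate=angular,
    )
    truth = TurnTruth(n_steps=spec.n_steps, total_duration=T, turn_sp=360.0 / T)
    return rec, truth


# ---------------------------------------------------------------------------
# cohort


def _scaled_counts(weights: Sequence[float], total: int) -> tuple[int, ...]:
    """Largest-remainder apportionment of ``total`` over ``weights``."""
    raw = np.asarray(weights, dtype=float) * total / float(np.sum(weights))
    base = np.floor(raw).astype(int)
    order = np.argsort(-(raw - base))
    for i in order[: total - base.sum()]:
        base[i] += 1
    return tuple(int(c) for c in base)


@dataclass(frozen=True)
class CohortSpec:
    """Composition of the simulated study cohort.

    Defaults mirror the published 40-subject study: Hoehn & Yahr stages
    1-4 with 6/13/12/9 subjects, 9 subjects with freezing of gait and 11
    with other gait difficulty (20 subjects with UPDRS gait score >= 2).
    With a different ``n_subjects`` the unspecified counts are rescaled
    proportionally.
    """

    n_subjects: int = 40
    stage_distribution: Optional[tuple[int, int, int, int]] = None
    fog_count: Optional[int] = None
    gait_difficulty_count: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ParameterError("CohortSpec: need at least 10 subjects")
        if self.stage_distribution is None:
            object.__setattr__(
                self,
                "stage_distribution",
                _scaled_counts((6, 13, 12, 9), self.n_subjects),
            )
        if self.fog_count is None:
            object.__setattr__(
                self, "fog_count", int(round(9 / 40 * self.n_subjects))
            )
        if self.gait_difficulty_count is None:
            object.__setattr__(
                self, "gait_difficulty_count", int(round(11 / 40 * self.n_subjects))
            )
        if sum(self.stage_distribution) != self.n_subjects:
            raise ParameterError(
                "CohortSpec: stage_distribution must sum to n_subjects"
            )
        if self.fog_count + self.gait_difficulty_count > self.n_subjects - 5:
            raise ParameterError(
                "CohortSpec: fog_count + gait_difficulty_count leaves fewer than "
                "5 subjects without gait difficulty"
            )


@dataclass
class Subject:
    subject_id: str
    hoehn_yahr: int
    tremor_updrs: int
    gait_updrs: int
    fog: bool
    tremor_rec: AccelerometerRecording
    walk_rec: AccelerometerRecording
    turn_rec: AccelerometerRecording
    tremor_truth: TremorTruth
    walk_truth: WalkTruth
    turn_truth: TurnTruth

    @property
    def tremor_present(self) -> bool:
        return self.tremor_updrs >= 1

    @property
    def gait_difficulty(self) -> bool:
        return self.gait_updrs >= 2


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[Subject] = field(default_factory=list)

    def labels_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "hoehn_yahr": [s.hoehn_yahr for s in self.subjects],
                "tremor_updrs": [s.tremor_updrs for s in self.subjects],
                "gait_updrs": [s.gait_updrs for s in self.subjects],
                "tremor_present": [s.tremor_present for s in self.subjects],
                "gait_difficulty": [s.gait_difficulty for s in self.subjects],
                "fog": [s.fog for s in self.subjects],
            }
        )


def _item_given_stage(rng: np.random.Generator, stage: int) -> int:
    """UPDRS item score given stage: discretized Gaussian centred at stage-1."""
    return int(np.clip(round(rng.normal(stage - 1, 0.6)), 0, 4))


def _adjust_counts(
    rng: np.random.Generator,
    scores: np.ndarray,
    stages: np.ndarray,
    threshold: int,
    target_at_or_above: int,
) -> np.ndarray:
    """Minimally nudge item scores so exactly `target` subjects are >= threshold.

    Demotions pick the lowest-stage borderline subjects, promotions the
    highest-stage ones, with random tie-breaking.
    """
    scores = scores.copy()
    jitter = rng.uniform(0, 0.1, size=scores.size)
    while (scores >= threshold).sum() > target_at_or_above:
        cand = np.flatnonzero(scores == threshold)
        if cand.size == 0:
            cand = np.flatnonzero(scores >= threshold)
        i = cand[np.argmin(stages[cand] + jitter[cand])]
        scores[i] = threshold - 1
    while (scores >= threshold).sum() < target_at_or_above:
        cand = np.flatnonzero(scores == threshold - 1)
        if cand.size == 0:
            cand = np.flatnonzero(scores < threshold)
        i = cand[np.argmax(stages[cand] + jitter[cand])]
        scores[i] = threshold
    return scores


# group parameter distributions (mean, SD) for walking/turning, keyed by
# gait-difficulty status (UPDRS gait score < 2 vs >= 2)
_CT_BY_GROUP = {False: (1.1, 0.32), True: (1.22, 0.49)}
_SL_BY_GROUP = {False: (1.26, 0.17), True: (1.07, 0.29)}
_AVG_ACC_BY_GROUP = {False: (5.2, 1.1), True: (3.6, 1.7)}
_NUM_TURN_BY_GROUP = {False: (3.1, 0.9), True: (5.4, 1.1)}
_TURN_SP_BY_GROUP = {False: (79.1, 8.49), True: (53.7, 6.98)}


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the labeled cohort with recordings for all three tasks.

    Stages follow the configured distribution exactly; UPDRS tremor and gait
    items are sampled conditional on stage (discretized Gaussian centred at
    stage-1), with the gait items nudged so the gait-difficulty group has
    exactly ``fog_count + gait_difficulty_count`` members and each detector
    class keeps at least 5 members for stratified 5-fold cross-validation.
    Per-subject signal parameters are drawn from the published group
    distributions.
    """
    rng = np.random.default_rng(spec.seed)
    stages = np.repeat(
        np.arange(1, 5), spec.stage_distribution
    )
    rng.shuffle(stages)
    n = spec.n_subjects
    tremor_items = np.array([_item_given_stage(rng, s) for s in stages])
    gait_items = np.array([_item_given_stage(rng, s) for s in stages])
    gait_items = np.clip(gait_items, 0, 3)

    gd_total = spec.fog_count + spec.gait_difficulty_count
    gait_items = _adjust_counts(rng, gait_items, stages, 2, gd_total)
    # keep both tremor classes large enough for stratified 5-fold CV
    n_present = int((tremor_items >= 1).sum())
    tremor_items = _adjust_counts(
        rng, tremor_items, stages, 1, int(np.clip(n_present, 5, n - 5))
    )

    gd_idx = np.flatnonzero(gait_items >= 2)
    fog_idx = set(rng.choice(gd_idx, size=min(spec.fog_count, gd_idx.size), replace=False))

    cohort = Cohort(spec=spec)
    for i in range(n):
        sid = f"subj{i:03d}"
        gd = bool(gait_items[i] >= 2)
        seeds = rng.integers(0, 2**31 - 1, size=3)

        amp = TREMOR_AMPLITUDE_BY_SEVERITY[tremor_items[i]]
        amp *= float(np.exp(rng.normal(0.0, 0.15))) if amp > 0 else 1.0
        tremor_spec = TremorSimSpec(severity=int(tremor_items[i]), amplitude=amp)
        tremor_rec, tremor_truth = simulate_tremor(tremor_spec, int(seeds[0]), sid)

        ct_mean, ct_sd = _CT_BY_GROUP[gd]
        sl_mean, sl_sd = _SL_BY_GROUP[gd]
        aa_mean, aa_sd = _AVG_ACC_BY_GROUP[gd]
        sl = max(_truncated_normal(rng, sl_mean, sl_sd), 0.6)
        n_strides = int(np.clip(round(7.62 / sl), 3, 12))
        fog_gaps: tuple[tuple[float, float], ...] = ()
        if i in fog_idx:
            gap_start = rng.uniform(2.5, 4.0)
            gap_len = rng.uniform(1.7, 2.3)
            fog_gaps = ((gap_start, gap_start + gap_len),)
        walk_spec = GaitSimSpec(
            ct_mean=ct_mean,
            ct_sd=ct_sd,
            peak_acc=WALK_PEAK_ACC_BY_SCORE[gait_items[i]],
            fog_gaps=fog_gaps,
            n_strides=n_strides,
            avg_acc_target=max(_truncated_normal(rng, aa_mean, aa_sd, 2.0), 0.8),
        )
        walk_rec, walk_truth = simulate_walk(walk_spec, int(seeds[1]), sid)

        nt_mean, nt_sd = _NUM_TURN_BY_GROUP[gd]
        sp_mean, sp_sd = _TURN_SP_BY_GROUP[gd]
        n_steps = max(1, int(round(_truncated_normal(rng, nt_mean, nt_sd, 2.0))))
        turn_speed = max(_truncated_normal(rng, sp_mean, sp_sd, 2.0), 20.0)
        turn_spec = TurnSimSpec(n_steps=n_steps, total_duration=360.0 / turn_speed)
        turn_rec, turn_truth = simulate_turn(turn_spec, int(seeds[2]), sid)

        cohort.subjects.append(
            Subject(
                subject_id=sid,
                hoehn_yahr=int(stages[i]),
                tremor_updrs=int(tremor_items[i]),
                gait_updrs=int(gait_items[i]),
                fog=i in fog_idx,
                tremor_rec=tremor_rec,
                walk_rec=walk_rec,
                turn_rec=turn_rec,
                tremor_truth=tremor_truth,
                walk_truth=walk_truth,
                turn_truth=turn_truth,
            )
        )
    return cohort
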