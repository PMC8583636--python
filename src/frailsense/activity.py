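"""Exercise parameterization: repetitions, activity class, metabolic cost.

The smart-vest accelerometer sees each repetition of a maintenance
exercise (and each step or pedal stroke) as one sawtooth cycle on a
dominant axis.  Parameterization selects the dominant axis by band-power
in 0.2–3 Hz, segments cycles with the hysteresis engine, and everything
else is bookkeeping: counting accepted cycles inside exercise-specific
period bounds, nearest-signature activity classification, and a linear
activity-counts → MET mapping anchored at 1 MET (rest) and 3.5 MET
(walking at the reference gait amplitude), converted to kcal/min via the
standard 3.5 ml O₂/kg/min equivalence.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .config import DetectorConfig, PersonProfile
from .errors import InsufficientSignal, MissingProfile
from .impact import signal_energy
from .sawtooth import SawtoothCycle, bandpass, movement_hysteresis, segment_cycles
from .streams import GRAVITY, AccelStream, ActivityKind
from .synthetic import EXERCISE_TEMPLATES

#: Dominant-axis selection band, Hz.
EXERCISE_BAND = (0.2, 3.0)

#: Conditioning band for cycle segmentation, Hz — a wider low edge so the
#: slowest maintenance-exercise cycles (4–5 s) keep their full amplitude.
CONDITION_BAND = (0.05, 3.5)

#: Shortest plausible repetition, seconds.
MIN_CYCLE_S = 0.25

#: Accepted period range relative to the exercise's nominal period.
PERIOD_BOUNDS = (0.5, 2.0)

#: Metabolic epoch length, seconds (shortest that spans several slow cycles).
EPOCH_S = 10.0

_AXES = "xyz"


@dataclass
class ActivityReport:
    exercise: ActivityKind
    n_repetitions: int
    elapsed_s: float
    instantaneous_kcal_min: list = field(default_factory=list)  # (epoch mid-time, kcal/min)
    cumulative_kcal: float = 0.0


def dominant_axis(stream: AccelStream, band=EXERCISE_BAND) -> int:
    """Axis with the largest band-power in the exercise band."""
    powers = [float(np.var(bandpass(stream.a[:, k], stream.fs, *band)))
              for k in range(3)]
    return int(np.argmax(powers))


def parameterize_sawtooth(stream: AccelStream,
                          config: DetectorConfig | None = None) -> list[SawtoothCycle]:
    """Abstract the dominant-axis waveform into sawtooth cycles.

    A cycle is accepted only when its peak-to-trough amplitude exceeds the
    floor derived from the movement-activity energy threshold.
    """
    config = config or DetectorConfig()
    if stream.duration < 2.0:
        raise InsufficientSignal("need at least 2 s of accelerometry")
    axis = dominant_axis(stream)
    h = movement_hysteresis(config.movement_activity_energy_threshold)
    cycles = segment_cycles(
        stream.a[:, axis], stream.fs, CONDITION_BAND, h,
        min_period=MIN_CYCLE_S, dominant_axis=_AXES[axis],
    )
    if stream.t0:
        for c in cycles:
            c.start_time += stream.t0
            c.peak_time += stream.t0
            c.end_time += stream.t0
    return cycles


@functools.lru_cache(maxsize=8)
def _reference_features(hysteresis_key: float) -> dict[ActivityKind, tuple[int, float, float, float]]:
    """Signature per kind measured by the same pipeline on noiseless templates.

    Measuring (rather than reading the template table) keeps classification
    consistent with any band-pass attenuation of the conditioning stage.
    """
    from .synthetic import gen_exercise  # local import avoids a cycle at import time

    config = DetectorConfig()
    refs = {}
    for kind in EXERCISE_TEMPLATES:
        if kind in (ActivityKind.WALKING, ActivityKind.CYCLING):
            ls = gen_exercise(kind, duration=12.0, noise_sd=0.0, seed=0)
        else:
            ls = gen_exercise(kind, n_reps=6, noise_sd=0.0, seed=0)
        cycles = parameterize_sawtooth(ls.stream, config)
        refs[kind] = _feature_vector(ls.stream, cycles)
    return refs


def _feature_vector(stream: AccelStream, cycles: list[SawtoothCycle]):
    periods = np.array([c.period for c in cycles])
    amps = np.array([c.amplitude for c in cycles])
    rises = np.array([c.rise_duration / c.period for c in cycles])
    axis = _AXES.index(cycles[0].dominant_axis) if cycles else 0
    return (axis, float(np.median(periods)), float(np.median(amps)),
            float(np.median(rises)))


def classify_activity(stream: AccelStream,
                      config: DetectorConfig | None = None) -> tuple[ActivityKind, str]:
    """Nearest-signature classification; returns (kind, body region)."""
    config = config or DetectorConfig()
    cycles = parameterize_sawtooth(stream, config)
    if len(cycles) < 3:
        raise InsufficientSignal("need at least 3 cycles to classify an activity")
    axis, period, amp, rise = _feature_vector(stream, cycles)
    refs = _reference_features(round(
        movement_hysteresis(config.movement_activity_energy_threshold), 6))
    best, best_d = None, np.inf
    for kind, (r_axis, r_period, r_amp, r_rise) in refs.items():
        d = (
            (0.0 if axis == r_axis else 100.0)
            + np.log(period / r_period) ** 2
            + np.log(amp / r_amp) ** 2
            + 0.5 * ((rise - r_rise) / 0.15) ** 2
        )
        if d < best_d:
            best, best_d = kind, d
    region = EXERCISE_TEMPLATES[best][4]
    return best, region


def _movement_energy(stream: AccelStream) -> np.ndarray:
    """Windowed variance (1 s) of the conditioned dominant-axis trace.

    The magnitude ‖a‖ is second-order insensitive to oscillation orthogonal
    to gravity, so the resting test runs on the same conditioned trace the
    cycles are segmented from.
    """
    from .impact import moving_variance

    axis = dominant_axis(stream)
    xf = bandpass(stream.a[:, axis], stream.fs, *CONDITION_BAND)
    return moving_variance(xf, int(round(stream.fs)) | 1)


@dataclass
class RepetitionCount:
    count: int
    cycles: list
    rejected_period: int
    rejected_resting: int


def count_repetitions(stream: AccelStream, exercise: ActivityKind,
                      config: DetectorConfig | None = None) -> RepetitionCount:
    """Count repetitions (steps for walking, strokes for cycling).

    The exercise is user-selected; its nominal period bounds the accepted
    cycle periods, and cycles peaking inside resting segments (windowed
    energy below the resting threshold) are excluded.
    """
    config = config or DetectorConfig()
    exercise = ActivityKind(exercise)
    if exercise not in EXERCISE_TEMPLATES:
        raise ValueError(f"{exercise.value} is not a countable exercise")
    nominal = EXERCISE_TEMPLATES[exercise][1]
    cycles = parameterize_sawtooth(stream, config)
    energy = _movement_energy(stream)
    lo, hi = PERIOD_BOUNDS[0] * nominal, PERIOD_BOUNDS[1] * nominal
    accepted = []
    rej_p = rej_r = 0
    for c in cycles:
        if not (lo <= c.period <= hi):
            rej_p += 1
            continue
        i0 = max(0, int(round((c.start_time - stream.t0) * stream.fs)))
        i1 = min(len(energy), int(round((c.end_time - stream.t0) * stream.fs)) + 1)
        # a genuine cycle shows movement-level energy somewhere in its span
        if i1 <= i0 or float(energy[i0:i1].max()) < config.resting_energy_threshold:
            rej_r += 1
            continue
        accepted.append(c)
    return RepetitionCount(count=len(accepted), cycles=accepted,
                           rejected_period=rej_p, rejected_resting=rej_r)


def precision(counted: int, true: int) -> float:
    """100 × (1 − |counted − true| / true), the repetition-count precision."""
    if true <= 0:
        raise ValueError("true count must be positive")
    return 100.0 * (1.0 - abs(counted - true) / true)


@functools.lru_cache(maxsize=1)
def _walking_reference_counts() -> float:
    """Mean rectified band-passed magnitude of the reference walking signal."""
    from .synthetic import gen_exercise

    ls = gen_exercise(ActivityKind.WALKING, duration=30.0, noise_sd=0.0, seed=0)
    stream = ls.stream
    dyn = bandpass(stream.magnitude() - GRAVITY, stream.fs, *EXERCISE_BAND)
    active = slice(int(1.0 * stream.fs), int((stream.duration - 1.0) * stream.fs))
    return float(np.mean(np.abs(dyn[active])))


def estimate_met(stream: AccelStream, profile: PersonProfile,
                 config: DetectorConfig | None = None,
                 exercise: ActivityKind | None = None) -> ActivityReport:
    """Per-epoch metabolic expenditure from activity counts.

    Counts (mean rectified band-passed ‖a‖) map linearly to MET, anchored
    at 1 MET for rest and 3.5 MET at the reference walking amplitude;
    epochs whose energy sits below the resting threshold are floored at
    1.0 MET.  kcal/min = MET × 3.5 × weight / 200.  Epochs with an upward
    vertical excursion beyond the ascending displacement threshold are
    tagged ascending in the report series.
    """
    config = config or DetectorConfig()
    if profile is None or getattr(profile, "weight_kg", None) in (None, 0):
        raise MissingProfile("weight is required for metabolic estimation")
    n = len(stream)
    report = ActivityReport(
        exercise=exercise or ActivityKind.WALKING,
        n_repetitions=0,
        elapsed_s=stream.duration,
    )
    if n == 0:
        return report
    dyn = bandpass(stream.magnitude() - GRAVITY, stream.fs, *EXERCISE_BAND) \
        if n >= 24 else stream.magnitude() - GRAVITY
    energy = signal_energy(stream, int(round(stream.fs)) | 1)
    c_ref = _walking_reference_counts()
    epoch = int(round(EPOCH_S * stream.fs))
    rates = []
    from .falls import vertical_displacement
    from .impact import ImpactWindow

    for i0 in range(0, n, epoch):
        i1 = min(n, i0 + epoch)
        counts = float(np.mean(np.abs(dyn[i0:i1])))
        if float(np.median(energy[i0:i1])) < config.resting_energy_threshold:
            met = 1.0
        else:
            met = 1.0 + 2.5 * counts / c_ref
        kcal_min = met * 3.5 * profile.weight_kg / 200.0
        ascending = False
        if i1 - i0 >= stream.fs:
            w = ImpactWindow(impact_index=i0, impact_time=stream.t0 + i0 / stream.fs,
                             samples=stream.a[i0:i1], peak_energy=0.0, fs=stream.fs)
            try:
                ascending = vertical_displacement(w) >= config.ascending_displacement_threshold
            except Exception:
                ascending = False
        mid_t = stream.t0 + (i0 + i1) / 2.0 / stream.fs
        rates.append((float(mid_t), float(kcal_min), bool(ascending)))
    report.instantaneous_kcal_min = rates
    # cumulative expenditure: time-integral of the piecewise-constant rate
    total = 0.0
    for k, (_, kcal_min, _) in enumerate(rates):
        i0 = k * epoch
        i1 = min(n, i0 + epoch)
        total += kcal_min * ((i1 - i0) / stream.fs) / 60.0
    report.cumulative_kcal = total
    if exercise is not None:
        report.n_repetitions = count_repetitions(stream, exercise, config).count
    return report
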