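"""Synthetic accelerometry and respiratory waveforms with ground truth.

No public dataset exists for the laboratory validation protocol these
algorithms were designed around, so every downstream stage is exercised
against generated signals that reproduce its kinematic and temporal
structure: five fall-free daily activities, three fall types, fifteen
static maintenance exercises plus walking and cycling, and a controlled
breathing ramp.

Signal models (the simplest kinematics that exercise every detector
feature):

* Falls — a quiescent standing phase, a sub-gravity descent pulse that
  accumulates the drop height, an impact half-sine whose peak is drawn
  from 30–60 m/s², and a trunk rotation from vertical to horizontal.  The
  device reads the specific force rotated into its own frame, so the
  magnitude ‖a‖ is orientation-free and equals ``g + z̈`` of the trunk.
* Fall-free ADLs — gravity-dominated streams with bounded oscillation
  (gait harmonics) or slow, low-energy posture transients (sitting,
  bending) that never satisfy the fall signature.
* Exercises — asymmetric-triangle ("sawtooth") oscillations on a per-kind
  dominant axis at a per-kind cadence and amplitude, riding on gravity.
* Breathing — raised-cosine inspiration/expiration ramps with a 40%
  inspiratory fraction.

Noise is additive band-limited Gaussian noise (white noise low-passed at
1 Hz and rescaled to the requested per-sample SD): at the sacrum and
thorax the dominant perturbation is low-frequency soft-tissue and
postural sway, not wide-band sensor noise, which for this accelerometer
is two orders of magnitude below the movement signals.

All generators are deterministic in (parameters, seed) and sample at
exactly 40 Hz starting at t = 0.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .streams import (
    GRAVITY,
    DEFAULT_FS,
    ADL_PROTOCOL_KINDS,
    FALL_PROTOCOL_KINDS,
    FALL_KINDS,
    STATIC_EXERCISE_KINDS,
    LOCOMOTION_KINDS,
    AccelStream,
    ActivityKind,
    LabeledStream,
    RespSignal,
    Truth,
)

#: Cut-off of the band-limited noise model, Hz.
NOISE_CUTOFF_HZ = 0.2

#: Inspiratory fraction of a breath cycle.
INSP_FRACTION = 0.4

#: Exercise waveform table: kind -> (axis index, period s, peak-to-trough
#: amplitude m/s², rise fraction, body region).  Axis 0 is the trunk
#: longitudinal axis.  Cadences/amplitudes are stated assumptions of the
#: generator (see docs/methods.md), chosen in the range of slow maintenance
#: exercise for elderly users.
EXERCISE_TEMPLATES: dict[ActivityKind, tuple[int, float, float, float, str]] = {
    ActivityKind.COSTAL_EXPANSION:       (1, 4.2, 2.9, 0.45, "upper"),
    ActivityKind.BICEPS_CURL:            (2, 4.0, 2.9, 0.45, "upper"),
    ActivityKind.ARM_RAISE:              (0, 3.8, 3.0, 0.40, "upper"),
    ActivityKind.ARM_FLEXION:            (2, 3.0, 2.9, 0.45, "upper"),
    ActivityKind.OVERHEAD_BEND:          (0, 4.4, 3.0, 0.50, "upper"),
    ActivityKind.SHOULDER_BLADE_SQUEEZE: (1, 3.4, 2.8, 0.50, "upper"),
    ActivityKind.KNEE_EXTENSION:         (2, 2.4, 2.6, 0.40, "lower"),
    ActivityKind.MARCHING_IN_PLACE:      (0, 1.5, 3.2, 0.50, "lower"),
    ActivityKind.CHAIR_PUSH_UPS:         (0, 3.0, 3.0, 0.45, "lower"),
    ActivityKind.KNEE_FLEXION:           (2, 3.5, 2.8, 0.50, "lower"),
    ActivityKind.SIDE_LEG_RAISE:         (1, 2.8, 2.6, 0.45, "lower"),
    ActivityKind.PLANTAR_FLEXION:        (0, 2.2, 2.4, 0.50, "lower"),
    ActivityKind.BODY_INCLINATION:       (1, 5.0, 3.0, 0.55, "upper"),
    ActivityKind.HIP_FLEXION:            (0, 4.2, 2.8, 0.40, "lower"),
    ActivityKind.HIP_EXTENSION:          (0, 3.4, 2.8, 0.55, "lower"),
    ActivityKind.WALKING:                (0, 0.6, 3.0, 0.50, "total"),
    ActivityKind.CYCLING:                (2, 1.0, 2.4, 0.50, "total"),
}

#: Gait parameters for the lower-back (fall detector) placement:
#: kind -> (cadence steps/min, half-amplitude of the magnitude oscillation).
_GAIT_ADL = {
    ActivityKind.WALKING: (100.0, 0.15),
    ActivityKind.STAIRS_UP: (70.0, 0.18),
    ActivityKind.STAIRS_DOWN: (80.0, 0.20),
}

#: Fall kinematics: kind -> (drop height m, descent acceleration m/s²).
_FALL_PARAMS = {
    ActivityKind.FALL_KNEES: (0.50, 8.0),
    ActivityKind.FALL_FROM_CHAIR: (0.45, 7.5),
    ActivityKind.FALL_FROM_BED: (0.55, 8.5),
}


def _bandlimited_noise(n: int, fs: float, sd: float, rng: np.random.Generator,
                       pad: int = 400) -> np.ndarray:
    """Gaussian noise low-passed at the model cut-off, exact per-stream SD.

    The white input is padded before filtering and the pad trimmed, so the
    zero-phase filter's edge transients never reach the stream.
    """
    if sd <= 0 or n == 0:
        return np.zeros(n)
    w = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(2, NOISE_CUTOFF_HZ, btype="low", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, w)[pad:-pad]
    x = x - x.mean()
    s = x.std()
    if s <= 0:
        return np.zeros(n)
    return sd * x / s


def _with_noise(a: np.ndarray, sd: float, rng: np.random.Generator, fs: float) -> np.ndarray:
    if sd <= 0:
        return a
    out = a.copy()
    for axis in range(a.shape[1]):
        out[:, axis] += _bandlimited_noise(a.shape[0], fs, sd, rng)
    return out


def _raised_cosine_pos(t: np.ndarray, t_start: float, depth: float, dur: float) -> np.ndarray:
    """Vertical position: smooth monotone descent by ``depth`` over ``dur``."""
    u = np.clip((t - t_start) / dur, 0.0, 1.0)
    return -depth * 0.5 * (1.0 - np.cos(np.pi * u))


def _second_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    v = np.gradient(x) * fs
    return np.gradient(v) * fs


# ---------------------------------------------------------------------------
# Fall-free activities of daily living (lower-back placement)
# ---------------------------------------------------------------------------

def gen_adl(kind: ActivityKind, duration: float, noise_sd: float, seed: int) -> LabeledStream:
    """Generate a fall-free daily activity at the lower-back sensor.

    The magnitude stays near gravity with bounded oscillation; no segment
    satisfies the fall signature, and ``truth.falls`` is empty.
    """
    kind = ActivityKind(kind)
    if kind not in ADL_PROTOCOL_KINDS:
        raise ValueError(f"{kind.value} is not a fall-free protocol activity")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    fs = DEFAULT_FS
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    a = np.zeros((n, 3))
    truth = Truth()
    labels = [(0.0, duration, kind.value)]

    if kind in _GAIT_ADL:
        cadence, half_amp = _GAIT_ADL[kind]
        f = cadence / 60.0
        osc = half_amp * (np.sin(2 * np.pi * f * t) + 0.3 * np.sin(4 * np.pi * f * t))
        a[:, 0] = GRAVITY + osc
        a[:, 1] = 0.3 * half_amp * np.sin(2 * np.pi * f * t + 1.1)
        step_times = np.arange(1, int(np.floor(duration * f)) + 1) / f
        truth.reps = len(step_times)
        truth.rep_times = [float(x) for x in step_times]
    elif kind is ActivityKind.SIT_DOWN:
        ev_dur = min(3.0, 0.8 * duration)
        t_start = max(0.0, duration / 2 - ev_dur / 2)
        z = _raised_cosine_pos(t, t_start, 0.40, ev_dur)
        a[:, 0] = GRAVITY + _second_derivative(z, fs)
    elif kind is ActivityKind.PICK_UP_OBJECT:
        ev_dur = min(3.0, 0.8 * duration)
        t_start = max(0.0, duration / 2 - ev_dur / 2)
        u = np.clip((t - t_start) / ev_dur, 0.0, 1.0)
        z = -0.25 * np.sin(np.pi * u) ** 2           # dip and return
        theta = np.deg2rad(60.0) * np.sin(np.pi * u) ** 2  # bend and straighten
        f_v = GRAVITY + _second_derivative(z, fs)
        a[:, 0] = np.cos(theta) * f_v
        a[:, 2] = np.sin(theta) * f_v
    else:  # pragma: no cover - exhaustive over ADL kinds
        raise AssertionError(kind)

    a = _with_noise(a, noise_sd, rng, fs)
    stream = AccelStream(a, fs=fs)
    out = LabeledStream(stream=stream, labels=labels, truth=truth, seed=seed)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Falls (lower-back placement)
# ---------------------------------------------------------------------------

def gen_fall(kind: ActivityKind, duration: float, noise_sd: float, seed: int) -> LabeledStream:
    """Generate a stream containing exactly one fall.

    Vertical posture before, horizontal after, a net downward displacement
    of about half a metre, and an impact transient whose windowed energy
    exceeds the default fall-energy threshold with a wide margin.
    """
    kind = ActivityKind(kind)
    if kind not in FALL_KINDS:
        raise ValueError(f"{kind.value} is not a fall activity")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    fs = DEFAULT_FS
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    h, a_drop = _FALL_PARAMS[kind]
    t_drop = float(np.sqrt(2.0 * h / a_drop))
    v_impact = a_drop * t_drop
    # impact half-sine duration drawn so the peak lands in 30–60 m/s²
    tau = float(rng.uniform(np.pi * v_impact / 110.0, np.pi * v_impact / 65.0))
    peak = np.pi * v_impact / (2.0 * tau)

    t_imp = float(np.clip(0.5 * duration, min(2.2, 0.4 * duration),
                          max(duration - 2.2, 0.6 * duration)))

    zdd = np.zeros(n)  # vertical acceleration of the trunk, up positive
    drop_mask = (t >= t_imp - t_drop) & (t < t_imp)
    zdd[drop_mask] = -a_drop
    imp_mask = (t >= t_imp) & (t < t_imp + tau)
    zdd[imp_mask] = peak * np.sin(np.pi * (t[imp_mask] - t_imp) / tau)
    # rescale the sampled impact pulse so the discrete (trapezoidal) velocity
    # returns exactly to rest — the short pulse is only a few samples wide
    dt = 1.0 / fs
    v_res = float(np.trapezoid(zdd, dx=dt))
    pulse_area = float(np.trapezoid(zdd[imp_mask], dx=dt))
    if pulse_area > 0:
        zdd[imp_mask] *= (pulse_area - v_res) / pulse_area

    # trunk rotation vertical -> horizontal across the descent and landing
    rot0, rot1 = t_imp - t_drop, t_imp + 0.3
    u = np.clip((t - rot0) / (rot1 - rot0), 0.0, 1.0)
    theta = np.deg2rad(90.0) * 0.5 * (1.0 - np.cos(np.pi * u))

    f_v = GRAVITY + zdd  # world-vertical specific force
    a = np.zeros((n, 3))
    a[:, 0] = np.cos(theta) * f_v
    a[:, 2] = np.sin(theta) * f_v

    a = _with_noise(a, noise_sd, rng, fs)
    stream = AccelStream(a, fs=fs)
    truth = Truth(falls=[t_imp])
    out = LabeledStream(stream=stream, labels=[(0.0, duration, kind.value)],
                        truth=truth, seed=seed)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Exercises (thorax / smart-vest placement)
# ---------------------------------------------------------------------------

def _triangle(t_active: np.ndarray, period: float, amp: float, rise_frac: float,
              n_cycles: int) -> np.ndarray:
    """0..amp asymmetric triangle, troughs at cycle boundaries."""
    out = np.zeros_like(t_active)
    active = t_active < n_cycles * period
    phase = np.mod(t_active[active], period) / period
    rise = phase < rise_frac
    vals = np.where(rise, phase / rise_frac, (1.0 - phase) / (1.0 - rise_frac))
    out[active] = amp * vals
    return out


def gen_exercise(
    kind: ActivityKind,
    n_reps: int | None = None,
    duration: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LabeledStream:
    """Generate a sawtooth-like exercise stream at the smart-vest sensor.

    Static exercises take ``n_reps``; walking/cycling take ``duration`` in
    seconds and produce cycles at the generator cadence (one cycle per
    step or pedal stroke).
    """
    kind = ActivityKind(kind)
    if kind not in STATIC_EXERCISE_KINDS and kind not in LOCOMOTION_KINDS:
        raise ValueError(f"{kind.value} is not an exercise or locomotion kind")
    axis, period, amp, rise_frac, _region = EXERCISE_TEMPLATES[kind]
    if kind in STATIC_EXERCISE_KINDS:
        if n_reps is None or n_reps < 1:
            raise ValueError("n_reps must be >= 1 for static exercises")
        n_cycles = int(n_reps)
    else:
        if duration is None or duration <= 0:
            raise ValueError("duration must be > 0 for walking/cycling")
        n_cycles = int(round(duration / period))
        if n_cycles < 1:
            raise ValueError("duration too short for a single cycle")

    fs = DEFAULT_FS
    rng = np.random.default_rng(seed)
    lead = 1.0
    active_dur = n_cycles * period
    total = lead + active_dur + lead
    n = int(round(total * fs))
    t = np.arange(n) / fs

    a = np.zeros((n, 3))
    a[:, 0] = GRAVITY
    a[:, axis] += _triangle(t - lead, period, amp, rise_frac, n_cycles) * (t >= lead)

    a = _with_noise(a, noise_sd, rng, fs)
    stream = AccelStream(a, fs=fs)
    rep_times = [lead + (k + rise_frac) * period for k in range(n_cycles)]
    truth = Truth(reps=n_cycles, rep_times=rep_times)
    labels = [(0.0, lead, "rest"), (lead, lead + active_dur, kind.value),
              (lead + active_dur, total, "rest")]
    out = LabeledStream(stream=stream, labels=labels, truth=truth, seed=seed)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Breathing
# ---------------------------------------------------------------------------

def gen_breathing(pattern: list[tuple[float, int]], noise_sd: float, seed: int,
                  amplitude: float = 1.0) -> LabeledStream:
    """Generate a controlled-breathing signal from (rate, n_cycles) segments.

    Each cycle is a raised-cosine inspiration (40% of the period) followed
    by a raised-cosine expiration; truth records every inspiration and
    expiration boundary and the per-segment programmed rate.
    """
    if not pattern:
        raise ValueError("pattern must contain at least one (rate, n_cycles) segment")
    for rate, n_cycles in pattern:
        if not (4.0 <= rate <= 60.0):
            raise ValueError(f"rate {rate} breaths/min outside the valid range [4, 60]")
        if n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    fs = DEFAULT_FS
    rng = np.random.default_rng(seed)
    truth = Truth()
    labels = []
    # exact cycle boundaries first, waveform evaluated on the global grid
    t_cursor = 0.0
    for rate, n_cycles in pattern:
        period = 60.0 / rate
        t_i = INSP_FRACTION * period
        seg_start = t_cursor
        for _ in range(int(n_cycles)):
            truth.breaths.append({
                "insp_start": t_cursor,
                "insp_end": t_cursor + t_i,
                "exp_end": t_cursor + period,
            })
            t_cursor += period
        truth.segments.append({"rate": float(rate), "n_cycles": int(n_cycles),
                               "t_start": seg_start, "t_end": t_cursor})
        labels.append((seg_start, t_cursor, f"breathing_{rate:g}bpm"))
    truth.reps = len(truth.breaths)

    total = t_cursor
    # include the closing boundary sample so the final trough is on the grid
    n = int(np.floor(total * fs + 1e-9)) + 1
    t = np.arange(n) / fs
    y = np.zeros(n)
    for b in truth.breaths:
        t_i = b["insp_end"] - b["insp_start"]
        t_e = b["exp_end"] - b["insp_end"]
        sel = (t >= b["insp_start"] - 1e-12) & (t < b["exp_end"] - 1e-12)
        u = t[sel] - b["insp_start"]
        insp = u < t_i
        y[sel] = np.where(
            insp,
            amplitude * 0.5 * (1.0 - np.cos(np.pi * u / t_i)),
            amplitude * 0.5 * (1.0 + np.cos(np.pi * np.minimum(u - t_i, t_e) / t_e)),
        )
    y = y + _bandlimited_noise(n, fs, noise_sd, rng)
    signal = RespSignal(y, fs=fs)
    out = LabeledStream(stream=signal, labels=labels, truth=truth, seed=seed)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Laboratory protocol replication
# ---------------------------------------------------------------------------

#: Interleaved order of one protocol sequence (falls alternating with
#: fall-free activities, as performed back-to-back in the laboratory).
PROTOCOL_ORDER = (
    ActivityKind.WALKING,
    ActivityKind.FALL_KNEES,
    ActivityKind.STAIRS_UP,
    ActivityKind.FALL_FROM_CHAIR,
    ActivityKind.PICK_UP_OBJECT,
    ActivityKind.STAIRS_DOWN,
    ActivityKind.FALL_FROM_BED,
    ActivityKind.SIT_DOWN,
)

_ADL_DURATION = {
    ActivityKind.WALKING: 12.0,
    ActivityKind.STAIRS_UP: 10.0,
    ActivityKind.STAIRS_DOWN: 10.0,
    ActivityKind.PICK_UP_OBJECT: 10.0,
    ActivityKind.SIT_DOWN: 10.0,
}

#: Volunteer anthropometrics: mean ± SD of age (y), height (cm), weight (kg).
VOLUNTEER_STATS = {"age": (38.0, 6.2), "height_cm": (175.0, 4.8),
                   "weight_kg": (75.7, 5.3)}


def gen_protocol_sequence(subjects: int, repetitions: int, noise_sd: float,
                          seed: int) -> list[LabeledStream]:
    """Replicate the laboratory fall-validation protocol.

    Each simulated subject performs ``repetitions`` interleaved sequences
    of the five fall-free and three fall activities; every activity
    instance is returned as one labeled stream with a per-subject
    anthropometric profile (drawn within the volunteer ranges) in ``meta``.
    """
    if subjects < 1 or repetitions < 1:
        raise ValueError("subjects and repetitions must be >= 1")
    master = np.random.default_rng(seed)
    streams: list[LabeledStream] = []
    for subj in range(subjects):
        profile = {
            "subject": subj,
            "age": float(master.normal(*VOLUNTEER_STATS["age"])),
            "height_cm": float(master.normal(*VOLUNTEER_STATS["height_cm"])),
            "weight_kg": float(master.normal(*VOLUNTEER_STATS["weight_kg"])),
        }
        for rep in range(repetitions):
            for kind in PROTOCOL_ORDER:
                child = int(master.integers(0, 2**31 - 1))
                if kind in FALL_KINDS:
                    ls = gen_fall(kind, 10.0, noise_sd, child)
                else:
                    ls = gen_adl(kind, _ADL_DURATION[kind], noise_sd, child)
                ls.meta.update(profile)
                ls.meta["repetition"] = rep
                ls.meta["kind"] = kind.value
                streams.append(ls)
    return streams
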