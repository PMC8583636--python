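"""In-memory signal containers and plain-text I/O.

The toolkit processes two kinds of uniformly sampled streams:

* :class:`AccelStream` — triaxial acceleration in m/s² from a body-worn
  sensor sampled at 40 Hz.  The device x-axis is aligned with the trunk
  longitudinal axis when the wearer stands, so a standing subject reads
  ``ax ≈ 9.81`` and a lying subject reads ``ax ≈ 0``.
* :class:`RespSignal` — a dimensionless amplitude proportional to
  thoraco-abdominal expansion (derived from the oscillation frequency of a
  capacitive textile sensor).  Rising amplitude is inspiration.

Streams produced by the synthetic generators come wrapped in a
:class:`LabeledStream` that carries interval labels and the ground truth
(fall times, repetition counts, breath-cycle boundaries) that downstream
detectors are evaluated against.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

#: Standard gravity as read by a resting accelerometer, m/s².
GRAVITY = 9.81

#: Sampling rate of both wearable devices, Hz.
DEFAULT_FS = 40.0


class Category(str, enum.Enum):
    FALL = "fall"
    FALL_FREE_ADL = "fall_free_adl"
    STATIC_EXERCISE = "static_exercise"
    LOCOMOTION = "locomotion"


class ActivityKind(str, enum.Enum):
    # locomotion (whole-body, also part of the fall-free protocol sequence)
    WALKING = "walking"
    CYCLING = "cycling"
    # fall-free activities of daily living
    STAIRS_UP = "stairs_up"
    STAIRS_DOWN = "stairs_down"
    PICK_UP_OBJECT = "pick_up_object"
    SIT_DOWN = "sit_down"
    # falls
    FALL_KNEES = "fall_knees"
    FALL_FROM_CHAIR = "fall_from_chair"
    FALL_FROM_BED = "fall_from_bed"
    # static maintenance exercises
    COSTAL_EXPANSION = "costal_expansion"
    BICEPS_CURL = "biceps_curl"
    ARM_RAISE = "arm_raise"
    ARM_FLEXION = "arm_flexion"
    OVERHEAD_BEND = "overhead_bend"
    SHOULDER_BLADE_SQUEEZE = "shoulder_blade_squeeze"
    KNEE_EXTENSION = "knee_extension"
    MARCHING_IN_PLACE = "marching_in_place"
    CHAIR_PUSH_UPS = "chair_push_ups"
    KNEE_FLEXION = "knee_flexion"
    SIDE_LEG_RAISE = "side_leg_raise"
    PLANTAR_FLEXION = "plantar_flexion"
    BODY_INCLINATION = "body_inclination"
    HIP_FLEXION = "hip_flexion"
    HIP_EXTENSION = "hip_extension"


FALL_KINDS = frozenset(
    {ActivityKind.FALL_KNEES, ActivityKind.FALL_FROM_CHAIR, ActivityKind.FALL_FROM_BED}
)

STATIC_EXERCISE_KINDS = frozenset(
    {
        ActivityKind.COSTAL_EXPANSION,
        ActivityKind.BICEPS_CURL,
        ActivityKind.ARM_RAISE,
        ActivityKind.ARM_FLEXION,
        ActivityKind.OVERHEAD_BEND,
        ActivityKind.SHOULDER_BLADE_SQUEEZE,
        ActivityKind.KNEE_EXTENSION,
        ActivityKind.MARCHING_IN_PLACE,
        ActivityKind.CHAIR_PUSH_UPS,
        ActivityKind.KNEE_FLEXION,
        ActivityKind.SIDE_LEG_RAISE,
        ActivityKind.PLANTAR_FLEXION,
        ActivityKind.BODY_INCLINATION,
        ActivityKind.HIP_FLEXION,
        ActivityKind.HIP_EXTENSION,
    }
)

LOCOMOTION_KINDS = frozenset({ActivityKind.WALKING, ActivityKind.CYCLING})

#: The five fall-free activities of the laboratory fall-protocol sequence.
ADL_PROTOCOL_KINDS = (
    ActivityKind.WALKING,
    ActivityKind.STAIRS_UP,
    ActivityKind.STAIRS_DOWN,
    ActivityKind.PICK_UP_OBJECT,
    ActivityKind.SIT_DOWN,
)

#: The three fall activities of the laboratory protocol sequence.
FALL_PROTOCOL_KINDS = (
    ActivityKind.FALL_KNEES,
    ActivityKind.FALL_FROM_CHAIR,
    ActivityKind.FALL_FROM_BED,
)


def category(kind: ActivityKind) -> Category:
    """Map an activity kind to its single category."""
    if kind in FALL_KINDS:
        return Category.FALL
    if kind in STATIC_EXERCISE_KINDS:
        return Category.STATIC_EXERCISE
    if kind in LOCOMOTION_KINDS:
        return Category.LOCOMOTION
    return Category.FALL_FREE_ADL


@dataclass
class AccelStream:
    """Uniformly sampled triaxial acceleration, m/s².

    ``a`` is an (n, 3) array; sample ``i`` has time ``t0 + i / fs``.
    """

    a: np.ndarray
    fs: float = DEFAULT_FS
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise ValueError("acceleration array must have shape (n, 3)")

    def __len__(self) -> int:
        return self.a.shape[0]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def magnitude(self) -> np.ndarray:
        """Euclidean norm ‖a‖ per sample."""
        return np.linalg.norm(self.a, axis=1)

    def slice_time(self, start: float, end: float) -> "AccelStream":
        i0 = max(0, int(np.ceil((start - self.t0) * self.fs)))
        i1 = min(len(self), int(np.floor((end - self.t0) * self.fs)) + 1)
        return AccelStream(self.a[i0:i1], fs=self.fs, t0=self.t0 + i0 / self.fs)


@dataclass
class RespSignal:
    """Uniformly sampled respiratory expansion signal (arbitrary units)."""

    amplitude: np.ndarray
    fs: float = DEFAULT_FS
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.ndim != 1:
            raise ValueError("respiratory amplitude must be 1-D")

    def __len__(self) -> int:
        return self.amplitude.shape[0]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    @property
    def duration(self) -> float:
        return len(self) / self.fs


@dataclass
class Truth:
    """Ground truth attached to a synthetic stream."""

    falls: list = field(default_factory=list)          # impact times, s
    reps: int | None = None                            # true cycle count
    rep_times: list = field(default_factory=list)      # per-cycle peak times, s
    breaths: list = field(default_factory=list)        # dicts insp_start/insp_end/exp_end
    segments: list = field(default_factory=list)       # breathing pattern segments

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LabeledStream:
    """A stream plus interval labels and generator ground truth."""

    stream: AccelStream | RespSignal
    labels: list  # list of (start_s, end_s, label)
    truth: Truth
    seed: int
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check label intervals are non-overlapping and inside the span."""
        span0 = self.stream.t0
        span1 = self.stream.t0 + self.stream.duration
        prev_end = -np.inf
        for start, end, _label in sorted(self.labels):
            if start < span0 - 1e-9 or end > span1 + 1e-9:
                raise ValueError(f"label interval ({start}, {end}) outside stream span")
            if start < prev_end - 1e-9:
                raise ValueError("label intervals overlap")
            prev_end = end


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def accel_to_csv(stream: AccelStream, path) -> None:
    pd.DataFrame({"t": stream.t, "ax": stream.a[:, 0], "ay": stream.a[:, 1],
                  "az": stream.a[:, 2]}).to_csv(path, index=False)


def accel_from_csv(path) -> AccelStream:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    fs = DEFAULT_FS if len(t) < 2 else 1.0 / np.median(np.diff(t))
    return AccelStream(df[["ax", "ay", "az"]].to_numpy(), fs=float(round(fs, 6)),
                       t0=float(t[0]) if len(t) else 0.0)


def resp_to_csv(signal: RespSignal, path) -> None:
    pd.DataFrame({"t": signal.t, "amplitude": signal.amplitude}).to_csv(path, index=False)


def resp_from_csv(path) -> RespSignal:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    fs = DEFAULT_FS if len(t) < 2 else 1.0 / np.median(np.diff(t))
    return RespSignal(df["amplitude"].to_numpy(), fs=float(round(fs, 6)),
                      t0=float(t[0]) if len(t) else 0.0)


def accel_to_jsonl(stream: AccelStream, path) -> None:
    with open(path, "w") as fh:
        for ti, (x, y, z) in zip(stream.t, stream.a):
            fh.write(json.dumps({"t": round(float(ti), 6), "ax": x, "ay": y, "az": z}) + "\n")


def accel_from_jsonl(path) -> AccelStream:
    rows = [json.loads(line) for line in open(path) if line.strip()]
    a = np.array([[r["ax"], r["ay"], r["az"]] for r in rows])
    t = np.array([r["t"] for r in rows])
    fs = DEFAULT_FS if len(t) < 2 else 1.0 / np.median(np.diff(t))
    return AccelStream(a, fs=float(round(fs, 6)), t0=float(t[0]) if len(t) else 0.0)


def save_truth(labeled: LabeledStream, path) -> None:
    """Write labels + ground truth as a JSON sidecar."""
    payload = {
        "labels": [[float(s), float(e), str(l)] for s, e, l in labeled.labels],
        "truth": labeled.truth.to_dict(),
        "seed": labeled.seed,
        "meta": labeled.meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_truth(path) -> tuple[list, Truth, int, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    truth = Truth(**payload["truth"])
    labels = [tuple(item) for item in payload["labels"]]
    return labels, truth, payload.get("seed", 0), payload.get("meta", {})
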