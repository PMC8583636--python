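"""End-to-end replications of the laboratory validation protocol.

Three runners, one per experiment: the fall protocol (sensitivity and
specificity of the two-stage detector over interleaved fall / fall-free
sequences), the exercise protocol (repetition-count precision for six
repetitions of each static exercise plus one minute of walking and of
cycling), and the controlled-breathing ramp (per-segment rate recovery
from 6 to 30 breaths/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import count_repetitions, precision
from .config import DetectorConfig
from .falls import ProtocolResult, evaluate_protocol
from .respiration import evaluate_breathing_protocol
from .streams import STATIC_EXERCISE_KINDS, ActivityKind
from .synthetic import gen_breathing, gen_exercise, gen_protocol_sequence

#: Noise level (m/s² per axis) of the laboratory-replication runs.
PROTOCOL_NOISE_SD = 0.3

#: The breathing ramp: 6 → 30 breaths/min in five steps, three cycles each.
BREATHING_RAMP = [(6.0, 3), (12.0, 3), (18.0, 3), (24.0, 3), (30.0, 3)]


def run_fall_protocol(subjects: int = 3, repetitions: int = 3,
                      noise_sd: float = PROTOCOL_NOISE_SD, seed: int = 0,
                      config: DetectorConfig | None = None) -> ProtocolResult:
    """Simulate the fall protocol and score the two-stage detector."""
    streams = gen_protocol_sequence(subjects, repetitions, noise_sd, seed)
    return evaluate_protocol(streams, config or DetectorConfig())


@dataclass
class ExerciseProtocolResult:
    static_precision: dict = field(default_factory=dict)   # kind -> %
    walking_precision: float = float("nan")                # mean %, over runs
    cycling_precision: float = float("nan")
    walking_runs: list = field(default_factory=list)
    cycling_runs: list = field(default_factory=list)

    @property
    def static_mean(self) -> float:
        return float(np.mean(list(self.static_precision.values())))


def run_exercise_protocol(noise_sd: float = PROTOCOL_NOISE_SD, seed: int = 0,
                          n_reps: int = 6, locomotion_duration: float = 60.0,
                          n_locomotion_runs: int = 20,
                          config: DetectorConfig | None = None) -> ExerciseProtocolResult:
    """Six repetitions of each static exercise + one minute walking/cycling.

    Locomotion precision is averaged over ``n_locomotion_runs`` seeded runs.
    """
    config = config or DetectorConfig()
    rng = np.random.default_rng(seed)
    out = ExerciseProtocolResult()
    for kind in sorted(STATIC_EXERCISE_KINDS, key=lambda k: k.value):
        child = int(rng.integers(0, 2**31 - 1))
        ls = gen_exercise(kind, n_reps=n_reps, noise_sd=noise_sd, seed=child)
        counted = count_repetitions(ls.stream, kind, config).count
        out.static_precision[kind.value] = precision(counted, ls.truth.reps)
    for kind, runs_attr, prec_attr in (
        (ActivityKind.WALKING, "walking_runs", "walking_precision"),
        (ActivityKind.CYCLING, "cycling_runs", "cycling_precision"),
    ):
        runs = []
        for _ in range(n_locomotion_runs):
            child = int(rng.integers(0, 2**31 - 1))
            ls = gen_exercise(kind, duration=locomotion_duration,
                              noise_sd=noise_sd, seed=child)
            counted = count_repetitions(ls.stream, kind, config).count
            runs.append(precision(counted, ls.truth.reps))
        setattr(out, runs_attr, runs)
        setattr(out, prec_attr, float(np.mean(runs)))
    return out


def run_breathing_protocol(pattern=None, noise_sd: float = 0.0, seed: int = 0,
                           config: DetectorConfig | None = None):
    """Generate the controlled-breathing ramp and score rate recovery."""
    labeled = gen_breathing(pattern or BREATHING_RAMP, noise_sd, seed)
    return evaluate_breathing_protocol(labeled, config=config)


def protocol_report(fall: ProtocolResult, exercise: ExerciseProtocolResult,
                    breathing) -> dict:
    """Serializable summary of the three protocol replications."""
    return {
        "fall": {
            "sensitivity_pct": fall.sensitivity,
            "specificity_pct": fall.specificity,
            "true_falls": fall.n_true_falls,
            "detected_true_falls": fall.n_detected_true,
            "fall_free_instances": fall.n_fall_free,
            "clean_fall_free_instances": fall.n_clean_fall_free,
            "false_alarms": fall.false_alarms,
        },
        "exercise": {
            "static_precision_pct": exercise.static_precision,
            "static_mean_pct": exercise.static_mean,
            "walking_precision_pct": exercise.walking_precision,
            "cycling_precision_pct": exercise.cycling_precision,
        },
        "breathing": [
            {
                "rate_true_bpm": s.rate_true,
                "rate_est_bpm": s.rate_est,
                "rate_abs_err_bpm": s.rate_abs_err,
                "mean_insp_err_s": s.mean_insp_err,
                "mean_exp_err_s": s.mean_exp_err,
            }
            for s in breathing
        ],
    }
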