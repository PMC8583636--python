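"""Breath-cycle segmentation, timing, rate estimation and artifact gating.

The capacitive respiratory channel is a sawtooth-like expansion signal:
the rising flank of each cycle is inspiration, the falling flank
expiration.  Segmentation reuses the sawtooth engine with a respiratory
band (0.05–1.5 Hz, covering 4–60 breaths/min), a hysteresis relative to
the signal's own excursion range (the channel's units are arbitrary, so
segmentation must be invariant under positive rescaling), and a 1 s
minimum cycle period to reject noise-induced micro-cycles.

When a concurrent acceleration stream is available, any cycle that
overlaps an interval of intense motion — |‖a‖ − g| above the artifact
threshold — is flagged and excluded from every rate estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DetectorConfig
from .errors import InsufficientSignal, NoValidData
from .sawtooth import segment_cycles
from .streams import GRAVITY, AccelStream, LabeledStream, RespSignal

#: Conditioning band for respiration, Hz (4–60 breaths/min with margin).
RESP_BAND = (0.05, 1.5)

#: Minimum physiological cycle period, s (60 breaths/min ceiling).
MIN_BREATH_PERIOD_S = 1.0

#: Hysteresis as a fraction of the 5th–95th percentile excursion.
REL_HYSTERESIS = 0.3


@dataclass
class BreathCycle:
    insp_start: float
    insp_end: float   # = expiration start
    exp_end: float
    artifact_gated: bool = False

    def __post_init__(self) -> None:
        if not (self.insp_start < self.insp_end < self.exp_end):
            raise ValueError("breath boundaries must be strictly ordered")

    @property
    def t_insp(self) -> float:
        return self.insp_end - self.insp_start

    @property
    def t_exp(self) -> float:
        return self.exp_end - self.insp_end

    @property
    def period(self) -> float:
        return self.exp_end - self.insp_start


def motion_artifact_intervals(accel: AccelStream, config: DetectorConfig) -> list[tuple[float, float]]:
    """Time intervals where |‖a‖ − g| exceeds the artifact threshold."""
    dev = np.abs(accel.magnitude() - GRAVITY)
    mask = dev > config.intense_motion_artifact_threshold
    intervals = []
    t = accel.t
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            intervals.append((float(t[i]), float(t[j])))
            i = j + 1
        else:
            i += 1
    return intervals


def segment_breaths(resp: RespSignal, accel: AccelStream | None = None,
                    config: DetectorConfig | None = None) -> list[BreathCycle]:
    """Segment the respiratory waveform into inspiration/expiration cycles."""
    config = config or DetectorConfig()
    if resp.duration < 10.0:
        raise InsufficientSignal("need at least 10 s of respiratory signal")
    x = resp.amplitude
    p5, p95 = np.percentile(x, [5, 95])
    spread = float(p95 - p5)
    if spread <= 0:
        return []
    h = REL_HYSTERESIS * spread
    cycles_raw = segment_cycles(x, resp.fs, RESP_BAND, h,
                                min_period=MIN_BREATH_PERIOD_S)
    gates = motion_artifact_intervals(accel, config) if accel is not None else []
    out = []
    for c in cycles_raw:
        start = resp.t0 + c.start_time
        peak = resp.t0 + c.peak_time
        end = resp.t0 + c.end_time
        gated = any(start <= g1 and g0 <= end for g0, g1 in gates)
        out.append(BreathCycle(insp_start=start, insp_end=peak, exp_end=end,
                               artifact_gated=gated))
    return out


def respiratory_rate(cycles: list[BreathCycle], window: float = 60.0) -> list[tuple[float, float]]:
    """Sliding-window rate series, breaths/min, from non-gated cycles.

    Each window's rate is 60 / mean cycle period of the non-gated cycles
    whose midpoint falls inside the window; gated cycles never contribute.
    """
    valid = [c for c in cycles if not c.artifact_gated]
    if not valid:
        raise NoValidData("no non-gated breath cycles")
    t_start = valid[0].insp_start
    t_end = valid[-1].exp_end
    step = window / 2.0
    out = []
    t = t_start
    while True:
        w0, w1 = t, min(t + window, t_end)
        inside = [c for c in valid if w0 <= 0.5 * (c.insp_start + c.exp_end) <= w1]
        if inside:
            mean_p = float(np.mean([c.period for c in inside]))
            out.append((0.5 * (w0 + w1), 60.0 / mean_p))
        if w1 >= t_end:
            break
        t += step
    if not out:
        mean_p = float(np.mean([c.period for c in valid]))
        out.append((0.5 * (t_start + t_end), 60.0 / mean_p))
    return out


@dataclass
class BreathingSegmentScore:
    rate_true: float
    rate_est: float
    rate_abs_err: float
    mean_insp_err: float
    mean_exp_err: float
    n_cycles_true: int
    n_cycles_est: int


def evaluate_breathing_protocol(labeled: LabeledStream,
                                accel: AccelStream | None = None,
                                config: DetectorConfig | None = None) -> list[BreathingSegmentScore]:
    """Per-segment rate and timing errors against protocol ground truth."""
    truth = labeled.truth
    if truth is None or not truth.segments:
        raise ValueError("labeled stream carries no breathing-protocol truth")
    cycles = segment_breaths(labeled.stream, accel, config)
    valid = [c for c in cycles if not c.artifact_gated]
    scores = []
    for seg in truth.segments:
        t0, t1 = seg["t_start"], seg["t_end"]
        est = [c for c in valid if t0 - 0.5 <= c.insp_start and c.exp_end <= t1 + 0.5]
        true_cycles = [b for b in truth.breaths if t0 - 1e-9 <= b["insp_start"] < t1 - 1e-9]
        if est:
            rate_est = 60.0 / float(np.mean([c.period for c in est]))
        else:
            rate_est = float("nan")
        insp_errs, exp_errs = [], []
        for b in true_cycles:
            nearest = min(est, key=lambda c: abs(c.insp_start - b["insp_start"]),
                          default=None)
            if nearest is None:
                continue
            insp_errs.append(abs(nearest.insp_end - b["insp_end"]))
            exp_errs.append(abs(nearest.exp_end - b["exp_end"]))
        scores.append(BreathingSegmentScore(
            rate_true=seg["rate"],
            rate_est=rate_est,
            rate_abs_err=abs(rate_est - seg["rate"]),
            mean_insp_err=float(np.mean(insp_errs)) if insp_errs else float("nan"),
            mean_exp_err=float(np.mean(exp_errs)) if exp_errs else float("nan"),
            n_cycles_true=len(true_cycles),
            n_cycles_est=len(est),
        ))
    return scores
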