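"""Stage-2 fall classification (gateway side).

Each impact excerpt is classified with a conjunction over exactly the
personalization-table parameter set:

* impact energy at or above the fall-energy threshold,
* vertical posture in the second before the impact,
* horizontal posture in the second after it, and
* a net downward vertical excursion at or below the descending
  displacement threshold.

Posture is the mean gravity projection on the trunk-longitudinal axis
(device x-axis).  The vertical excursion is obtained from ‖a‖ − g — an
orientation-free vertical acceleration surrogate — high-passed to kill
integration drift and doubly integrated.  Post-impact immobility is
deliberately not a criterion: a person attempting to stand up must not
turn a detected fall into a miss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DetectorConfig
from .errors import InsufficientSignal
from .impact import ImpactWindow, detect_impacts
from .streams import GRAVITY, AccelStream, LabeledStream

#: Posture segments: first/last second of the excerpt.
POSTURE_SEGMENT_S = 1.0

#: Displacement estimator: dynamic-acceleration gate opening the event
#: support (m/s²), its dilation (s), and the flank used for the local
#: linear baseline (s).
_DISP_GATE = 2.0
_DISP_DILATE_S = 0.2
_DISP_FLANK_S = 0.6

#: A detection matches a true fall when within this many seconds of it.
MATCH_TOLERANCE_S = 2.0

VERTICAL = "vertical"
HORIZONTAL = "horizontal"


@dataclass
class FallFeatures:
    pre_posture: str
    post_posture: str
    impact_energy: float          # m²/s⁴
    vertical_displacement: float | None  # m, negative = downward; None if not computable
    truncated: bool = False


@dataclass
class FallEvent:
    impact_time: float
    is_fall: bool
    features: FallFeatures
    config_used: DetectorConfig
    low_confidence: bool = False


def decide(features: FallFeatures, config: DetectorConfig) -> bool:
    """The stage-2 decision rule, re-derivable from stored features."""
    ok = (
        features.impact_energy >= config.fall_energy_threshold
        and features.pre_posture == VERTICAL
        and features.post_posture == HORIZONTAL
    )
    if features.vertical_displacement is not None:
        ok = ok and features.vertical_displacement <= config.descending_displacement_threshold
    return ok


def classify_posture(segment: np.ndarray, config: DetectorConfig | None = None,
                     fs: float = 40.0) -> str:
    """Classify a quasi-static segment as vertical or horizontal posture.

    Uses |mean gravity projection| on the trunk axis; values between the
    two thresholds take the nearer class, with the exact midpoint
    resolved to vertical (the non-alarm direction at the pre-impact
    check).
    """
    config = config or DetectorConfig()
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise InsufficientSignal("empty posture segment")
    if segment.ndim != 2 or segment.shape[1] != 3:
        raise ValueError("posture segment must be (n, 3)")
    if segment.shape[0] < 0.5 * fs:
        raise InsufficientSignal("posture segment shorter than 0.5 s")
    proj = abs(float(np.mean(segment[:, 0])))
    if proj >= config.vertical_posture_threshold:
        return VERTICAL
    if proj <= config.horizontal_posture_threshold:
        return HORIZONTAL
    d_vert = config.vertical_posture_threshold - proj
    d_horiz = proj - config.horizontal_posture_threshold
    return VERTICAL if d_vert <= d_horiz else HORIZONTAL


def vertical_displacement(window: ImpactWindow) -> float:
    """Net signed vertical excursion over the excerpt, metres (down < 0).

    ‖a‖ − g is an orientation-free vertical-acceleration surrogate (the
    magnitude is invariant to trunk rotation, and during a fall equals
    g + z̈ of the trunk).  Double integration amplifies any slow baseline
    error as 1/ω², so the integral is restricted to the detected event
    support: the samples where |‖a‖ − g| exceeds a 2 m/s² gate (well above
    sway, well below any impact), dilated by 0.2 s.  A linear baseline
    fitted on the 0.6 s flanks on either side of the support is removed
    first (drift control), the wearer is taken as quasi-static at the
    support start (v = 0), and the signed extreme excursion of the doubly
    trapezoid-integrated trace is returned.  A window with no gate
    exceedance has no measurable vertical transition and returns 0.
    """
    if window.truncated:
        raise InsufficientSignal("displacement not computable on a truncated window")
    fs = window.fs
    a_v = np.linalg.norm(window.samples, axis=1) - GRAVITY
    n = len(a_v)
    t = np.arange(n) / fs
    exc = np.flatnonzero(np.abs(a_v) > _DISP_GATE)
    if exc.size == 0:
        return 0.0
    i1 = max(0, int(exc[0]) - int(_DISP_DILATE_S * fs))
    i2 = min(n - 1, int(exc[-1]) + int(_DISP_DILATE_S * fs))
    flank = np.concatenate([
        np.arange(max(0, i1 - int(_DISP_FLANK_S * fs)), i1),
        np.arange(i2 + 1, min(n, i2 + 1 + int(_DISP_FLANK_S * fs))),
    ])
    if flank.size >= 4:
        line = np.polyfit(t[flank], a_v[flank], 1)
        a_c = a_v - np.polyval(line, t)
    else:
        a_c = a_v - np.median(a_v)
    dt = 1.0 / fs
    seg = a_c[i1:i2 + 1]
    v = np.concatenate([[0.0], np.cumsum((seg[1:] + seg[:-1]) * 0.5 * dt)])
    p = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) * 0.5 * dt)])
    p_min, p_max = float(p.min()), float(p.max())
    return p_min if -p_min >= p_max else p_max


def classify_fall(window: ImpactWindow, config: DetectorConfig | None = None) -> FallEvent:
    """Apply the stage-2 conjunction rule to one impact excerpt.

    Truncated excerpts are decided on the available criteria (posture and
    energy) and flagged low-confidence.
    """
    config = config or DetectorConfig()
    seg_len = int(round(POSTURE_SEGMENT_S * window.fs))
    pre = window.samples[:seg_len]
    post = window.samples[-seg_len:]
    try:
        disp = vertical_displacement(window)
    except InsufficientSignal:
        disp = None
    features = FallFeatures(
        pre_posture=classify_posture(pre, config, fs=window.fs),
        post_posture=classify_posture(post, config, fs=window.fs),
        impact_energy=window.peak_energy,
        vertical_displacement=disp,
        truncated=window.truncated,
    )
    return FallEvent(
        impact_time=window.impact_time,
        is_fall=decide(features, config),
        features=features,
        config_used=config.model_copy(),
        low_confidence=window.truncated,
    )


def detect_falls(stream: AccelStream, config: DetectorConfig | None = None) -> list[FallEvent]:
    """Run both stages on a raw stream."""
    config = config or DetectorConfig()
    return [classify_fall(w, config) for w in detect_impacts(stream, config)]


@dataclass
class ProtocolResult:
    sensitivity: float         # %
    specificity: float         # %
    n_true_falls: int
    n_detected_true: int
    n_fall_free: int
    n_clean_fall_free: int
    false_alarms: int


def evaluate_protocol(streams: list[LabeledStream],
                      config: DetectorConfig | None = None) -> ProtocolResult:
    """Score the two-stage detector against protocol ground truth.

    Sensitivity is the percentage of true falls matched by a fall-positive
    event within ±2 s; specificity is the percentage of fall-free activity
    instances (streams without a true fall) that raise no fall alarm.
    """
    config = config or DetectorConfig()
    if not streams or any(ls.truth is None for ls in streams):
        raise ValueError("protocol streams must carry ground-truth annotations")
    n_true = n_matched = 0
    n_free = n_clean = false_alarms = 0
    for ls in streams:
        events = detect_falls(ls.stream, config)
        fall_times = [e.impact_time for e in events if e.is_fall]
        if ls.truth.falls:
            for t_true in ls.truth.falls:
                n_true += 1
                if any(abs(t - t_true) <= MATCH_TOLERANCE_S for t in fall_times):
                    n_matched += 1
        else:
            n_free += 1
            if fall_times:
                false_alarms += len(fall_times)
            else:
                n_clean += 1
    if n_true == 0 and n_free == 0:
        raise ValueError("no annotated activity instances")
    sens = 100.0 * n_matched / n_true if n_true else float("nan")
    spec = 100.0 * n_clean / n_free if n_free else float("nan")
    return ProtocolResult(
        sensitivity=sens,
        specificity=spec,
        n_true_falls=n_true,
        n_detected_true=n_matched,
        n_fall_free=n_free,
        n_clean_fall_free=n_clean,
        false_alarms=false_alarms,
    )
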