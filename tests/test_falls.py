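"""Stage-2 fall classification: posture, displacement, decision rule."""

import numpy as np
import pytest

from frailsense.config import DetectorConfig
from frailsense.errors import InsufficientSignal
from frailsense.falls import (
    FallFeatures,
    HORIZONTAL,
    VERTICAL,
    classify_fall,
    classify_posture,
    decide,
    detect_falls,
    evaluate_protocol,
    vertical_displacement,
)
from frailsense.impact import ImpactWindow, detect_impacts
from frailsense.streams import (
    GRAVITY,
    ADL_PROTOCOL_KINDS,
    FALL_PROTOCOL_KINDS,
    AccelStream,
    ActivityKind,
    LabeledStream,
    Truth,
)
from frailsense.synthetic import gen_adl, gen_fall, gen_protocol_sequence


def _segment(proj: float, n: int = 40) -> np.ndarray:
    seg = np.zeros((n, 3))
    seg[:, 0] = proj
    return seg


class TestPosture:
    def test_standing_is_vertical(self, config):
        assert classify_posture(_segment(GRAVITY), config) == VERTICAL

    def test_lying_is_horizontal(self, config):
        seg = np.zeros((40, 3))
        seg[:, 2] = GRAVITY  # gravity off the trunk axis
        assert classify_posture(seg, config) == HORIZONTAL

    @pytest.mark.parametrize("proj,expected", [
        (6.5, VERTICAL), (2.5, HORIZONTAL),
        (5.0, VERTICAL),      # nearer the vertical threshold
        (3.5, HORIZONTAL),    # nearer the horizontal threshold
        (4.5, VERTICAL),      # exact midpoint resolves to the non-alarm class
        (-9.8, VERTICAL),     # projection magnitude, sign-free
    ])
    def test_threshold_band_nearest_class(self, proj, expected, config):
        assert classify_posture(_segment(proj), config) == expected

    def test_rejects_empty_or_short_segment(self, config):
        with pytest.raises(InsufficientSignal):
            classify_posture(np.empty((0, 3)), config)
        with pytest.raises(InsufficientSignal):
            classify_posture(_segment(GRAVITY, n=5), config)


def _window_from(a: np.ndarray, impact_index: int = 80) -> ImpactWindow:
    return ImpactWindow(impact_index=impact_index, impact_time=impact_index / 40.0,
                        samples=a, peak_energy=float("nan"), fs=40.0,
                        offset=impact_index)


class TestVerticalDisplacement:
    def test_zero_dynamic_acceleration_gives_zero(self):
        a = np.zeros((161, 3))
        a[:, 0] = GRAVITY
        assert vertical_displacement(_window_from(a)) == 0.0

    def test_free_fall_drop_recovered_within_ten_percent(self):
        # free-fall (z'' = -g) for 0.319 s = 0.5 m, stopped by a half-sine
        # impact; oracle = discrete double trapezoid integral of the profile
        fs, n = 40.0, 161
        t = np.arange(n) / fs
        t_imp, h = 2.0, 0.5
        t_drop = np.sqrt(2 * h / GRAVITY)
        v_i = GRAVITY * t_drop
        tau = 0.1
        zdd = np.zeros(n)
        zdd[(t >= t_imp - t_drop) & (t < t_imp)] = -GRAVITY
        m = (t >= t_imp) & (t < t_imp + tau)
        zdd[m] = (np.pi * v_i / (2 * tau)) * np.sin(np.pi * (t[m] - t_imp) / tau)
        dt = 1 / fs
        # the body is at rest after landing: rescale the sampled pulse so the
        # discrete velocity returns exactly to zero
        resid = np.trapezoid(zdd, dx=dt)
        zdd[m] *= (np.trapezoid(zdd[m], dx=dt) - resid) / np.trapezoid(zdd[m], dx=dt)
        v = np.concatenate([[0], np.cumsum((zdd[1:] + zdd[:-1]) * dt / 2)])
        p = np.concatenate([[0], np.cumsum((v[1:] + v[:-1]) * dt / 2)])
        oracle = p[-1]
        a = np.zeros((n, 3))
        a[:, 0] = GRAVITY + zdd  # reading = g + z'' on the vertical axis
        est = vertical_displacement(_window_from(a))
        assert est == pytest.approx(oracle, rel=0.10)
        assert est <= -0.4

    def test_sinusoidal_acceleration_bounded_below_2cm(self):
        t = np.arange(161) / 40.0
        for phase in (0.0, np.pi / 2):
            a = np.zeros((161, 3))
            a[:, 0] = GRAVITY + np.sin(2 * np.pi * 2.0 * t + phase)
            assert abs(vertical_displacement(_window_from(a))) < 0.02

    def test_truncated_window_not_computable(self):
        a = np.zeros((100, 3))
        a[:, 0] = GRAVITY
        w = ImpactWindow(impact_index=10, impact_time=0.25, samples=a,
                         peak_energy=1.0, fs=40.0, truncated=True, offset=10)
        with pytest.raises(InsufficientSignal):
            vertical_displacement(w)


class TestFallDecision:
    def test_generated_fall_is_classified_fall(self, config):
        ls = gen_fall(ActivityKind.FALL_FROM_CHAIR, 10.0, 0.0, seed=6)
        [w] = detect_impacts(ls.stream, config)
        event = classify_fall(w, config)
        assert event.is_fall
        assert event.features.pre_posture == VERTICAL
        assert event.features.post_posture == HORIZONTAL
        assert event.features.vertical_displacement <= config.descending_displacement_threshold

    def test_sit_down_never_reaches_stage_two(self, config):
        ls = gen_adl(ActivityKind.SIT_DOWN, 10.0, 0.0, seed=7)
        assert detect_impacts(ls.stream, config) == []

    def test_conjunction_fails_on_shallow_displacement(self, config):
        features = FallFeatures(pre_posture=VERTICAL, post_posture=HORIZONTAL,
                                impact_energy=1.0, vertical_displacement=-0.05)
        assert not decide(features, config)
        features.vertical_displacement = -0.5
        assert decide(features, config)

    def test_decision_monotone_in_thresholds(self, config):
        ls = gen_fall(ActivityKind.FALL_KNEES, 10.0, 0.3, seed=8)
        [w] = detect_impacts(ls.stream, config)
        assert classify_fall(w, config).is_fall
        # raising the energy threshold or deepening the displacement
        # threshold can only turn falls into non-falls, never the reverse
        for strict in (
            DetectorConfig(fall_energy_threshold=1e6),
            DetectorConfig(descending_displacement_threshold=-50.0),
        ):
            assert not classify_fall(w, strict).is_fall

    def test_stored_flag_rederivable_from_features(self, config):
        for kind in FALL_PROTOCOL_KINDS:
            ls = gen_fall(kind, 10.0, 0.3, seed=9)
            for event in detect_falls(ls.stream, config):
                assert event.is_fall == decide(event.features, event.config_used)


class TestNoiselessRecovery:
    def test_every_fall_kind_detected_every_adl_clean(self, config):
        for kind in FALL_PROTOCOL_KINDS:
            ls = gen_fall(kind, 10.0, 0.0, seed=20)
            events = [e for e in detect_falls(ls.stream, config) if e.is_fall]
            assert len(events) == 1, kind
            assert abs(events[0].impact_time - ls.truth.falls[0]) <= 2.0
        for kind in ADL_PROTOCOL_KINDS:
            ls = gen_adl(kind, 12.0, 0.0, seed=21)
            assert all(not e.is_fall for e in detect_falls(ls.stream, config))


class TestEvaluateProtocol:
    def test_perfect_detector_on_generated_protocol(self, config):
        streams = gen_protocol_sequence(1, 1, 0.0, seed=30)
        res = evaluate_protocol(streams, config)
        assert res.n_true_falls == 3 and res.n_fall_free == 5
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_degenerate_detectors(self, config):
        streams = gen_protocol_sequence(1, 1, 0.0, seed=31)
        never = DetectorConfig(fall_energy_threshold=1e9)
        res = evaluate_protocol(streams, never)
        assert res.sensitivity == 0.0 and res.specificity == 100.0

    def test_requires_truth(self, config):
        with pytest.raises(ValueError):
            evaluate_protocol([], config)
        a = np.zeros((100, 3))
        a[:, 0] = GRAVITY
        bad = LabeledStream(stream=AccelStream(a), labels=[], truth=None, seed=0)
        with pytest.raises(ValueError):
            evaluate_protocol([bad], config)
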