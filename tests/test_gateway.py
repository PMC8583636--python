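"""Personalization config, alert state machine, event log."""

import datetime
import itertools

import pytest
from pydantic import ValidationError

from frailsense.alerts import AlertState, AlertStateMachine, AlertTrigger, EventLog
from frailsense.config import (
    AlertConfig,
    DetectorConfig,
    PersonProfile,
    load_config,
    save_config,
)
from frailsense.falls import FallEvent, FallFeatures


def make_fall_event(is_fall=True, t=12.0):
    features = FallFeatures(pre_posture="vertical", post_posture="horizontal",
                            impact_energy=1.0, vertical_displacement=-0.5)
    return FallEvent(impact_time=t, is_fall=is_fall, features=features,
                     config_used=DetectorConfig())


class TestConfig:
    def test_factory_defaults_bit_exact(self):
        c = DetectorConfig()
        assert c.vertical_posture_threshold == 6.5
        assert c.fall_energy_threshold == 0.079
        assert c.horizontal_posture_threshold == 2.5
        assert c.movement_activity_energy_threshold == 0.1490
        assert c.resting_energy_threshold == 0.0306
        assert c.ascending_displacement_threshold == 0.1
        assert c.descending_displacement_threshold == -0.12
        assert c.intense_motion_artifact_threshold == 3.7

    @pytest.mark.parametrize("kwargs", [
        {"descending_displacement_threshold": 0.1},
        {"fall_energy_threshold": -1.0},
        {"horizontal_posture_threshold": 7.0},       # above the vertical threshold
        {"resting_energy_threshold": 0.2},           # above the movement threshold
    ])
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            DetectorConfig(**kwargs)

    def test_profile_has_no_defaults(self):
        with pytest.raises(ValidationError):
            PersonProfile(weight_kg=75.0)

    def test_yaml_round_trip_and_partial_defaults(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("device:\n  fall_energy_threshold: 0.05\n")
        device, profile, alerts = load_config(path)
        assert device.fall_energy_threshold == 0.05
        assert device.vertical_posture_threshold == 6.5  # untouched default
        assert profile is None
        custom = DetectorConfig(fall_energy_threshold=0.2,
                                intense_motion_artifact_threshold=4.2)
        prof = PersonProfile(weight_kg=80.0, birth_date=datetime.date(1950, 3, 2),
                             gender="male", height_cm=170.0, thorax_perimeter_cm=100.0)
        out = tmp_path / "out.yaml"
        save_config(out, custom, prof, AlertConfig(prompt_timeout_s=20.0))
        d2, p2, a2 = load_config(out)
        assert d2 == custom
        assert p2 == prof
        assert a2.prompt_timeout_s == 20.0

    def test_empty_device_section_gives_defaults(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("device:\n")
        device, _, _ = load_config(path)
        assert device == DetectorConfig()


class TestAlertMachine:
    def test_fall_prompt_expires_to_auto_alert(self):
        m = AlertStateMachine()
        m.on_fall_event(make_fall_event(), now=100.0)
        assert m.state is AlertState.FALL_PROMPT
        assert m.prompt_deadline == 130.0
        m.tick(now=129.9)
        assert m.state is AlertState.FALL_PROMPT
        m.tick(now=130.0)
        assert m.state is AlertState.ALERT_SENT
        assert m.trigger is AlertTrigger.FALL_AUTO

    def test_in_time_ok_cancels(self):
        m = AlertStateMachine()
        m.on_fall_event(make_fall_event(), now=0.0)
        m.user_response("ok", now=29.0)
        assert m.state is AlertState.CANCELLED

    def test_help_needed_confirms(self):
        m = AlertStateMachine()
        m.on_fall_event(make_fall_event(), now=0.0)
        m.user_response("help_needed", now=5.0)
        assert m.state is AlertState.ALERT_SENT
        assert m.trigger is AlertTrigger.FALL_CONFIRMED

    def test_non_fall_event_is_noop(self):
        m = AlertStateMachine()
        m.on_fall_event(make_fall_event(is_fall=False), now=0.0)
        assert m.state is AlertState.IDLE

    def test_sos_hold_boundary(self):
        m = AlertStateMachine()
        m.on_sos_press(press_start=0.0, release=2.9)
        assert m.state is AlertState.IDLE
        m.on_sos_press(press_start=10.0, release=13.0)
        assert m.state is AlertState.SOS_COUNTDOWN
        m.tick(now=13.0 + 5.0)
        assert m.state is AlertState.ALERT_SENT
        assert m.trigger is AlertTrigger.SOS

    def test_sos_cancel_during_countdown(self):
        m = AlertStateMachine()
        m.on_sos_press(press_start=0.0, release=4.0)
        m.cancel(now=4.0)
        assert m.state is AlertState.CANCELLED

    def test_safety_and_liveness_by_exhaustive_enumeration(self):
        """alert_sent is unreachable without a fall, an expired prompt, or
        a completed SOS hold+countdown; fall_prompt always resolves."""
        actions = [
            ("fall", lambda m, t: m.on_fall_event(make_fall_event(), now=t)),
            ("nonfall", lambda m, t: m.on_fall_event(make_fall_event(False), now=t)),
            ("ok", lambda m, t: m.user_response("ok", now=t)),
            ("help", lambda m, t: m.user_response("help_needed", now=t)),
            ("sos_short", lambda m, t: m.on_sos_press(t, t + 2.0)),
            ("sos_long", lambda m, t: m.on_sos_press(t, t + 3.5)),
            ("cancel", lambda m, t: m.cancel(now=t)),
            ("tick_far", lambda m, t: m.tick(now=t + 100.0)),
        ]
        for length in range(1, 5):
            for combo in itertools.product(actions, repeat=length):
                m = AlertStateMachine()
                t = 0.0
                names = []
                for name, act in combo:
                    act(m, t)
                    names.append(name)
                    t += 1.0
                if m.state is AlertState.ALERT_SENT:
                    legit = (
                        ("fall" in names and ("tick_far" in names or "help" in names))
                        or "sos_long" in names
                    )
                    assert legit, names
                # liveness: a prompt opened and ticked far enough resolves
                if "fall" in names and names[-1] == "tick_far":
                    assert m.state is not AlertState.FALL_PROMPT

    def test_response_at_expired_deadline_sends_auto_alert(self):
        m = AlertStateMachine(config=AlertConfig(prompt_timeout_s=10.0))
        m.on_fall_event(make_fall_event(), now=0.0)
        m.user_response("ok", now=10.0)  # exactly at the deadline: too late
        assert m.state is AlertState.ALERT_SENT
        assert m.trigger is AlertTrigger.FALL_AUTO


class TestEventLog:
    def test_append_query_chronological(self):
        log = EventLog()
        log.append(1.0, "fall", {"x": 1})
        log.append(2.0, "alert")
        log.append(2.0, "activity_report")
        assert [r["type"] for r in log.query(0.0, 10.0)] == \
            ["fall", "alert", "activity_report"]
        assert log.query(5.0, 6.0) == []

    def test_out_of_order_append_rejected(self):
        log = EventLog()
        log.append(5.0, "fall")
        with pytest.raises(ValueError):
            log.append(4.0, "alert")

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            EventLog().query(3.0, 1.0)

    def test_jsonl_round_trip(self, tmp_path):
        log = EventLog()
        log.append(1.5, "breathing_summary", {"rate": 12.0})
        log.append(9.0, "heart_rate", {"bpm": 71})
        path = tmp_path / "log.jsonl"
        log.save_jsonl(path)
        again = EventLog.load_jsonl(path)
        assert again.records == log.records
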