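"""Smartwatch-side alert logic: fall prompt, SOS hold, event log.

Time is always injected (`now` arguments and explicit `tick`), never read
from a clock, so every behaviour is deterministic and enumerable in
tests.  The safety property the machine guarantees: ``alert_sent`` is
reachable only through a confirmed fall, an expired fall prompt, or a
completed ≥3 s SOS hold followed by its countdown.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

from .config import AlertConfig
from .falls import FallEvent


class AlertState(str, enum.Enum):
    IDLE = "idle"
    FALL_PROMPT = "fall_prompt"
    SOS_COUNTDOWN = "sos_countdown"
    ALERT_SENT = "alert_sent"
    CANCELLED = "cancelled"


class AlertTrigger(str, enum.Enum):
    FALL_AUTO = "fall_auto"
    FALL_CONFIRMED = "fall_confirmed"
    SOS = "sos"


@dataclass
class AlertStateMachine:
    config: AlertConfig = field(default_factory=AlertConfig)
    state: AlertState = AlertState.IDLE
    prompt_deadline: float | None = None
    countdown_deadline: float | None = None
    trigger: AlertTrigger | None = None
    transitions: list = field(default_factory=list)

    def _move(self, state: AlertState, now: float, why: str) -> None:
        self.transitions.append({"t": now, "from": self.state.value,
                                 "to": state.value, "why": why})
        self.state = state

    def _send(self, trigger: AlertTrigger, now: float) -> None:
        self.trigger = trigger
        self._move(AlertState.ALERT_SENT, now, trigger.value)

    # -- fall path ---------------------------------------------------------

    def on_fall_event(self, event: FallEvent, now: float) -> "AlertStateMachine":
        """A confirmed fall opens the help prompt; non-falls are no-ops."""
        if not event.is_fall or self.state is not AlertState.IDLE:
            return self
        self.prompt_deadline = now + self.config.prompt_timeout_s
        self._move(AlertState.FALL_PROMPT, now, "fall_detected")
        return self

    def user_response(self, response: str, now: float) -> "AlertStateMachine":
        """'help_needed' or 'ok' while the fall prompt is open."""
        if self.state is not AlertState.FALL_PROMPT:
            return self
        self.tick(now)
        if self.state is not AlertState.FALL_PROMPT:
            return self  # deadline already expired at `now`
        if response == "help_needed":
            self._send(AlertTrigger.FALL_CONFIRMED, now)
        elif response == "ok":
            self._move(AlertState.CANCELLED, now, "user_ok")
        else:
            raise ValueError("response must be 'help_needed' or 'ok'")
        return self

    # -- SOS path ----------------------------------------------------------

    def on_sos_press(self, press_start: float, release: float | None = None) -> "AlertStateMachine":
        """Press-and-hold: >= the hold duration starts the send countdown."""
        if self.state is not AlertState.IDLE:
            return self
        held = (release - press_start) if release is not None else float("inf")
        if held < self.config.sos_hold_s:
            return self
        start = press_start + self.config.sos_hold_s
        self.countdown_deadline = start + self.config.sos_countdown_s
        self._move(AlertState.SOS_COUNTDOWN, start, "sos_hold_complete")
        return self

    def cancel(self, now: float) -> "AlertStateMachine":
        """Cancel the SOS countdown before it elapses."""
        if self.state is not AlertState.SOS_COUNTDOWN:
            return self
        if self.countdown_deadline is not None and now >= self.countdown_deadline:
            self._send(AlertTrigger.SOS, self.countdown_deadline)
            return self
        self._move(AlertState.CANCELLED, now, "sos_cancelled")
        return self

    # -- clock -------------------------------------------------------------

    def tick(self, now: float) -> "AlertStateMachine":
        """Advance injected time; expired deadlines fire their transitions."""
        if (self.state is AlertState.FALL_PROMPT
                and self.prompt_deadline is not None and now >= self.prompt_deadline):
            self._send(AlertTrigger.FALL_AUTO, self.prompt_deadline)
        elif (self.state is AlertState.SOS_COUNTDOWN
                and self.countdown_deadline is not None and now >= self.countdown_deadline):
            self._send(AlertTrigger.SOS, self.countdown_deadline)
        return self

    def reset(self) -> "AlertStateMachine":
        """Return a terminal machine to idle (alert acknowledged)."""
        if self.state in (AlertState.ALERT_SENT, AlertState.CANCELLED):
            self.state = AlertState.IDLE
            self.prompt_deadline = self.countdown_deadline = None
            self.trigger = None
        return self


# ---------------------------------------------------------------------------
# Event log
# ---------------------------------------------------------------------------

@dataclass
class EventLog:
    """Append-only chronological log of typed gateway records.

    Records cover falls, alerts, activity reports, breathing summaries
    and passthrough types (heart rate, reminders); each entry is a dict
    with a monotone non-decreasing timestamp.
    """

    records: list = field(default_factory=list)

    def append(self, time_s: float, type_: str, data: dict | None = None) -> None:
        if self.records and time_s < self.records[-1]["t"]:
            raise ValueError("out-of-order append: the log is append-only and chronological")
        self.records.append({"t": float(time_s), "type": str(type_),
                             "data": data or {}})

    def query(self, start: float, end: float) -> list:
        if start > end:
            raise ValueError("invalid range: start > end")
        return [r for r in self.records if start <= r["t"] <= end]

    def save_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(r) + "\n")

    @classmethod
    def load_jsonl(cls, path) -> "EventLog":
        log = cls()
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    r = json.loads(line)
                    log.append(r["t"], r["type"], r.get("data"))
        return log
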