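"""Personalization parameters of the gateway API.

Two groups of parameters exist.  Device/algorithm thresholds
(:class:`DetectorConfig`) ship with defaults and may be tuned per subject;
anthropometric parameters (:class:`PersonProfile`) have no defaults and must
be configured before activity or metabolic processing can run.

Config files are YAML with a ``device:`` section (thresholds), an optional
``profile:`` section (anthropometrics) and an optional ``alerts:`` section
(prompt/countdown timings, which the original device does not document and
are therefore explicitly configurable).
"""

from __future__ import annotations

import datetime

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class DetectorConfig(BaseModel):
    """Device-side thresholds with their factory defaults.

    Units: posture thresholds are gravity projections in m/s²; energy
    thresholds are windowed variances of the acceleration magnitude in
    m²/s⁴; displacement thresholds are vertical excursions in metres
    (negative = downward); the motion-artifact threshold is a deviation of
    ‖a‖ from static gravity in m/s².
    """

    model_config = ConfigDict(validate_assignment=True)

    vertical_posture_threshold: float = 6.5
    fall_energy_threshold: float = 0.079
    horizontal_posture_threshold: float = 2.5
    movement_activity_energy_threshold: float = 0.1490
    resting_energy_threshold: float = 0.0306
    ascending_displacement_threshold: float = 0.1
    descending_displacement_threshold: float = -0.12
    intense_motion_artifact_threshold: float = 3.7

    @model_validator(mode="after")
    def _check_invariants(self) -> "DetectorConfig":
        positive = [
            "vertical_posture_threshold",
            "fall_energy_threshold",
            "horizontal_posture_threshold",
            "movement_activity_energy_threshold",
            "resting_energy_threshold",
            "ascending_displacement_threshold",
            "intense_motion_artifact_threshold",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.descending_displacement_threshold >= 0:
            raise ValueError("descending_displacement_threshold must be < 0")
        if self.horizontal_posture_threshold >= self.vertical_posture_threshold:
            raise ValueError(
                "horizontal_posture_threshold must be below vertical_posture_threshold"
            )
        if self.resting_energy_threshold >= self.movement_activity_energy_threshold:
            raise ValueError(
                "resting_energy_threshold must be below movement_activity_energy_threshold"
            )
        return self


class PersonProfile(BaseModel):
    """Anthropometric parameters — all required, no defaults."""

    weight_kg: float
    birth_date: datetime.date
    gender: str
    height_cm: float
    thorax_perimeter_cm: float

    @model_validator(mode="after")
    def _check_positive(self) -> "PersonProfile":
        for name in ("weight_kg", "height_cm", "thorax_perimeter_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        return self


class AlertConfig(BaseModel):
    """Timings of the alert state machine (device values undocumented)."""

    prompt_timeout_s: float = 30.0
    sos_hold_s: float = 3.0
    sos_countdown_s: float = 5.0

    @model_validator(mode="after")
    def _check_positive(self) -> "AlertConfig":
        for name in ("prompt_timeout_s", "sos_hold_s", "sos_countdown_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        return self


def load_config(path) -> tuple[DetectorConfig, PersonProfile | None, AlertConfig]:
    """Load a YAML config; unspecified device parameters take their defaults.

    The profile is returned as ``None`` when the ``profile:`` section is
    absent; operations that need anthropometrics refuse to run then.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    device = DetectorConfig(**(raw.get("device") or {}))
    alerts = AlertConfig(**(raw.get("alerts") or {}))
    profile = None
    if raw.get("profile"):
        profile = PersonProfile(**raw["profile"])
    return device, profile, alerts


def save_config(path, device: DetectorConfig,
                profile: PersonProfile | None = None,
                alerts: AlertConfig | None = None) -> None:
    payload: dict = {"device": device.model_dump()}
    if profile is not None:
        prof = profile.model_dump()
        prof["birth_date"] = profile.birth_date.isoformat()
        payload["profile"] = prof
    if alerts is not None:
        payload["alerts"] = alerts.model_dump()
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
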