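"""Typed records for participant sessions.

These are the plain-data inputs to the knowledge-graph builder: one daily
wearable activity observation, one external weather observation, the
participant's coaching preferences, and the activity goal specification the
daily/weekly evaluation runs against.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from datetime import date, datetime
from typing import Any

__all__ = [
    "ValidationError",
    "Participant",
    "ActivityObservation",
    "WeatherObservation",
    "Preferences",
    "GoalSpec",
]

MINUTES_PER_DAY = 1440

GOAL_TYPES = ("generic", "personalized")
GOAL_STYLES = ("direct", "motivational")
RESPONSE_TYPES = ("direct", "indirect")
INTERACTION_MEDIA = ("audio", "voice", "text", "graph")
INTERACTION_FREQUENCIES = ("hourly", "daily", "weekly", "monthly")


class ValidationError(ValueError):
    """A record violates its domain invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class Participant:
    participant_id: str
    first_name: str = "Test"
    last_name: str = "Participant"
    age: int = 35
    gender: str = "unspecified"
    role: str = "participant"
    email: str = ""

    def __post_init__(self) -> None:
        _require(bool(self.participant_id), "participant_id must be non-empty")
        _require(self.age >= 18, "participants are adults (age >= 18)")


@dataclass(frozen=True)
class ActivityObservation:
    """One day of wearable activity data for one participant.

    Waking-time components (LPA + MPA + VPA + sedentary) cannot exceed the
    1440 minutes in a day; sleep is recorded separately with the same cap.
    """

    participant_id: str
    date: date
    steps: int
    lpa_min: int
    mpa_min: int
    vpa_min: int
    sedentary_min: int
    sleep_min: int
    timestamp: datetime

    def __post_init__(self) -> None:
        for name in ("steps", "lpa_min", "mpa_min", "vpa_min", "sedentary_min", "sleep_min"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(
            self.lpa_min + self.mpa_min + self.vpa_min + self.sedentary_min
            <= MINUTES_PER_DAY,
            "LPA + MPA + VPA + sedentary minutes exceed one day",
        )
        _require(self.sleep_min <= MINUTES_PER_DAY, "sleep minutes exceed one day")

    @property
    def pa_total_min(self) -> int:
        """Total physical-activity minutes (LPA + MPA + VPA)."""
        return self.lpa_min + self.mpa_min + self.vpa_min


@dataclass(frozen=True)
class WeatherObservation:
    """One external weather record in the shape common weather APIs share."""

    city: str
    country: str
    weather_code: int
    status: str
    description: str
    temperature_c: float
    real_feel_c: float
    pressure_hpa: float
    humidity_pct: float
    visibility_m: float
    wind_speed_ms: float
    timestamp: datetime

    def __post_init__(self) -> None:
        _require(0 <= self.humidity_pct <= 100, "humidity_pct must lie in [0, 100]")
        _require(self.visibility_m >= 0, "visibility_m must be >= 0")
        _require(self.wind_speed_ms >= 0, "wind_speed_ms must be >= 0")


@dataclass(frozen=True)
class Preferences:
    """Coaching preferences: goal settings, response type, interaction type."""

    goal_type: str = "generic"          # generic | personalized
    goal_style: str = "motivational"    # direct | motivational
    response_type: str = "direct"       # direct | indirect
    interaction_mode: str = "style"
    interaction_medium: str = "text"    # audio | voice | text | graph
    interaction_frequency: str = "daily"  # hourly | daily | weekly | monthly
    notification_persistent: bool = False

    def __post_init__(self) -> None:
        _require(self.goal_type in GOAL_TYPES, f"goal_type must be one of {GOAL_TYPES}")
        _require(self.goal_style in GOAL_STYLES, f"goal_style must be one of {GOAL_STYLES}")
        _require(
            self.response_type in RESPONSE_TYPES,
            f"response_type must be one of {RESPONSE_TYPES}",
        )
        _require(
            self.interaction_medium in INTERACTION_MEDIA,
            f"interaction_medium must be one of {INTERACTION_MEDIA}",
        )
        _require(
            self.interaction_frequency in INTERACTION_FREQUENCIES,
            f"interaction_frequency must be one of {INTERACTION_FREQUENCIES}",
        )


@dataclass(frozen=True)
class GoalSpec:
    """Activity targets a day (or week) is evaluated against.

    The step and sleep targets form the primary objective; the sedentary cap
    and total-PA target are the secondary objective.
    """

    scope: str = "daily"  # daily | weekly
    step_target: int = 10_000
    sleep_target_min: int = 420
    sedentary_cap_min: int = 480
    pa_total_target_min: int = 30

    def __post_init__(self) -> None:
        _require(self.scope in ("daily", "weekly"), "scope must be daily|weekly")
        for name in ("step_target", "sleep_target_min", "sedentary_cap_min",
                     "pa_total_target_min"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")


def record_to_dict(rec: Any) -> dict:
    """JSON-ready dict for any of the records (dates → ISO-8601 strings)."""
    def _conv(v):
        if isinstance(v, (datetime, date)):
            return v.isoformat()
        return v

    return {k: _conv(v) for k, v in asdict(rec).items()}
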