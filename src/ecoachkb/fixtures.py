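"""Seeded synthetic session generator.

No public dataset exists for this tool: the verification surface is eight
canonical single-day test cases crossing the goal type (generic for cases
1–4, personalized for cases 5–8) with the two-bit daily status over
(step goal met, sleep goal met) — 11, 10, 01, 00.  The generator synthesizes
observation values that realize each achievement pattern with a configurable
margin around the targets (the pattern, not the specific count, is the
contract), under one constant weather context shared by all cases.

``random_session`` additionally produces multi-day sessions whose per-day
achievement bits are independent Bernoulli draws, for stress-testing the
pipeline beyond the canonical cases.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import (
    ActivityObservation,
    GoalSpec,
    Participant,
    Preferences,
    WeatherObservation,
)
from .rule_engine import RecommendationSet, decode_case, weather_config

__all__ = [
    "ParticipantSession",
    "EXPECTED_CASE_MESSAGES",
    "GENERIC_GOAL",
    "PERSONALIZED_GOAL",
    "constant_weather",
    "canonical_case",
    "all_canonical",
    "random_session",
    "session_to_json",
    "session_from_json",
]

#: Ground-truth message sets per verification case (todo, informal), frozen
#: from the published verification table; every canonical fixture's
#: ``expected`` map carries its row.
EXPECTED_CASE_MESSAGES: dict[int, tuple[tuple[str, ...], tuple[str, ...]]] = {
    1: (("A-3", "A-6", "A-8", "A-10", "A-12"), ("A-13", "C-1")),
    2: (("A-2", "A-5", "A-8", "A-10", "A-11"), ("A-14", "C-1")),
    3: (("A-1", "A-5", "A-7", "A-9", "A-12"), ("A-14", "C-1")),
    4: (("A-1", "A-5", "A-7", "A-9", "A-11"), ("A-14", "C-1")),
    5: (("A-4", "A-6", "A-8", "A-10", "A-12"), ("A-13", "C-1")),
    6: (("A-4", "A-5", "A-8", "A-9", "A-11"), ("A-14", "C-1")),
    7: (("A-3", "A-5", "A-7", "A-9", "A-12"), ("A-14", "C-1")),
    8: (("A-3", "A-5", "A-7", "A-9", "A-11"), ("A-14", "C-1")),
}

#: Generic goal: WHO-style daily guideline defaults (configurable, not
#: claimed as the guideline's exact numbers).
GENERIC_GOAL = GoalSpec(scope="daily", step_target=10_000, sleep_target_min=420,
                        sedentary_cap_min=480, pa_total_target_min=30)
#: Personalized goal: a distinct profile so cases 5–8 exercise the
#: personalized path.
PERSONALIZED_GOAL = GoalSpec(scope="daily", step_target=8_000, sleep_target_min=450,
                             sedentary_cap_min=480, pa_total_target_min=30)

#: Relative margin around a target within which synthesized values fall.
ACHIEVEMENT_MARGIN = 0.2

_BASE_DATE = _dt.date(2022, 6, 1)


@dataclass
class ParticipantSession:
    """One participant's days, weather context, preferences and goal,
    optionally with the expected per-day recommendation sets."""

    participant: Participant
    prefs: Preferences
    goal: GoalSpec
    days: list[ActivityObservation]
    weather: list[WeatherObservation]
    expected: dict[_dt.date, RecommendationSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dates = [d.date for d in self.days]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("observation dates must be strictly increasing")
        extra = set(self.expected) - set(dates)
        if extra:
            raise ValueError(f"expected map keys outside session dates: {extra}")


def constant_weather() -> WeatherObservation:
    """The constant weather context shared by all canonical fixtures."""
    cfg = weather_config()["constant"]
    return WeatherObservation(
        city=cfg["city"],
        country=cfg["country"],
        weather_code=cfg["weather_code"],
        status=cfg["status"],
        description=cfg["description"],
        temperature_c=cfg["temperature_c"],
        real_feel_c=cfg["real_feel_c"],
        pressure_hpa=cfg["pressure_hpa"],
        humidity_pct=cfg["humidity_pct"],
        visibility_m=cfg["visibility_m"],
        wind_speed_ms=cfg["wind_speed_ms"],
        timestamp=_dt.datetime.fromisoformat(cfg["timestamp"]),
    )


def _meet(rng: np.random.Generator, target: int, achieved: bool) -> int:
    """A value ≥ target (achieved) or strictly < target, within the margin."""
    u = float(rng.uniform(0.05, 1.0))
    if achieved:
        return int(target * (1.0 + ACHIEVEMENT_MARGIN * u))
    return min(int(target * (1.0 - ACHIEVEMENT_MARGIN * u)), target - 1)


def _observation(
    rng: np.random.Generator,
    participant_id: str,
    day: _dt.date,
    goal: GoalSpec,
    step_achieved: bool,
    sleep_achieved: bool,
) -> ActivityObservation:
    lpa = int(rng.integers(20, 60))
    mpa = int(rng.integers(10, 30))
    vpa = int(rng.integers(5, 15))
    sedentary = int(rng.integers(goal.sedentary_cap_min - 120, goal.sedentary_cap_min))
    return ActivityObservation(
        participant_id=participant_id,
        date=day,
        steps=_meet(rng, goal.step_target, step_achieved),
        lpa_min=lpa,
        mpa_min=mpa,
        vpa_min=vpa,
        sedentary_min=sedentary,
        sleep_min=_meet(rng, goal.sleep_target_min, sleep_achieved),
        timestamp=_dt.datetime.combine(day, _dt.time(21, 0)),
    )


def canonical_case(case_id: int, seed: int) -> ParticipantSession:
    """One canonical single-day verification session; deterministic per seed."""
    goal_type, step, sleep = decode_case(case_id)  # validates case_id
    rng = np.random.default_rng([seed % (2**31), case_id])
    goal = GENERIC_GOAL if goal_type == "generic" else PERSONALIZED_GOAL
    pid = f"P{case_id:03d}"
    participant = Participant(
        participant_id=pid,
        first_name=f"Case{case_id}",
        last_name="Sim",
        age=30 + case_id,
        gender="female" if case_id % 2 else "male",
        email=f"case{case_id}@example.org",
    )
    prefs = Preferences(goal_type=goal_type)
    obs = _observation(rng, pid, _BASE_DATE, goal, step, sleep)
    todo, informal = EXPECTED_CASE_MESSAGES[case_id]
    expected = {
        _BASE_DATE: RecommendationSet(todo=todo, informal=informal, date=_BASE_DATE)
    }
    return ParticipantSession(
        participant=participant,
        prefs=prefs,
        goal=goal,
        days=[obs],
        weather=[constant_weather()],
        expected=expected,
    )


def all_canonical(seed: int) -> list[ParticipantSession]:
    """All eight canonical sessions (4 generic + 4 personalized), one
    identical weather record across all."""
    return [canonical_case(case_id, seed) for case_id in range(1, 9)]


def random_session(
    n_days: int,
    profile: dict[str, float] | None = None,
    seed: int = 0,
    goal_type: str = "generic",
) -> ParticipantSession:
    """Multi-day session with Bernoulli per-day achievement.

    ``profile`` gives the marginal achievement probabilities
    (``p_step``, ``p_sleep``); observed frequencies converge to them.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    profile = dict(profile or {})
    p_step = profile.get("p_step", 0.5)
    p_sleep = profile.get("p_sleep", 0.5)
    for name, p in (("p_step", p_step), ("p_sleep", p_sleep)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    if goal_type not in ("generic", "personalized"):
        raise ValueError(f"goal_type must be generic|personalized, got {goal_type!r}")
    rng = np.random.default_rng(seed % (2**31))
    goal = GENERIC_GOAL if goal_type == "generic" else PERSONALIZED_GOAL
    pid = "R001"
    days = []
    for i in range(n_days):
        day = _BASE_DATE + _dt.timedelta(days=i)
        step = bool(rng.random() < p_step)
        sleep = bool(rng.random() < p_sleep)
        days.append(_observation(rng, pid, day, goal, step, sleep))
    return ParticipantSession(
        participant=Participant(participant_id=pid, first_name="Random", last_name="Sim"),
        prefs=Preferences(goal_type=goal_type),
        goal=goal,
        days=days,
        weather=[constant_weather()],
    )


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def session_to_json(session: ParticipantSession) -> str:
    def _obs(o: ActivityObservation) -> dict:
        return {
            "participant_id": o.participant_id,
            "date": o.date.isoformat(),
            "steps": o.steps,
            "lpa_min": o.lpa_min,
            "mpa_min": o.mpa_min,
            "vpa_min": o.vpa_min,
            "sedentary_min": o.sedentary_min,
            "sleep_min": o.sleep_min,
            "timestamp": o.timestamp.isoformat(),
        }

    def _weather(w: WeatherObservation) -> dict:
        return {
            "city": w.city, "country": w.country, "weather_code": w.weather_code,
            "status": w.status, "description": w.description,
            "temperature_c": w.temperature_c, "real_feel_c": w.real_feel_c,
            "pressure_hpa": w.pressure_hpa, "humidity_pct": w.humidity_pct,
            "visibility_m": w.visibility_m, "wind_speed_ms": w.wind_speed_ms,
            "timestamp": w.timestamp.isoformat(),
        }

    p = session.participant
    payload = {
        "participant": {
            "participant_id": p.participant_id, "first_name": p.first_name,
            "last_name": p.last_name, "age": p.age, "gender": p.gender,
            "role": p.role, "email": p.email,
        },
        "prefs": {
            "goal_type": session.prefs.goal_type,
            "goal_style": session.prefs.goal_style,
            "response_type": session.prefs.response_type,
            "interaction_mode": session.prefs.interaction_mode,
            "interaction_medium": session.prefs.interaction_medium,
            "interaction_frequency": session.prefs.interaction_frequency,
            "notification_persistent": session.prefs.notification_persistent,
        },
        "goal": {
            "scope": session.goal.scope,
            "step_target": session.goal.step_target,
            "sleep_target_min": session.goal.sleep_target_min,
            "sedentary_cap_min": session.goal.sedentary_cap_min,
            "pa_total_target_min": session.goal.pa_total_target_min,
        },
        "days": [_obs(o) for o in session.days],
        "weather": [_weather(w) for w in session.weather],
        "expected": {
            d.isoformat(): {"todo": list(r.todo), "informal": list(r.informal)}
            for d, r in session.expected.items()
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def session_from_json(text: str) -> ParticipantSession:
    raw = json.loads(text)
    return ParticipantSession(
        participant=Participant(**raw["participant"]),
        prefs=Preferences(**raw["prefs"]),
        goal=GoalSpec(**raw["goal"]),
        days=[
            ActivityObservation(
                participant_id=o["participant_id"],
                date=_dt.date.fromisoformat(o["date"]),
                steps=o["steps"], lpa_min=o["lpa_min"], mpa_min=o["mpa_min"],
                vpa_min=o["vpa_min"], sedentary_min=o["sedentary_min"],
                sleep_min=o["sleep_min"],
                timestamp=_dt.datetime.fromisoformat(o["timestamp"]),
            )
            for o in raw["days"]
        ],
        weather=[
            WeatherObservation(
                city=w["city"], country=w["country"], weather_code=w["weather_code"],
                status=w["status"], description=w["description"],
                temperature_c=w["temperature_c"], real_feel_c=w["real_feel_c"],
                pressure_hpa=w["pressure_hpa"], humidity_pct=w["humidity_pct"],
                visibility_m=w["visibility_m"], wind_speed_ms=w["wind_speed_ms"],
                timestamp=_dt.datetime.fromisoformat(w["timestamp"]),
            )
            for w in raw["weather"]
        ],
        expected={
            _dt.date.fromisoformat(d): RecommendationSet(
                todo=tuple(r["todo"]), informal=tuple(r["informal"]),
                date=_dt.date.fromisoformat(d),
            )
            for d, r in raw.get("expected", {}).items()
        },
    )


def write_session(session: ParticipantSession, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(session_to_json(session), encoding="utf-8")
    return path


def read_session(path: str | Path) -> ParticipantSession:
    return session_from_json(Path(path).read_text(encoding="utf-8"))
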