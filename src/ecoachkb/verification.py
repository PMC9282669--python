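"""Verification procedures: retrieval precision and the exclusivity guarantee.

``retrieval_precision`` rebuilds the canonical fixture graphs, runs every
shipped retrieval query, and scores each returned binding against the
generator's ground-truth records.  ``max_once_a_day_emissions`` enumerates
all 64 admissible input truth assignments (goal type × step × sleep ×
sedentary × PA × weather) and reports the largest number of once-a-day
messages any emission set contains.
"""

from __future__ import annotations

from itertools import product

from .fixtures import all_canonical
from .graph import run_query, shipped_query
from .pipeline import recommend_session, session_graph
from .rule_engine import RuleBase, default_rulebase, evaluate
from .schema import DATA

__all__ = ["retrieval_precision", "max_once_a_day_emissions", "enumerate_assignments"]


def _score(row: dict, truth: dict) -> tuple[int, int]:
    """(correct, total) over the bindings the ground truth constrains."""
    correct = 0
    total = 0
    for key, expected in truth.items():
        total += 1
        got = row.get(key)
        if isinstance(expected, float):
            if got is not None and abs(float(got) - expected) < 1e-9:
                correct += 1
        elif got == expected:
            correct += 1
    return correct, total


def retrieval_precision(seed: int) -> tuple[float, int]:
    """Percent of correctly retrieved bindings over all canonical fixtures.

    Returns ``(precision_percent, n_bindings)``.
    """
    correct = 0
    total = 0
    for session in all_canonical(seed):
        pid = session.participant.participant_id
        kg = session_graph(session)
        results = recommend_session(session, kg=kg)

        obs = session.days[0]
        rows = run_query(kg, shipped_query("activity_by_day"))
        truth = {
            "participant": str(DATA[f"{pid}/Participant/0"]),
            "datetime": obs.timestamp,
            "steps": obs.steps,
            "lpa": obs.lpa_min,
            "mpa": obs.mpa_min,
            "vpa": obs.vpa_min,
            "sedentary": obs.sedentary_min,
            "sleep": obs.sleep_min,
        }
        c, t = _score(rows[0] if rows else {}, truth)
        correct, total = correct + c, total + t

        rows = run_query(kg, shipped_query("preferences"))
        truth = {
            "participant": str(DATA[f"{pid}/Participant/0"]),
            "goalType": session.prefs.goal_type,
            "goalStyle": session.prefs.goal_style,
            "responseType": session.prefs.response_type,
            "medium": session.prefs.interaction_medium,
            "frequency": session.prefs.interaction_frequency,
        }
        c, t = _score(rows[0] if rows else {}, truth)
        correct, total = correct + c, total + t

        weather = session.weather[0]
        rows = run_query(kg, shipped_query("weather_context"))
        truth = {
            "city": weather.city,
            "country": weather.country,
            "code": weather.weather_code,
            "temperature": float(weather.temperature_c),
            "humidity": float(weather.humidity_pct),
            "wind": float(weather.wind_speed_ms),
        }
        c, t = _score(rows[0] if rows else {}, truth)
        correct, total = correct + c, total + t

        rows = run_query(kg, shipped_query("recommendations_delivered"))
        expected_codes = {
            code
            for _, (_, _, recset) in results.items()
            for code in recset.todo + recset.informal
        }
        got_codes = {row.get("code") for row in rows}
        for code in sorted(expected_codes):
            total += 1
            if code in got_codes:
                correct += 1
        for code in sorted(got_codes - expected_codes):
            total += 1  # spurious binding counts against precision

    return (100.0 * correct / total if total else 0.0), total


def enumerate_assignments():
    """All 64 admissible base-fact assignments."""
    for generic, step, sleep, sed, pa, outdoor in product([True, False], repeat=6):
        yield {
            "goal_generic": generic,
            "goal_personalized": not generic,
            "step_goal_met": step,
            "sleep_goal_met": sleep,
            "sedentary_ok": sed,
            "pa_total_ok": pa,
            "weather_outdoor_ok": outdoor,
        }


def max_once_a_day_emissions(rulebase: RuleBase | None = None) -> tuple[int, int]:
    """Largest once-a-day intersection over the exhaustive enumeration.

    Returns ``(max_count, n_assignments)``.
    """
    rulebase = rulebase if rulebase is not None else default_rulebase()
    group = set(rulebase.exclusivity_groups.get("once_a_day", {"A-13", "A-14"}))
    worst = 0
    n = 0
    for facts in enumerate_assignments():
        result = evaluate(rulebase, facts)
        worst = max(worst, len(set(result.emissions) & group))
        n += 1
    return worst, n
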