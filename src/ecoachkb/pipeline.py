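"""End-to-end wiring: session → knowledge graph → rules → recommendations."""

from __future__ import annotations

from .fixtures import ParticipantSession
from .graph import KnowledgeGraph, add_recommendations, build_graph
from .rule_engine import (
    DailyStatus,
    RecommendationSet,
    RuleBase,
    WeatherThresholds,
    recommend_day,
)
from .schema import SchemaDef, default_schema

__all__ = ["session_graph", "recommend_session"]


def session_graph(
    session: ParticipantSession, schema: SchemaDef | None = None
) -> KnowledgeGraph:
    """Build the participant knowledge graph for one session."""
    return build_graph(
        schema or default_schema(),
        session.participant,
        session.days,
        session.weather,
        session.prefs,
        goal=session.goal,
    )


def recommend_session(
    session: ParticipantSession,
    rulebase: RuleBase | None = None,
    thresholds: WeatherThresholds | None = None,
    kg: KnowledgeGraph | None = None,
) -> dict:
    """Run the daily pipeline for every day of a session.

    Returns ``{date: (DailyStatus, case_id, RecommendationSet)}``; when a
    graph is supplied the delivered recommendations are also written into it
    as ActivityRecommendation individuals.
    """
    results: dict = {}
    weather_obs = session.weather[0] if session.weather else None
    if weather_obs is None:
        raise ValueError("session has no weather context")
    for obs in session.days:
        status, case_id, recset = recommend_day(
            obs, session.goal, session.prefs.goal_type, weather_obs,
            rulebase=rulebase, thresholds=thresholds,
        )
        results[obs.date] = (status, case_id, recset)
        if kg is not None:
            add_recommendations(
                kg, session.participant.participant_id, obs.date,
                recset.todo, recset.informal, recset.fired_rules,
            )
    return results
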