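"""Build, serialize, persist, query and validate the participant knowledge graph.

The graph holds RDF triples: one ``Participant`` individual per person,
linked to an ``ActivityData`` health record whose ``ActivityDataValue``
individuals carry the daily wearable observations, ``ContextData``
individuals carrying ``ExternalWeatherValue`` records, a ``Preferences``
individual (goal / interaction / response type), and — once the rule engine
has run — delivered ``ActivityRecommendation`` individuals.

Individual IRIs are minted deterministically as
``<…/data#{participant_id}/{Class}/{date-or-seq}>`` so that identical inputs
produce identical graphs.  Persistence writes canonically sorted N-Triples
(a Turtle subset), which makes repeated saves byte-identical.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdflib import Graph, Literal, RDF, URIRef
from rdflib.plugins.parsers.notation3 import BadSyntax

from .records import (
    ActivityObservation,
    GoalSpec,
    Participant,
    Preferences,
    ValidationError,
    WeatherObservation,
)
from .schema import DATA, ONTO, SchemaDef, default_schema

__all__ = [
    "KnowledgeGraph",
    "Violation",
    "GraphConflictError",
    "TurtleParseError",
    "QueryError",
    "StorageError",
    "build_graph",
    "add_recommendations",
    "serialize_turtle",
    "parse_turtle",
    "run_query",
    "validate_graph",
    "persist",
    "load",
    "shipped_query",
    "SHIPPED_QUERIES",
]


class GraphConflictError(ValueError):
    """Attempt to add a participant whose id already exists in the graph."""


class TurtleParseError(ValueError):
    """Malformed Turtle input; carries the offending line when known."""

    def __init__(self, message: str, line: int | None = None) -> None:
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class QueryError(ValueError):
    """Syntactically invalid SPARQL (including unknown prefixes)."""


class StorageError(OSError):
    """Persistence failure (missing path, unreadable file, ...)."""


@dataclass
class KnowledgeGraph:
    """An rdflib graph paired with the schema its individuals are typed by."""

    graph: Graph = field(default_factory=Graph)
    schema: SchemaDef = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        self.graph.bind("onto", ONTO)
        self.graph.bind("data", DATA)

    def triples(self) -> set[tuple]:
        return set(self.graph)

    def __len__(self) -> int:
        return len(self.graph)

    def participants(self) -> set[str]:
        return {
            str(s).rsplit("#", 1)[1].split("/", 1)[0]
            for s in self.graph.subjects(RDF.type, ONTO.Participant)
        }


@dataclass(frozen=True)
class Violation:
    """One structural-consistency violation found by :func:`validate_graph`."""

    kind: str  # disjointness | cardinality | domain | range | functional | unknown_class
    subject: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.subject}: {self.detail}"


# ---------------------------------------------------------------------------
# IRI minting
# ---------------------------------------------------------------------------

def _iri(participant_id: str, cls: str, key: str | int) -> URIRef:
    return DATA[f"{participant_id}/{cls}/{key}"]


def _lit_dt(ts: _dt.datetime) -> Literal:
    return Literal(ts.isoformat(), datatype=URIRef("http://www.w3.org/2001/XMLSchema#dateTime"))


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_graph(
    schema: SchemaDef,
    participant: Participant,
    observations: Sequence[ActivityObservation],
    weather: Sequence[WeatherObservation],
    prefs: Preferences,
    goal: GoalSpec | None = None,
    kg: KnowledgeGraph | None = None,
) -> KnowledgeGraph:
    """Assemble the knowledge graph for one participant.

    Pass an existing ``kg`` to add a further participant to it; adding the
    same participant id twice raises :class:`GraphConflictError`.
    """
    schema.validate()
    kg = kg if kg is not None else KnowledgeGraph(schema=schema)
    pid = participant.participant_id
    if pid in kg.participants():
        raise GraphConflictError(f"participant {pid!r} already present in graph")
    for obs in observations:
        if obs.participant_id != pid:
            raise ValidationError(
                f"observation for {obs.participant_id!r} attached to participant {pid!r}"
            )
    g = kg.graph

    person = _iri(pid, "Participant", 0)
    g.add((person, RDF.type, ONTO.Participant))
    g.add((person, ONTO.hasUniqueUserId, Literal(pid)))
    g.add((person, ONTO.hasFirstName, Literal(participant.first_name)))
    g.add((person, ONTO.hasLastName, Literal(participant.last_name)))
    g.add((person, ONTO.hasAge, Literal(participant.age)))
    g.add((person, ONTO.hasGender, Literal(participant.gender)))
    g.add((person, ONTO.hasRole, Literal(participant.role)))
    if participant.email:
        g.add((person, ONTO.hasEmail, Literal(participant.email)))

    record = _iri(pid, "ActivityData", 0)
    g.add((record, RDF.type, ONTO.ActivityData))
    g.add((person, ONTO.hasHealthRecord, record))

    for obs in observations:
        value = _iri(pid, "ActivityDataValue", obs.date.isoformat())
        g.add((value, RDF.type, ONTO.ActivityDataValue))
        g.add((record, ONTO.hasBeenCollectedBy, value))
        g.add((value, ONTO.hasDateTime, _lit_dt(obs.timestamp)))
        g.add((value, ONTO.hasSteps, Literal(obs.steps)))
        g.add((value, ONTO.hasLpaMinutes, Literal(obs.lpa_min)))
        g.add((value, ONTO.hasMpaMinutes, Literal(obs.mpa_min)))
        g.add((value, ONTO.hasVpaMinutes, Literal(obs.vpa_min)))
        g.add((value, ONTO.hasSedentaryMinutes, Literal(obs.sedentary_min)))
        g.add((value, ONTO.hasSleepMinutes, Literal(obs.sleep_min)))

    for seq, w in enumerate(weather):
        context = _iri(pid, "ContextData", seq)
        value = _iri(pid, "ExternalWeatherValue", seq)
        g.add((context, RDF.type, ONTO.ContextData))
        g.add((value, RDF.type, ONTO.ExternalWeatherValue))
        g.add((context, ONTO.hasContextValue, value))
        g.add((value, ONTO.hasDateTime, _lit_dt(w.timestamp)))
        g.add((value, ONTO.hasCity, Literal(w.city)))
        g.add((value, ONTO.hasCountry, Literal(w.country)))
        g.add((value, ONTO.hasWeatherCode, Literal(w.weather_code)))
        g.add((value, ONTO.hasWeatherStatus, Literal(w.status)))
        g.add((value, ONTO.hasWeatherDescription, Literal(w.description)))
        g.add((value, ONTO.hasTemperature, _decimal(w.temperature_c)))
        g.add((value, ONTO.hasRealFeel, _decimal(w.real_feel_c)))
        g.add((value, ONTO.hasPressure, _decimal(w.pressure_hpa)))
        g.add((value, ONTO.hasHumidity, _decimal(w.humidity_pct)))
        g.add((value, ONTO.hasVisibility, _decimal(w.visibility_m)))
        g.add((value, ONTO.hasWindSpeed, _decimal(w.wind_speed_ms)))

    pref = _iri(pid, "Preferences", 0)
    g.add((pref, RDF.type, ONTO.Preferences))
    g.add((person, ONTO.hasPreferences, pref))

    goal_cls = "Weekly" if (goal is not None and goal.scope == "weekly") else "Daily"
    goal_node = _iri(pid, "Goal", 0)
    g.add((goal_node, RDF.type, ONTO[goal_cls]))
    g.add((pref, ONTO.hasGoal, goal_node))
    g.add((goal_node, ONTO.hasGoalType, Literal(prefs.goal_type)))
    g.add((goal_node, ONTO.hasGoalStyle, Literal(prefs.goal_style)))
    if goal is not None:
        g.add((goal_node, ONTO.hasStepTarget, Literal(goal.step_target)))
        g.add((goal_node, ONTO.hasSleepTargetMinutes, Literal(goal.sleep_target_min)))
        g.add((goal_node, ONTO.hasSedentaryCapMinutes, Literal(goal.sedentary_cap_min)))
        g.add((goal_node, ONTO.hasPaTotalTargetMinutes, Literal(goal.pa_total_target_min)))

    response = _iri(pid, "ResponseType", 0)
    g.add((response, RDF.type, ONTO.ResponseType))
    g.add((pref, ONTO.hasResponseType, response))
    g.add((response, ONTO.hasResponseTypeValue, Literal(prefs.response_type)))

    interaction = _iri(pid, "Interaction", 0)
    g.add((interaction, RDF.type, ONTO.Interaction))
    g.add((pref, ONTO.hasInteractionType, interaction))
    g.add((interaction, ONTO.hasInteractionMode, Literal(prefs.interaction_mode)))
    g.add((interaction, ONTO.hasInteractionMedium, Literal(prefs.interaction_medium)))
    g.add((interaction, ONTO.hasInteractionFrequency, Literal(prefs.interaction_frequency)))
    g.add((interaction, ONTO.hasNotificationPersistent,
           Literal(prefs.notification_persistent)))

    return kg


def _decimal(value: float) -> Literal:
    from decimal import Decimal

    return Literal(Decimal(str(value)))


def add_recommendations(
    kg: KnowledgeGraph,
    participant_id: str,
    date: _dt.date,
    todo: Iterable[str],
    informal: Iterable[str],
    fired_rules: Iterable[str] = (),
) -> KnowledgeGraph:
    """Write a day's delivered recommendations into the graph.

    Each message becomes an ``ActivityRecommendation`` individual linked from
    the participant via ``hasReceivedRecommendation`` and to a ``ToDo`` or
    ``Informal`` intent individual via ``hasMessageIntent``.
    """
    g = kg.graph
    person = _iri(participant_id, "Participant", 0)
    if (person, RDF.type, ONTO.Participant) not in g:
        raise GraphConflictError(f"participant {participant_id!r} not in graph")
    stamp = _dt.datetime.combine(date, _dt.time(23, 59))
    fired = sorted(fired_rules)
    for intent_cls, codes in (("ToDo", todo), ("Informal", informal)):
        intent_node = _iri(participant_id, intent_cls, 0)
        g.add((intent_node, RDF.type, ONTO[intent_cls]))
        for code in codes:
            rec = _iri(participant_id, "ActivityRecommendation",
                       f"{date.isoformat()}/{code}")
            g.add((rec, RDF.type, ONTO.ActivityRecommendation))
            g.add((person, ONTO.hasReceivedRecommendation, rec))
            g.add((rec, ONTO.hasMessageIntent, intent_node))
            g.add((rec, ONTO.hasMessageCode, Literal(code)))
            g.add((rec, ONTO.hasRecommendationDateTime, _lit_dt(stamp)))
            for rule_id in fired:
                g.add((rec, ONTO.hasFiredRule, Literal(rule_id)))
    return kg


# ---------------------------------------------------------------------------
# serialization / persistence
# ---------------------------------------------------------------------------

def serialize_turtle(kg: KnowledgeGraph) -> str:
    """Valid Turtle text; :func:`parse_turtle` inverts it on the triple set."""
    return kg.graph.serialize(format="turtle")


def parse_turtle(text: str, schema: SchemaDef | None = None) -> KnowledgeGraph:
    kg = KnowledgeGraph(schema=schema or default_schema())
    try:
        kg.graph.parse(data=text, format="turtle")
    except BadSyntax as exc:  # rdflib reports the offending line
        raise TurtleParseError(str(exc.message or exc), line=exc.lines + 1) from exc
    except Exception as exc:  # pragma: no cover - defensive
        raise TurtleParseError(str(exc)) from exc
    return kg


def _canonical_lines(kg: KnowledgeGraph) -> list[str]:
    tmp = Graph()
    for t in kg.graph:
        tmp.add(t)
    nt = tmp.serialize(format="nt")
    return sorted(line for line in nt.splitlines() if line.strip())


def persist(kg: KnowledgeGraph, path: str | Path) -> Path:
    """Write the graph as canonically ordered N-Triples (a Turtle subset).

    Sorting by subject, predicate, object makes two persists of equal graphs
    byte-identical.
    """
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("\n".join(_canonical_lines(kg)) + "\n", encoding="utf-8")
    except OSError as exc:
        raise StorageError(f"cannot persist graph to {path}: {exc}") from exc
    return path


def load(path: str | Path, schema: SchemaDef | None = None) -> KnowledgeGraph:
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise StorageError(f"cannot load graph from {path}: {exc}") from exc
    return parse_turtle(text, schema=schema)


# ---------------------------------------------------------------------------
# querying
# ---------------------------------------------------------------------------

#: Names of the retrieval queries shipped as package data under queries/.
SHIPPED_QUERIES = (
    "activity_by_day",
    "preferences",
    "weather_context",
    "recommendations_delivered",
)


def shipped_query(name: str) -> str:
    """Text of one shipped SPARQL SELECT query (see :data:`SHIPPED_QUERIES`)."""
    from importlib.resources import files

    if name not in SHIPPED_QUERIES:
        raise KeyError(f"unknown query {name!r}; available: {SHIPPED_QUERIES}")
    return (files("ecoachkb") / "queries" / f"{name}.rq").read_text(encoding="utf-8")


def run_query(kg: KnowledgeGraph, query: str) -> list[dict[str, object]]:
    """Run a SPARQL 1.1 SELECT query; rows are dicts of plain Python values.

    IRIs come back as strings, literals as their Python-native values.
    Row order follows the query's ORDER BY when present.
    """
    try:
        result = kg.graph.query(query)
    except Exception as exc:
        raise QueryError(f"invalid SPARQL query: {exc}") from exc
    rows: list[dict[str, object]] = []
    for binding in result:
        row: dict[str, object] = {}
        for var, value in zip(result.vars, binding):
            if value is None:
                continue
            if isinstance(value, Literal):
                row[str(var)] = value.toPython()
            else:
                row[str(var)] = str(value)
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------

def validate_graph(kg: KnowledgeGraph) -> list[Violation]:
    """Structural consistency check standing in for a description-logic reasoner.

    Reports: individuals typed by two disjoint classes, missing
    min-cardinality values, property uses whose subject/object fall outside
    the declared domain/range, and functional / inverse-functional property
    violations.  An empty list means the graph is consistent.
    """
    schema = kg.schema
    g = kg.graph
    violations: list[Violation] = []

    types: dict[URIRef, set[str]] = {}
    for s, o in g.subject_objects(RDF.type):
        if not str(o).startswith(str(ONTO)):
            continue
        name = _local(o)
        types.setdefault(s, set()).add(name)
        if name not in schema.classes:
            violations.append(Violation("unknown_class", str(s),
                                        f"typed by undeclared class {name}"))

    # (a) disjointness
    for ind, clss in sorted(types.items(), key=lambda kv: str(kv[0])):
        names = sorted(c for c in clss if c in schema.classes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if schema.are_disjoint(a, b):
                    violations.append(Violation(
                        "disjointness", str(ind),
                        f"typed by disjoint classes {a} and {b}"))

    # (b) min-cardinality
    for prop in schema.object_properties + schema.data_properties:
        if prop.min_cardinality <= 0:
            continue
        applicable = schema.descendants(prop.domain)
        pred = ONTO[prop.name]
        for ind, clss in sorted(types.items(), key=lambda kv: str(kv[0])):
            if clss & applicable:
                count = sum(1 for _ in g.objects(ind, pred))
                if count < prop.min_cardinality:
                    violations.append(Violation(
                        "cardinality", str(ind),
                        f"{prop.name} requires >= {prop.min_cardinality} value(s), "
                        f"found {count}"))

    # (c) domain / range for every used schema property
    for s, p, o in sorted(g, key=lambda t: (str(t[0]), str(t[1]), str(t[2]))):
        if p == RDF.type or not str(p).startswith(str(ONTO)):
            continue
        prop = schema.property(_local(p) or "")
        if prop is None:
            continue
        dom = schema.descendants(prop.domain)
        if not (types.get(s, set()) & dom):
            violations.append(Violation(
                "domain", str(s),
                f"subject of {prop.name} is not a {prop.domain}"))
        if prop.kind == "object":
            if isinstance(o, Literal):
                violations.append(Violation(
                    "range", str(s),
                    f"object property {prop.name} points at a literal"))
            elif not (types.get(o, set()) & schema.descendants(prop.range)):
                violations.append(Violation(
                    "range", str(o),
                    f"object of {prop.name} is not a {prop.range}"))
        else:
            if not isinstance(o, Literal):
                violations.append(Violation(
                    "range", str(s),
                    f"data property {prop.name} points at a non-literal"))

    # (d) functional / inverse-functional uniqueness
    for prop in schema.object_properties + schema.data_properties:
        pred = ONTO[prop.name]
        if "functional" in prop.characteristics:
            for s in sorted(set(g.subjects(pred, None)), key=str):
                values = set(g.objects(s, pred))
                if len(values) > 1:
                    violations.append(Violation(
                        "functional", str(s),
                        f"functional property {prop.name} has {len(values)} values"))
        if "inverse_functional" in prop.characteristics:
            for o in sorted(set(g.objects(None, pred)), key=str):
                subjects = set(g.subjects(pred, o))
                if len(subjects) > 1:
                    violations.append(Violation(
                        "functional", str(o),
                        f"inverse-functional property {prop.name} identifies "
                        f"{len(subjects)} subjects"))

    return violations


def _local(node: object) -> str | None:
    text = str(node)
    if "#" in text:
        return text.rsplit("#", 1)[1]
    return None
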