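"""Graph construction, serialization round trips, querying and validation."""

import datetime as dt

import pytest
from rdflib import RDF

from ecoachkb import (
    GoalSpec,
    Participant,
    Preferences,
    build_graph,
    load,
    parse_turtle,
    persist,
    run_query,
    serialize_turtle,
    session_graph,
    shipped_query,
    validate_graph,
)
from ecoachkb.fixtures import canonical_case, constant_weather
from ecoachkb.graph import (
    GraphConflictError,
    KnowledgeGraph,
    QueryError,
    StorageError,
    TurtleParseError,
)
from ecoachkb.records import ActivityObservation, ValidationError
from ecoachkb.schema import DATA, ONTO

from oracles import bgp_match


def _observation(pid="P900", day=dt.date(2022, 6, 1), **kw):
    defaults = dict(steps=9000, lpa_min=40, mpa_min=20, vpa_min=10,
                    sedentary_min=400, sleep_min=430,
                    timestamp=dt.datetime(2022, 6, 1, 21, 0))
    defaults.update(kw)
    return ActivityObservation(participant_id=pid, date=day, **defaults)


class TestBuildGraph:
    def test_participant_linked_to_preferences(self, schema):
        kg = build_graph(schema, Participant("P900"), [_observation()],
                         [constant_weather()], Preferences())
        person = DATA["P900/Participant/0"]
        prefs = list(kg.graph.objects(person, ONTO.hasPreferences))
        assert len(prefs) == 1
        assert (prefs[0], RDF.type, ONTO.Preferences) in kg.graph

    def test_empty_observation_list_still_valid(self, schema):
        kg = build_graph(schema, Participant("P901"), [], [], Preferences())
        assert validate_graph(kg) == []
        assert not list(kg.graph.subjects(RDF.type, ONTO.ActivityDataValue))

    def test_triple_count_matches_per_record_tally(self, case1_session):
        """Independent tally: fixed triples per participant plus a constant
        per-observation and per-weather-record overhead."""
        kg = session_graph(case1_session)
        n_participant = 9   # type + id + 6 profile literals + health record link
        n_record = 1        # ActivityData type
        n_prefs = 19        # prefs/goal/response/interaction nodes and payload
        per_obs = 9
        per_weather = 15
        expected = (
            n_participant + n_record + n_prefs
            + per_obs * len(case1_session.days)
            + per_weather * len(case1_session.weather)
        )
        assert len(kg) == expected

    def test_duplicate_participant_rejected(self, schema):
        kg = build_graph(schema, Participant("P902"), [], [], Preferences())
        with pytest.raises(GraphConflictError):
            build_graph(schema, Participant("P902"), [], [], Preferences(), kg=kg)

    def test_two_participants_share_one_graph(self, schema):
        kg = build_graph(schema, Participant("P903"), [], [], Preferences())
        kg = build_graph(schema, Participant("P904"), [], [], Preferences(), kg=kg)
        assert kg.participants() == {"P903", "P904"}
        assert validate_graph(kg) == []

    def test_foreign_observation_rejected(self, schema):
        with pytest.raises(ValidationError):
            build_graph(schema, Participant("P905"),
                        [_observation(pid="SOMEONE_ELSE")], [], Preferences())


class TestRoundTrips:
    def test_empty_graph_round_trip(self):
        kg = KnowledgeGraph()
        assert parse_turtle(serialize_turtle(kg)).triples() == set()

    def test_turtle_round_trip_is_identity(self, case1_graph):
        back = parse_turtle(serialize_turtle(case1_graph))
        assert back.triples() == case1_graph.triples()

    def test_hand_written_document_parses_exactly(self):
        text = """
        @prefix onto: <https://example.org/ecoach/onto#> .
        @prefix data: <https://example.org/ecoach/data#> .
        data:x a onto:Participant .
        data:x onto:hasFirstName "Ada" .
        data:x onto:hasLastName "L" .
        """
        assert len(parse_turtle(text).triples()) == 3

    def test_malformed_turtle_reports_line(self):
        with pytest.raises(TurtleParseError):
            parse_turtle("this is not turtle @@@")

    def test_persist_load_round_trip(self, case1_graph, tmp_path):
        path = persist(case1_graph, tmp_path / "case1.ttl")
        assert load(path).triples() == case1_graph.triples()

    def test_persist_is_byte_deterministic(self, case1_graph, tmp_path):
        a = persist(case1_graph, tmp_path / "a.ttl").read_bytes()
        b = persist(case1_graph, tmp_path / "b.ttl").read_bytes()
        assert a == b

    def test_load_missing_path_raises_storage_error(self, tmp_path):
        with pytest.raises(StorageError):
            load(tmp_path / "absent.ttl")


class TestQueries:
    def test_select_on_empty_graph_returns_no_rows(self):
        rows = run_query(KnowledgeGraph(), shipped_query("activity_by_day"))
        assert rows == []

    def test_activity_query_returns_generator_values(self, case1_session, case1_graph):
        rows = run_query(case1_graph, shipped_query("activity_by_day"))
        assert len(rows) == 1
        obs = case1_session.days[0]
        assert rows[0]["steps"] == obs.steps
        assert rows[0]["sleep"] == obs.sleep_min
        assert rows[0]["sedentary"] == obs.sedentary_min

    def test_syntax_error_raises_query_error(self, case1_graph):
        with pytest.raises(QueryError):
            run_query(case1_graph, "SELECT WHERE { broken")

    def test_unknown_prefix_raises_query_error(self, case1_graph):
        with pytest.raises(QueryError):
            run_query(case1_graph, "SELECT ?s WHERE { ?s missing:p ?o }")

    @pytest.mark.parametrize("name,patterns", [
        ("activity_by_day", [
            ("?participant", ONTO.hasHealthRecord, "?record"),
            ("?record", ONTO.hasBeenCollectedBy, "?value"),
            ("?value", ONTO.hasDateTime, "?datetime"),
            ("?value", ONTO.hasSteps, "?steps"),
            ("?value", ONTO.hasLpaMinutes, "?lpa"),
            ("?value", ONTO.hasMpaMinutes, "?mpa"),
            ("?value", ONTO.hasVpaMinutes, "?vpa"),
            ("?value", ONTO.hasSedentaryMinutes, "?sedentary"),
            ("?value", ONTO.hasSleepMinutes, "?sleep"),
        ]),
        ("preferences", [
            ("?participant", ONTO.hasPreferences, "?prefs"),
            ("?prefs", ONTO.hasGoal, "?goal"),
            ("?goal", ONTO.hasGoalType, "?goalType"),
            ("?goal", ONTO.hasGoalStyle, "?goalStyle"),
            ("?prefs", ONTO.hasResponseType, "?rt"),
            ("?rt", ONTO.hasResponseTypeValue, "?responseType"),
            ("?prefs", ONTO.hasInteractionType, "?it"),
            ("?it", ONTO.hasInteractionMedium, "?medium"),
            ("?it", ONTO.hasInteractionFrequency, "?frequency"),
        ]),
        ("weather_context", [
            ("?context", ONTO.hasContextValue, "?value"),
            ("?value", ONTO.hasCity, "?city"),
            ("?value", ONTO.hasCountry, "?country"),
            ("?value", ONTO.hasWeatherCode, "?code"),
            ("?value", ONTO.hasTemperature, "?temperature"),
            ("?value", ONTO.hasHumidity, "?humidity"),
            ("?value", ONTO.hasWindSpeed, "?wind"),
        ]),
    ])
    def test_query_engine_agrees_with_naive_matcher(self, name, patterns,
                                                    canonical_sessions):
        """SPARQL results equal brute-force BGP matching on every canonical
        fixture graph (soundness and completeness on small graphs)."""
        for session in canonical_sessions:
            kg = session_graph(session)
            rows = run_query(kg, shipped_query(name))
            # project the oracle bindings onto the query's selected variables
            selected = {f"?{v}" for v in rows[0]} if rows else None
            oracle = bgp_match(kg.triples(), patterns)
            if selected is not None:
                oracle = {
                    frozenset((k, v) for k, v in sol if k in selected)
                    for sol in oracle
                }
            got = {frozenset((f"?{k}", v) for k, v in row.items()) for row in rows}
            if rows:
                assert got == oracle
            else:
                assert not oracle


class TestValidation:
    def test_canonical_fixtures_are_clean(self, canonical_sessions):
        for session in canonical_sessions:
            assert validate_graph(session_graph(session)) == []

    def test_disjoint_double_typing_detected(self, case1_graph):
        node = DATA["P001/Oops/0"]
        case1_graph.graph.add((node, RDF.type, ONTO.ToDo))
        case1_graph.graph.add((node, RDF.type, ONTO.Informal))
        kinds = [v.kind for v in validate_graph(case1_graph)]
        assert kinds.count("disjointness") == 1

    def test_missing_timestamp_is_cardinality_violation(self, case1_graph):
        node = DATA["P001/ActivityDataValue/extra"]
        case1_graph.graph.add((node, RDF.type, ONTO.ActivityDataValue))
        violations = validate_graph(case1_graph)
        assert [v.kind for v in violations] == ["cardinality"]
        assert "hasDateTime" in violations[0].detail

    def test_domain_violation_detected(self, case1_graph):
        # a weather value collecting activity data is out of domain
        weather = DATA["P001/ExternalWeatherValue/0"]
        target = DATA["P001/ActivityDataValue/2022-06-01"]
        case1_graph.graph.add((weather, ONTO.hasBeenCollectedBy, target))
        assert "domain" in {v.kind for v in validate_graph(case1_graph)}

    def test_range_violation_detected(self, case1_graph):
        person = DATA["P001/Participant/0"]
        wrong = DATA["P001/ActivityData/0"]  # not a Preferences individual
        case1_graph.graph.add((person, ONTO.hasPreferences, wrong))
        assert "range" in {v.kind for v in validate_graph(case1_graph)}

    def test_functional_property_uniqueness(self, schema):
        kg = build_graph(schema, Participant("P910"), [], [], Preferences())
        from rdflib import Literal

        person = DATA["P910/Participant/0"]
        kg.graph.add((person, ONTO.hasUniqueUserId, Literal("second-id")))
        assert "functional" in {v.kind for v in validate_graph(kg)}

    def test_inverse_functional_key_shared_by_two_subjects(self, schema):
        kg = build_graph(schema, Participant("P911"), [], [], Preferences())
        kg = build_graph(schema, Participant("P912"), [], [], Preferences(), kg=kg)
        from rdflib import Literal

        kg.graph.add((DATA["P912/Participant/0"], ONTO.hasUniqueUserId,
                      Literal("P911")))
        assert "functional" in {v.kind for v in validate_graph(kg)}


def test_goal_targets_written_when_goal_given(schema):
    kg = build_graph(schema, Participant("P920"), [], [], Preferences(),
                     goal=GoalSpec(step_target=12_000))
    goal_node = DATA["P920/Goal/0"]
    values = list(kg.graph.objects(goal_node, ONTO.hasStepTarget))
    assert [v.toPython() for v in values] == [12_000]
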