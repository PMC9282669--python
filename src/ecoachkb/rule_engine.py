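"""Rule-based recommendation generation.

The engine evaluates a day's activity observation against the participant's
goal, encodes the result as one of eight verification cases (goal type ×
step-goal bit × sleep-goal bit), classifies the weather context, and
forward-chains a 12-rule base to a fixpoint to emit recommendation message
codes.  The default rule base splits 10 / 1 / 1 across activity-level
classification, weather classification, and satisfiability:

* R1–R8 assign the overall daily-status truth values, one rule per
  (goal type, step, sleep) combination;
* R9/R10 select ToDo and Informal messages through guarded slot decision
  tables (each slot contributes exactly one code);
* R11 is the satisfiability rule: at most one *once a day* message
  (A-13 / A-14) may appear in any emission set;
* R12 emits the contextual weather message C-1 when outdoor activity is
  advisable.

Rules are A → B implications evaluated as ``NOT A OR B`` over three-valued
propositions (true / false / unknown); a rule fires only when its antecedent
is definitely true, and assignments are monotone — they never retract.
"""

from __future__ import annotations

import ast
import json
import tomllib
from dataclasses import dataclass, field
from datetime import date as _date
from enum import Enum
from importlib.resources import files
from pathlib import Path
from typing import Mapping, Sequence

from .message_kb import ONCE_A_DAY_GROUP, lookup
from .records import ActivityObservation, GoalSpec, WeatherObservation

__all__ = [
    "PROPOSITIONS",
    "Rule",
    "RuleBase",
    "RuleBaseError",
    "RuleConflictError",
    "DailyStatus",
    "Overall",
    "WeatherClass",
    "WeatherThresholds",
    "EvaluationResult",
    "RecommendationSet",
    "default_rulebase",
    "load_rulebase",
    "classify_daily_status",
    "encode_case",
    "decode_case",
    "classify_weather",
    "facts_for_case",
    "evaluate",
    "check_exclusivity",
    "select_messages",
    "evaluate_week",
    "recommend_day",
]

#: Closed set of proposition names the default rule base speaks about.
PROPOSITIONS = frozenset(
    {
        "goal_generic",
        "goal_personalized",
        "step_goal_met",
        "sleep_goal_met",
        "sedentary_ok",
        "pa_total_ok",
        "daily_goal_full",
        "daily_goal_partial",
        "daily_goal_none",
        "weather_outdoor_ok",
        "weekly_goal_met",
    }
)


class RuleBaseError(ValueError):
    """Malformed rule base (bad expression, unknown action, bad category mix)."""


class RuleConflictError(RuleBaseError):
    """Two rules assigned opposite truth values to one proposition."""


# ---------------------------------------------------------------------------
# three-valued boolean expressions
# ---------------------------------------------------------------------------

def _parse_expression(text: str) -> ast.expr:
    """Parse a NOT/AND/OR expression over proposition names.

    Uses Python expression syntax restricted to boolean operators,
    parentheses, and identifiers; ``true`` and ``false`` are constants.
    """
    try:
        tree = ast.parse(text, mode="eval").body
    except SyntaxError as exc:
        raise RuleBaseError(f"invalid rule expression {text!r}: {exc}") from exc
    for node in ast.walk(tree):
        if isinstance(node, (ast.BoolOp, ast.And, ast.Or, ast.Load)):
            continue
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
            continue
        if isinstance(node, ast.Not) or isinstance(node, ast.Name):
            continue
        raise RuleBaseError(
            f"invalid rule expression {text!r}: only NOT/AND/OR over "
            f"proposition names are allowed"
        )
    return tree


def _eval(node: ast.expr, facts: Mapping[str, bool | None]) -> bool | None:
    """Kleene three-valued evaluation; unknown propositions evaluate to None."""
    if isinstance(node, ast.Name):
        if node.id == "true":
            return True
        if node.id == "false":
            return False
        return facts.get(node.id)
    if isinstance(node, ast.UnaryOp):
        inner = _eval(node.operand, facts)
        return None if inner is None else not inner
    if isinstance(node, ast.BoolOp):
        values = [_eval(v, facts) for v in node.values]
        if isinstance(node.op, ast.And):
            if any(v is False for v in values):
                return False
            if any(v is None for v in values):
                return None
            return True
        if any(v is True for v in values):
            return True
        if any(v is None for v in values):
            return None
        return False
    raise RuleBaseError(f"unsupported expression node {node!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# rule base
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    """One A → B rule: a boolean antecedent and a list of consequent actions.

    Actions are dicts with exactly one of: ``assign``+``value`` (set a
    proposition), ``emit`` (a message code), ``emit_table`` (a named slot
    decision table), ``assert_exclusive`` (an exclusivity group name).
    """

    id: str
    category: str  # activity | weather | satisfiability
    antecedent: str
    consequent: tuple[dict, ...]

    def __post_init__(self) -> None:
        if self.category not in ("activity", "weather", "satisfiability"):
            raise RuleBaseError(f"rule {self.id}: unknown category {self.category!r}")
        _parse_expression(self.antecedent)
        for action in self.consequent:
            keys = set(action) & {"assign", "emit", "emit_table", "assert_exclusive"}
            if len(keys) != 1:
                raise RuleBaseError(f"rule {self.id}: malformed action {action!r}")


@dataclass(frozen=True)
class RuleBase:
    rules: tuple[Rule, ...]
    decision_tables: Mapping[str, tuple] = field(default_factory=dict)
    exclusivity_groups: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def category_counts(self) -> dict[str, int]:
        counts = {"activity": 0, "weather": 0, "satisfiability": 0}
        for rule in self.rules:
            counts[rule.category] += 1
        return counts

    def __len__(self) -> int:
        return len(self.rules)


def _rulebase_from_dict(raw: dict) -> RuleBase:
    rules = tuple(
        Rule(
            id=r["id"],
            category=r["category"],
            antecedent=r["if"],
            consequent=tuple(r["then"]),
        )
        for r in raw.get("rules", [])
    )
    ids = [r.id for r in rules]
    if len(ids) != len(set(ids)):
        raise RuleBaseError("duplicate rule ids")
    tables = {
        name: tuple(
            {"slot": slot["slot"], "cases": tuple(
                {"when": c["when"], "emit": c["emit"]} for c in slot["cases"]
            )}
            for slot in slots
        )
        for name, slots in raw.get("decision_tables", {}).items()
    }
    for slots in tables.values():
        for slot in slots:
            for case in slot["cases"]:
                _parse_expression(case["when"])
    groups = {
        name: frozenset(codes)
        for name, codes in raw.get("exclusivity_groups", {}).items()
    }
    for rule in rules:
        for action in rule.consequent:
            if "emit_table" in action and action["emit_table"] not in tables:
                raise RuleBaseError(
                    f"rule {rule.id}: unknown decision table {action['emit_table']!r}")
            if "assert_exclusive" in action and action["assert_exclusive"] not in groups:
                raise RuleBaseError(
                    f"rule {rule.id}: unknown exclusivity group "
                    f"{action['assert_exclusive']!r}")
    return RuleBase(rules=rules, decision_tables=tables, exclusivity_groups=groups)


def load_rulebase(path: str | Path) -> RuleBase:
    """Load a rule base from a JSON file."""
    try:
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise RuleBaseError(f"malformed rule base JSON: {exc}") from exc
    return _rulebase_from_dict(raw)


_DEFAULT_RULEBASE: RuleBase | None = None


def default_rulebase() -> RuleBase:
    """The shipped 12-rule base (10 activity / 1 weather / 1 satisfiability)."""
    global _DEFAULT_RULEBASE
    if _DEFAULT_RULEBASE is None:
        raw = json.loads(
            (files("ecoachkb") / "rules" / "default.json").read_text(encoding="utf-8")
        )
        _DEFAULT_RULEBASE = _rulebase_from_dict(raw)
    return _DEFAULT_RULEBASE


# ---------------------------------------------------------------------------
# daily goal evaluation and case encoding
# ---------------------------------------------------------------------------

class Overall(str, Enum):
    ACHIEVED = "ACHIEVED"
    PARTIAL = "PARTIAL"
    NOT_ACHIEVED = "NOT_ACHIEVED"


@dataclass(frozen=True)
class DailyStatus:
    """Goal-achievement flags for one participant-day.

    The primary objective is the (step, sleep) pair: both met → ACHIEVED,
    neither met → NOT_ACHIEVED, otherwise PARTIAL.  The secondary objective
    (sedentary cap, total-PA target) is carried alongside but does not move
    the overall status.
    """

    step_achieved: bool
    sleep_achieved: bool
    sedentary_ok: bool
    pa_total_ok: bool

    @property
    def overall(self) -> Overall:
        if self.step_achieved and self.sleep_achieved:
            return Overall.ACHIEVED
        if not self.step_achieved and not self.sleep_achieved:
            return Overall.NOT_ACHIEVED
        return Overall.PARTIAL


def classify_daily_status(obs: ActivityObservation, goal: GoalSpec) -> DailyStatus:
    """Compare one day's observation with its goal; all comparisons inclusive."""
    return DailyStatus(
        step_achieved=obs.steps >= goal.step_target,
        sleep_achieved=obs.sleep_min >= goal.sleep_target_min,
        sedentary_ok=obs.sedentary_min <= goal.sedentary_cap_min,
        pa_total_ok=obs.pa_total_min >= goal.pa_total_target_min,
    )


#: (goal_type, step bit, sleep bit) → case id; the 11/10/01/00 encoding.
_CASE_TABLE = {
    ("generic", True, True): 1,
    ("generic", True, False): 2,
    ("generic", False, True): 3,
    ("generic", False, False): 4,
    ("personalized", True, True): 5,
    ("personalized", True, False): 6,
    ("personalized", False, True): 7,
    ("personalized", False, False): 8,
}
_CASE_INVERSE = {v: k for k, v in _CASE_TABLE.items()}


def encode_case(goal_type: str, step_achieved: bool, sleep_achieved: bool) -> int:
    """Map (goal type, step bit, sleep bit) to the verification case id 1–8."""
    key = (goal_type, bool(step_achieved), bool(sleep_achieved))
    if key not in _CASE_TABLE:
        raise ValueError(f"goal_type must be generic|personalized, got {goal_type!r}")
    return _CASE_TABLE[key]


def decode_case(case_id: int) -> tuple[str, bool, bool]:
    """Inverse of :func:`encode_case`."""
    if case_id not in _CASE_INVERSE:
        raise ValueError(f"case_id must be in 1..8, got {case_id!r}")
    return _CASE_INVERSE[case_id]


# ---------------------------------------------------------------------------
# weather classification
# ---------------------------------------------------------------------------

class WeatherClass(str, Enum):
    OUTDOOR_OK = "OUTDOOR_OK"
    INDOOR_ADVISED = "INDOOR_ADVISED"


@dataclass(frozen=True)
class WeatherThresholds:
    """Bounds for advising outdoor activity; both temperature bounds inclusive."""

    t_min_c: float = 0.0
    t_max_c: float = 30.0
    wind_max_ms: float = 10.0
    severe_codes: frozenset[int] = frozenset()

    @staticmethod
    def from_config() -> "WeatherThresholds":
        cfg = weather_config()["thresholds"]
        return WeatherThresholds(
            t_min_c=cfg["t_min_c"],
            t_max_c=cfg["t_max_c"],
            wind_max_ms=cfg["wind_max_ms"],
            severe_codes=frozenset(cfg["severe_codes"]),
        )


def weather_config() -> dict:
    """Parsed weather TOML: the constant fixture context and the thresholds."""
    return tomllib.loads(
        (files("ecoachkb") / "config" / "weather_default.toml").read_text(
            encoding="utf-8"
        )
    )


def classify_weather(
    w: WeatherObservation, cfg: WeatherThresholds | None = None
) -> WeatherClass:
    cfg = cfg or WeatherThresholds.from_config()
    ok = (
        cfg.t_min_c <= w.temperature_c <= cfg.t_max_c
        and w.wind_speed_ms <= cfg.wind_max_ms
        and w.weather_code not in cfg.severe_codes
    )
    return WeatherClass.OUTDOOR_OK if ok else WeatherClass.INDOOR_ADVISED


# ---------------------------------------------------------------------------
# forward chaining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationResult:
    facts: dict[str, bool]
    emissions: frozenset[str]
    consistent: bool
    fired_rules: tuple[str, ...]


def evaluate(
    rulebase: RuleBase, facts: Mapping[str, bool]
) -> EvaluationResult:
    """Forward-chain the rule base to a fixpoint.

    Monotone semantics: a rule fires when its antecedent is definitely true
    under the current assignment; its assignments and emissions accumulate
    and are never retracted.  Opposite assignments to one proposition raise
    :class:`RuleConflictError` naming both origins.  ``consistent`` is False
    iff an asserted exclusivity group (the satisfiability rule) ends up with
    more than one emitted member.
    """
    state: dict[str, bool] = dict(facts)
    origin: dict[str, str] = {name: "facts" for name in facts}
    emissions: set[str] = set()
    asserted_groups: list[str] = []
    fired: list[str] = []
    parsed = {rule.id: _parse_expression(rule.antecedent) for rule in rulebase.rules}

    # A fixpoint is reached in at most |rules| * (|propositions| + 1) sweeps;
    # each productive sweep fixes at least one new proposition or emission.
    max_sweeps = max(1, len(rulebase.rules)) * (len(PROPOSITIONS) + len(state) + 2)
    for _ in range(max_sweeps):
        changed = False
        for rule in rulebase.rules:
            if _eval(parsed[rule.id], state) is not True:
                continue
            for action in rule.consequent:
                if "assign" in action:
                    prop, value = action["assign"], bool(action["value"])
                    if prop in state and state[prop] != value:
                        raise RuleConflictError(
                            f"proposition {prop!r} assigned {state[prop]} by "
                            f"{origin[prop]} and {value} by {rule.id}"
                        )
                    if prop not in state:
                        state[prop] = value
                        origin[prop] = rule.id
                        changed = True
                elif "emit" in action:
                    if action["emit"] not in emissions:
                        emissions.add(action["emit"])
                        changed = True
                elif "emit_table" in action:
                    for slot in rulebase.decision_tables[action["emit_table"]]:
                        for case in slot["cases"]:
                            if _eval(_parse_expression(case["when"]), state) is True:
                                if case["emit"] not in emissions:
                                    emissions.add(case["emit"])
                                    changed = True
                                break
                elif "assert_exclusive" in action:
                    if action["assert_exclusive"] not in asserted_groups:
                        asserted_groups.append(action["assert_exclusive"])
                        changed = True
            if rule.id not in fired:
                fired.append(rule.id)
                changed = True
        if not changed:
            break

    consistent = all(
        check_exclusivity(emissions, rulebase.exclusivity_groups[name])
        for name in asserted_groups
    )
    return EvaluationResult(
        facts=state,
        emissions=frozenset(emissions),
        consistent=consistent,
        fired_rules=tuple(fired),
    )


def check_exclusivity(emissions: set[str], group: frozenset[str] | set[str]) -> bool:
    """True iff at most one member of the exclusivity group was emitted."""
    return len(set(emissions) & set(group)) <= 1


# ---------------------------------------------------------------------------
# message selection
# ---------------------------------------------------------------------------

def _code_key(code: str) -> tuple[str, int]:
    prefix, _, number = code.partition("-")
    return (prefix, int(number))


@dataclass(frozen=True)
class RecommendationSet:
    """Engine output for one participant-day, in canonical code order."""

    todo: tuple[str, ...]
    informal: tuple[str, ...]
    fired_rules: tuple[str, ...] = ()
    date: _date | None = None

    def __post_init__(self) -> None:
        for codes in (self.todo, self.informal):
            if len(codes) != len(set(codes)):
                raise ValueError("duplicate message codes in recommendation set")
        once = set(self.todo) | set(self.informal)
        if len(once & ONCE_A_DAY_GROUP) > 1:
            raise ValueError("more than one once-a-day message selected")


def facts_for_case(
    case_id: int,
    weather: WeatherClass = WeatherClass.OUTDOOR_OK,
    sedentary_ok: bool = True,
    pa_total_ok: bool = True,
) -> dict[str, bool]:
    """Initial proposition assignment for one verification case."""
    goal_type, step, sleep = decode_case(case_id)
    return {
        "goal_generic": goal_type == "generic",
        "goal_personalized": goal_type == "personalized",
        "step_goal_met": step,
        "sleep_goal_met": sleep,
        "sedentary_ok": sedentary_ok,
        "pa_total_ok": pa_total_ok,
        "weather_outdoor_ok": weather is WeatherClass.OUTDOOR_OK,
    }


def select_messages(
    case_id: int,
    weather: WeatherClass = WeatherClass.OUTDOOR_OK,
    rulebase: RuleBase | None = None,
    date: _date | None = None,
) -> RecommendationSet:
    """Run the rule base for one verification case and collect its messages.

    The ToDo / Informal partition follows the registry intents; codes are
    returned in canonical order.  The result is produced by forward
    chaining, not by a row lookup.
    """
    rulebase = rulebase if rulebase is not None else default_rulebase()
    result = evaluate(rulebase, facts_for_case(case_id, weather))
    if not result.consistent:
        raise RuleConflictError(
            f"case {case_id}: exclusivity violated in {sorted(result.emissions)}"
        )
    todo = tuple(sorted(
        (c for c in result.emissions if lookup(c).intent == "ToDo"), key=_code_key))
    informal = tuple(sorted(
        (c for c in result.emissions if lookup(c).intent == "Informal"), key=_code_key))
    return RecommendationSet(
        todo=todo, informal=informal, fired_rules=result.fired_rules, date=date
    )


def evaluate_week(
    daily: Sequence[DailyStatus], weekly_achieved_days: int = 5
) -> tuple[bool, str]:
    """Weekly determination over exactly seven daily statuses.

    The week's goal is met when at least ``weekly_achieved_days`` days were
    fully ACHIEVED (inclusive bound); A-15 signals a met week, A-16 a missed
    one.
    """
    if len(daily) != 7:
        raise ValueError(f"expected exactly 7 daily statuses, got {len(daily)}")
    achieved = sum(1 for d in daily if d.overall is Overall.ACHIEVED)
    met = achieved >= weekly_achieved_days
    return met, ("A-15" if met else "A-16")


def recommend_day(
    obs: ActivityObservation,
    goal: GoalSpec,
    goal_type: str,
    weather_obs: WeatherObservation,
    rulebase: RuleBase | None = None,
    thresholds: WeatherThresholds | None = None,
) -> tuple[DailyStatus, int, RecommendationSet]:
    """End-to-end per-day pipeline: classify → encode → rule evaluation."""
    status = classify_daily_status(obs, goal)
    case_id = encode_case(goal_type, status.step_achieved, status.sleep_achieved)
    weather = classify_weather(weather_obs, thresholds)
    recset = select_messages(case_id, weather, rulebase, date=obs.date)
    return status, case_id, recset
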