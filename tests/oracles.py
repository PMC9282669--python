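"""Independent oracles used by the test suite.

Both implementations are deliberately naive and share no code with the
package: a repeated-sweep rule evaluator built on Python ``eval``, and a
brute-force basic-graph-pattern matcher over raw triple sets.
"""

from __future__ import annotations

from itertools import product

from rdflib import Literal


# ---------------------------------------------------------------------------
# naive repeated-sweep rule evaluation
# ---------------------------------------------------------------------------

_NAME = __import__("re").compile(r"\b(?!and\b|or\b|not\b|true\b|false\b)[a-z_][a-z0-9_]*\b")


def _guard_true(expr: str, facts: dict) -> bool:
    """Definitely true: the guard holds under *every* completion of the
    propositions the current state leaves unassigned."""
    names = sorted(set(_NAME.findall(expr)))
    unknown = [n for n in names if n not in facts]
    base = {"true": True, "false": False, **{n: facts[n] for n in names if n in facts}}
    for bits in product([True, False], repeat=len(unknown)):
        env = dict(base)
        env.update(zip(unknown, bits))
        if not eval(expr, {"__builtins__": {}}, env):  # noqa: S307
            return False
    return True


def naive_evaluate(rulebase, facts: dict):
    """Repeated full sweeps until nothing changes; returns (facts, emissions,
    consistent)."""
    state = dict(facts)
    emissions: set[str] = set()
    groups: list[str] = []
    while True:
        before = (dict(state), set(emissions), list(groups))
        for rule in rulebase.rules:
            if not _guard_true(rule.antecedent, state):
                continue
            for action in rule.consequent:
                if "assign" in action:
                    state[action["assign"]] = bool(action["value"])
                elif "emit" in action:
                    emissions.add(action["emit"])
                elif "emit_table" in action:
                    for slot in rulebase.decision_tables[action["emit_table"]]:
                        for case in slot["cases"]:
                            if _guard_true(case["when"], state):
                                emissions.add(case["emit"])
                                break
                elif "assert_exclusive" in action:
                    if action["assert_exclusive"] not in groups:
                        groups.append(action["assert_exclusive"])
        if (state, emissions, groups) == (before[0], before[1], before[2]):
            break
    consistent = all(
        len(emissions & set(rulebase.exclusivity_groups[g])) <= 1 for g in groups
    )
    return state, emissions, consistent


def all_64_assignments():
    """Every admissible base-fact assignment: goal type x step x sleep x
    sedentary x PA x weather."""
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


# ---------------------------------------------------------------------------
# brute-force BGP matching
# ---------------------------------------------------------------------------

def _to_python(term):
    return term.toPython() if isinstance(term, Literal) else str(term)


def bgp_match(triples, patterns):
    """All solution mappings for a conjunctive triple pattern.

    ``patterns`` is a list of (s, p, o) where strings starting with '?' are
    variables and everything else must equal str(term) exactly.  Returns a
    set of frozensets of (var, value) pairs, values converted to plain
    Python as the package's query layer does.
    """
    solutions = [dict()]
    for s_pat, p_pat, o_pat in patterns:
        next_solutions = []
        for binding in solutions:
            for s, p, o in triples:
                trial = dict(binding)
                ok = True
                for pat, term in ((s_pat, s), (p_pat, p), (o_pat, o)):
                    if isinstance(pat, str) and pat.startswith("?"):
                        value = _to_python(term)
                        if pat in trial and trial[pat] != value:
                            ok = False
                            break
                        trial[pat] = value
                    elif str(term) != str(pat):
                        ok = False
                        break
                if ok:
                    next_solutions.append(trial)
        solutions = next_solutions
    return {frozenset(b.items()) for b in solutions}
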