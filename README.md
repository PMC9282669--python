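# ecoachkb

Knowledge-graph modeling and rule-based recommendation generation for
physical-activity e-coaching.

An activity e-coach observes a person's daily behavior through a wearable
sensor (steps, low/medium/vigorous physical-activity minutes, sedentary and
sleep minutes), knows the local weather context, and knows the person's
preferences (generic vs. personalized goals, direct vs. motivational style,
how and how often to be contacted). From these it must pick, every evening,
a small set of personalized motivational messages for the next day.
`ecoachkb` implements that pipeline as a semantic knowledge model plus a
forward-chaining rule engine, for researchers prototyping behavior-change
decision support.

## The model

**Knowledge graph.** The domain is an ontology Ω = (C, R): a tree of classes
rooted at `Thing` (participants, health records, observation values for
activity and weather, contextual data, preference qualifiers, recommendation
messages with intent and components) plus object/data properties with
domain, range, characteristics and minimum cardinalities, and disjointness
axioms such as `ToDo ⊓ Informal = ∅`. Participant data are minted as RDF
individuals with deterministic IRIs, serialized as Turtle, queried with
SPARQL 1.1 SELECT, and checked by a structural validator (disjointness,
cardinality, domain/range, functional keys).

**Daily evaluation.** A day is scored against the active goal
specification: `step_achieved ⇔ steps ≥ step_target`,
`sleep_achieved ⇔ sleep ≥ sleep_target` (primary objective), with the
sedentary cap and total-PA target as a secondary objective. The two primary
bits crossed with the goal type (generic / personalized) give eight
verification cases: case 1 = generic 11, … case 8 = personalized 00.

**Rule base.** Twelve A → B rules — each evaluated as `NOT A OR B` over
three-valued propositions — split 10 activity / 1 weather / 1
satisfiability. R1–R8 assign the overall daily-status truth values (one per
goal-type × step × sleep combination), R9/R10 select ToDo and Informal
message codes through guarded slot decision tables, R12 emits the
contextual message C-1 when the weather permits outdoor activity, and R11
guarantees that at most one *once a day* message (A-13/A-14) is ever
emitted. Forward chaining is monotone and reaches a fixpoint; the engine
reports provenance (which rules fired) and an inconsistency flag.

## Worked example

Generate the canonical case-1 fixture (generic goal, both daily goals met)
and produce its recommendations:

```bash
$ ecoachkb generate --case 1 --seed 7 --out-dir demo
wrote 2 files to demo
$ ecoachkb recommend --session demo/case1_session.json
{
  "2022-06-01": {
    "case": 1,
    "fired_rules": ["R1", "R9", "R10", "R11", "R12"],
    "informal": ["A-13", "C-1"],
    "overall": "ACHIEVED",
    "todo": ["A-3", "A-6", "A-8", "A-10", "A-12"]
  }
}
```

The simulated day (10,459 steps ≥ 10,000; 436 sleep minutes ≥ 420) achieves
both primary goals, so the engine classifies the day `ACHIEVED` (rule R1),
selects the five ToDo messages for a fully successful generic day —
keep-the-routine plan (A-3), congratulation (A-6), step goal met (A-8),
target on track (A-10), sleep goal met (A-12) — and the informal pair: the
once-a-day success summary A-13 and the weather message C-1 (the constant
context is clear-sky, so outdoor activity is advised). The same library
surface is available in Python:

```python
from ecoachkb import canonical_case, session_graph, recommend_session

session = canonical_case(1, seed=7)
kg = session_graph(session)              # RDF knowledge graph
results = recommend_session(session, kg=kg)
```

`ecoachkb validate graph.ttl` reports structural violations, and
`ecoachkb query --graph graph.ttl --name activity_by_day` runs the shipped
retrieval queries.

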