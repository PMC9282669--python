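# Methods

## Scope and shape

`ecoachkb` models activity e-coaching data — wearable activity observations,
contextual weather, personal preferences, recommendation messages — as an
RDF knowledge graph and generates personalized daily recommendations by
forward-chaining a small rule base. It is a modeling and verification tool:
all data are simulated by the fixtures module; no sensor or weather-API
adapters are included.

## Ontology

The class hierarchy is a tree rooted at `Thing` (every non-root class has
exactly one parent), so levels are well-defined: the root sits at level 0
and the level sets partition the classes. The canonical schema has depth 4
(e.g. `Thing > Qualifier > Preferences > Goal > Daily`). Disjointness is
declared between message intents (`ToDo` / `Informal`), goal scopes
(`Daily` / `Weekly`), and observation value kinds, and is inherited by
subclasses.

Property modeling choices:

* `hasUniqueUserId` is functional **and** inverse-functional — it is the
  participant key. `functional` and `transitive` are mutually exclusive on
  one property by contract.
* Credentials, role, status and gender are literal-valued data properties;
  expanding them into class hierarchies would add nodes without adding
  distinctions the rules ever consult.
* The only minimum-cardinality restriction is `hasDateTime ≥ 1` on
  observation values: an observation without a timestamp is meaningless in
  a coaching timeline, and the restriction gives the validator a real
  cardinality check to exercise.
* IRIs are minted under `https://example.org/ecoach/` (`onto#` for terms,
  `data#` for individuals); individuals use
  `data#{participant_id}/{Class}/{date-or-seq}` so identical inputs yield
  identical graphs.

In place of a description-logic reasoner, `validate_graph` performs
structural validation: disjoint double-typing, minimum cardinality,
domain/range of every used property, and functional / inverse-functional
uniqueness. This covers exactly the constraint kinds the schema can
express; it does not compute inferred class hierarchies or detect
unsatisfiable class expressions.

## Graph store

Graphs are held in `rdflib` and serialized as Turtle. Persistence writes
canonically sorted N-Triples (a Turtle subset) so that two persists of
equal graphs are byte-identical; the contract is round-trip fidelity on the
triple set, not compatibility with any particular triple-store binary
format. Literal datatypes: counts and minutes as `xsd:integer`,
temperatures and other continuous weather values as `xsd:decimal`,
timestamps as `xsd:dateTime` (ISO-8601). A participant-day carries at most
one activity observation, keyed by (participant, date).

Four retrieval queries ship with the package (`queries/*.rq`): activity by
day, preferences, weather context, recommendations delivered. They are
plain basic-graph-pattern SELECTs; the test suite checks them against an
independent brute-force pattern matcher, and retrieval precision is scored
binding-by-binding against the generator's ground truth.

## Daily evaluation and case encoding

All goal comparisons are inclusive (`≥` target, `≤` cap). The primary
objective is the (step, sleep) pair; overall status is `ACHIEVED` iff both
bits are set, `NOT_ACHIEVED` iff neither, else `PARTIAL`. The secondary
objective (sedentary cap, total LPA+MPA+VPA target) is evaluated and
carried on `DailyStatus`, and is available to custom rules, but does not
move the case id: the verification cases are defined on the two primary
bits crossed with the goal type, generic → cases 1–4 and personalized →
cases 5–8 in the order 11, 10, 01, 00.

Default generic targets follow the spirit of public activity guidelines
without claiming their exact numbers: 10,000 steps/day, 420 sleep minutes,
480-minute sedentary cap, 30 PA minutes/day. The personalized profile
(8,000 steps, 450 sleep minutes) is deliberately different so cases 5–8
exercise a distinct goal path. All targets are configurable per
`GoalSpec`.

## Rule base

Rules are A → B implications; the engine treats them as `NOT A OR B` over
three-valued propositions (true / false / unknown) and fires a rule only
when its antecedent is *definitely* true (Kleene evaluation). Assignments
are monotone — never retracted — so the fixpoint is reached in at most
|rules| · (|propositions| + 1) sweeps; opposite assignments to one
proposition raise an error naming both origin rules.

The default base has 12 rules, 10 activity / 1 weather / 1 satisfiability:

* **R1–R8** assign the overall daily-status truth value, one rule per
  (goal type, step, sleep) combination — mirroring the eight verification
  cases.
* **R9/R10** select the ToDo and Informal messages. Rather than a lookup of
  whole case rows, each consequent is a guarded *slot decision table*: five
  ToDo slots (plan A-1…A-4, coach A-5/A-6, steps A-7/A-8, target A-9/A-10,
  sleep A-11/A-12) and one Informal slot (A-13/A-14), each slot a list of
  expression-guarded cases of which the first definitely-true one emits.
  The published eight-case table is therefore *composed* from six
  independent slot decisions at run time.
* **R11** (satisfiability) asserts the once-a-day exclusivity group
  {A-13, A-14}: evaluation reports `consistent = false` iff more than one
  group member was emitted. Because the A-13/A-14 slot guards are mutually
  exclusive and exhaustive, the exhaustive 64-assignment enumeration shows
  the bound is never exceeded.
* **R12** (weather) emits C-1 when the context classifies as
  `OUTDOOR_OK`: temperature within [0, 30] °C inclusive, wind ≤ 10 m/s,
  and the weather code outside a severe-weather list (thunderstorm, heavy
  rain/snow, squalls, tornado, in the OpenWeather code scheme). The bounds
  are configuration, not claims about meteorology.

Rule bases load from JSON (`rules/default.json` ships as package data), so
deployments can edit guards, tables and groups without touching code.

Weekly evaluation counts fully `ACHIEVED` days over exactly seven statuses;
the week's goal is met at ≥ 5 achieved days (inclusive, configurable).
A-15 denotes a met week and A-16 a missed one — the direction of that
assignment is a labeled convention of this implementation.

## Message registry

Seventeen messages: A-1…A-16 and C-1. Codes, intents (twelve ToDo daily
messages, A-13/A-14/A-15/A-16/C-1 Informal) and the once-a-day exclusivity
group are the stable contract. The template texts are synthetic
placeholders in a positive-psychology style, shipped in `messages.json` for
localization; rendering is plain deterministic placeholder substitution
that raises on a missing binding.

## Synthetic data

The fixtures module is the data source for the whole package. The eight
canonical sessions each hold one simulated day whose values realize the
case's achievement pattern within ±20 % of the target (achieved: value in
[target, 1.2·target]; missed: value in [0.8·target, target)), secondary
objectives satisfied, under one constant clear-sky weather context (shipped
in `config/weather_default.toml`). The contract is the achievement
pattern, not specific counts. `random_session` draws per-day step/sleep
achievement as independent Bernoulli variables with configurable marginals
for stress-testing; at 10,000 days the observed rates recover the profile
within ±0.02. All generation is seeded (`numpy` Generator) and
reproducible bit-for-bit.

What the generator does **not** emulate: real wearable noise and missing
days, within-day time structure, correlated step/sleep behavior, weather
variation, and adaptive/personalized goal adjustment over time. Passing
tests therefore demonstrate the correctness of the modeling and rule
machinery on pattern-faithful inputs, not performance on field data.

## Verification quantities

`scripts/acceptance.py` recomputes, from scratch at run time:

* **retrieval precision** — all canonical fixtures are generated, their
  graphs built and their recommendations delivered; every shipped query is
  run and every returned binding is compared with the generator's stored
  record (spurious or wrong bindings count against precision);
* **maximum once-a-day emissions** — all 64 admissible assignments of the
  base propositions (goal type × step × sleep × sedentary × PA × weather)
  are pushed through the engine and the largest intersection with the
  once-a-day group is reported.

Problem sizes: 8 sessions × 4 queries (216 scored bindings) and 64
assignments; both complete in seconds on one CPU.

## Known limitations

* No OWL-DL reasoning (no inferred hierarchy, no tableau consistency);
  validation is structural only.
* SPARQL support is whatever `rdflib` provides, exposed for SELECT; no
  UPDATE/CONSTRUCT, no HTTP endpoint, no named graphs.
* Message *texts* are placeholders; only codes/intents are contractual.
* Single-participant sessions are the tested path; multi-participant
  graphs are supported but recommendations are generated per session.
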