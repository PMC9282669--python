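"""Ontology schema for the activity e-coaching knowledge model.

The domain is modeled as a tree-shaped class hierarchy Ω = (C, R) rooted at
``Thing``: participants and their health records, sensor observation values
(wearable activity data and external weather), contextual data, temporal
stamps, personal preferences (goals, interaction, response type), and
recommendation messages broken into intent (ToDo / Informal) and components
(Time, Element, Action, Subject).  Alongside the hierarchy the schema carries
object/data property definitions with domain, range, characteristics
(functional, transitive, ...) and minimum cardinalities, plus disjointness
axioms — everything the structural validator in :mod:`ecoachkb.graph` needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, XSD

__all__ = [
    "PropertyDef",
    "SchemaDef",
    "SchemaError",
    "ONTO",
    "DATA",
    "default_schema",
    "levels",
    "nodes_at_level",
    "schema_to_turtle",
]

#: Namespace for ontology terms (classes and properties).
ONTO = Namespace("https://example.org/ecoach/onto#")
#: Namespace for minted individuals.
DATA = Namespace("https://example.org/ecoach/data#")

ROOT = "Thing"

#: Literal datatypes a data-property range may name.
LITERAL_DATATYPES = frozenset(
    {"string", "integer", "decimal", "boolean", "dateTime", "date"}
)

CHARACTERISTICS = frozenset(
    {"functional", "inverse_functional", "transitive", "symmetric", "reflexive"}
)


class SchemaError(ValueError):
    """Structural defect in a schema definition (cycle, dangling name, ...)."""


@dataclass(frozen=True)
class PropertyDef:
    """One object or data property.

    ``range`` names a class for object properties and a literal datatype
    (``string``, ``integer``, ``decimal``, ``boolean``, ``dateTime``) for
    data properties.  ``min_cardinality`` > 0 demands that every individual
    of the domain class carries at least that many values.
    """

    name: str
    kind: str  # "object" | "data"
    domain: str
    range: str
    characteristics: frozenset[str] = frozenset()
    min_cardinality: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("object", "data"):
            raise SchemaError(f"property {self.name}: kind must be object|data")
        unknown = set(self.characteristics) - CHARACTERISTICS
        if unknown:
            raise SchemaError(f"property {self.name}: unknown characteristics {unknown}")
        if {"functional", "transitive"} <= set(self.characteristics):
            raise SchemaError(
                f"property {self.name}: functional and transitive are mutually exclusive"
            )
        if self.min_cardinality < 0:
            raise SchemaError(f"property {self.name}: negative min_cardinality")


@dataclass
class SchemaDef:
    """Class hierarchy + property table + disjointness axioms.

    The subclass relation is a tree rooted at ``Thing``: every class other
    than the root has exactly one parent.  ``validate`` enforces the
    structural invariants; all public constructors call it.
    """

    classes: set[str]
    subclass_of: dict[str, str]
    disjoint_sets: list[frozenset[str]] = field(default_factory=list)
    object_properties: list[PropertyDef] = field(default_factory=list)
    data_properties: list[PropertyDef] = field(default_factory=list)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if ROOT not in self.classes:
            raise SchemaError(f"root class {ROOT!r} missing")
        for cls, parent in self.subclass_of.items():
            if cls not in self.classes:
                raise SchemaError(f"subclass_of names undeclared class {cls!r}")
            if parent not in self.classes:
                raise SchemaError(f"parent {parent!r} of {cls!r} is undeclared")
        for cls in self.classes:
            if cls != ROOT and cls not in self.subclass_of:
                raise SchemaError(f"non-root class {cls!r} has no parent")
        if ROOT in self.subclass_of:
            raise SchemaError("root class must not have a parent")
        # acyclicity: walk every chain up to the root
        for cls in self.classes:
            self._depth(cls)
        for dset in self.disjoint_sets:
            missing = dset - self.classes
            if missing:
                raise SchemaError(f"disjoint set names undeclared classes {missing}")
        seen: set[str] = set()
        for prop in self.object_properties + self.data_properties:
            if prop.name in seen:
                raise SchemaError(f"duplicate property name {prop.name!r}")
            seen.add(prop.name)
            if prop.domain not in self.classes:
                raise SchemaError(f"property {prop.name}: undeclared domain {prop.domain!r}")
            if prop.kind == "object":
                if prop.range not in self.classes:
                    raise SchemaError(
                        f"property {prop.name}: undeclared range {prop.range!r}"
                    )
            elif prop.range not in LITERAL_DATATYPES:
                raise SchemaError(
                    f"property {prop.name}: unknown literal datatype {prop.range!r}"
                )

    def _depth(self, cls: str) -> int:
        depth = 0
        node = cls
        seen = {node}
        while node != ROOT:
            node = self.subclass_of[node]
            if node in seen:
                raise SchemaError(f"subclass cycle through {cls!r}")
            seen.add(node)
            depth += 1
            if depth > len(self.classes):
                raise SchemaError(f"subclass cycle through {cls!r}")
        return depth

    # -- introspection ------------------------------------------------------
    def property(self, name: str) -> PropertyDef | None:
        for prop in self.object_properties + self.data_properties:
            if prop.name == name:
                return prop
        return None

    def descendants(self, cls: str) -> set[str]:
        """``cls`` together with all classes below it in the tree."""
        out = {cls}
        changed = True
        while changed:
            changed = False
            for child, parent in self.subclass_of.items():
                if parent in out and child not in out:
                    out.add(child)
                    changed = True
        return out

    def are_disjoint(self, a: str, b: str) -> bool:
        """True iff some disjointness axiom separates ``a`` and ``b``.

        Disjointness is inherited: if ``Daily`` and ``Weekly`` are disjoint,
        so are their respective subclasses.
        """
        if a == b:
            return False
        for dset in self.disjoint_sets:
            for x in dset:
                for y in dset:
                    if x != y and a in self.descendants(x) and b in self.descendants(y):
                        return True
        return False


# ---------------------------------------------------------------------------
# canonical schema
# ---------------------------------------------------------------------------

_HIERARCHY: dict[str, str] = {
    "Human": ROOT,
    "Participant": "Human",
    "ParticipantHealthRecord": ROOT,
    "ActivityData": "ParticipantHealthRecord",
    "ObservableEntity": ROOT,
    "ObservationValue": "ObservableEntity",
    "ActivityDataValue": "ObservationValue",
    "ExternalWeatherValue": "ObservationValue",
    "ContextualData": ROOT,
    "ContextData": "ContextualData",
    "TemporalEntity": ROOT,
    "Qualifier": ROOT,
    "Preferences": "Qualifier",
    "Goal": "Preferences",
    "Daily": "Goal",
    "Weekly": "Goal",
    "Interaction": "Preferences",
    "ResponseType": "Preferences",
    "Recommendation": ROOT,
    "ActivityRecommendation": "Recommendation",
    "MessageIntent": ROOT,
    "ToDo": "MessageIntent",
    "Informal": "MessageIntent",
    "MessageComponent": ROOT,
    "Time": "MessageComponent",
    "Element": "MessageComponent",
    "Action": "MessageComponent",
    "Subject": "MessageComponent",
}

_OBJECT_PROPERTIES: list[tuple] = [
    # (name, domain, range, characteristics, min_card)
    ("hasHealthRecord", "Participant", "ParticipantHealthRecord", (), 0),
    ("hasPreferences", "Participant", "Preferences", ("functional",), 0),
    ("hasReceivedRecommendation", "Participant", "Recommendation", (), 0),
    ("hasBeenCollectedBy", "ActivityData", "ActivityDataValue", (), 0),
    ("hasContextValue", "ContextData", "ExternalWeatherValue", (), 0),
    ("hasMessageIntent", "ActivityRecommendation", "MessageIntent", (), 0),
    ("hasMessageComponent", "ActivityRecommendation", "MessageComponent", (), 0),
    ("hasRecoToDo", "MessageIntent", "ToDo", (), 0),
    ("hasRecoInformal", "MessageIntent", "Informal", (), 0),
    ("hasTime", "MessageComponent", "Time", (), 0),
    ("hasElement", "MessageComponent", "Element", (), 0),
    ("hasAction", "MessageComponent", "Action", (), 0),
    ("hasSubject", "MessageComponent", "Subject", (), 0),
    ("hasInteractionType", "Preferences", "Interaction", (), 0),
    ("hasResponseType", "Preferences", "ResponseType", (), 0),
    ("hasGoal", "Preferences", "Goal", (), 0),
]

_DATA_PROPERTIES: list[tuple] = [
    # participant credentials / profile; hasUniqueUserId is a key
    ("hasRole", "Participant", "string", (), 0),
    ("hasPassword", "Participant", "string", ("functional",), 0),
    ("hasUniqueUserId", "Participant", "string", ("functional", "inverse_functional"), 0),
    ("hasStatus", "Participant", "string", (), 0),
    ("hasAge", "Participant", "integer", ("functional",), 0),
    ("hasDesignation", "Participant", "string", (), 0),
    ("hasEmail", "Participant", "string", (), 0),
    ("hasFirstName", "Participant", "string", (), 0),
    ("hasLastName", "Participant", "string", (), 0),
    ("hasGender", "Participant", "string", (), 0),
    ("hasMobile", "Participant", "string", (), 0),
    # every observation value is time-stamped
    ("hasDateTime", "ObservationValue", "dateTime", (), 1),
    # wearable activity observation payload
    ("hasSteps", "ActivityDataValue", "integer", (), 0),
    ("hasLpaMinutes", "ActivityDataValue", "integer", (), 0),
    ("hasMpaMinutes", "ActivityDataValue", "integer", (), 0),
    ("hasVpaMinutes", "ActivityDataValue", "integer", (), 0),
    ("hasSedentaryMinutes", "ActivityDataValue", "integer", (), 0),
    ("hasSleepMinutes", "ActivityDataValue", "integer", (), 0),
    # external weather payload
    ("hasCity", "ExternalWeatherValue", "string", (), 0),
    ("hasCountry", "ExternalWeatherValue", "string", (), 0),
    ("hasWeatherCode", "ExternalWeatherValue", "integer", (), 0),
    ("hasWeatherStatus", "ExternalWeatherValue", "string", (), 0),
    ("hasWeatherDescription", "ExternalWeatherValue", "string", (), 0),
    ("hasTemperature", "ExternalWeatherValue", "decimal", (), 0),
    ("hasRealFeel", "ExternalWeatherValue", "decimal", (), 0),
    ("hasPressure", "ExternalWeatherValue", "decimal", (), 0),
    ("hasHumidity", "ExternalWeatherValue", "decimal", (), 0),
    ("hasVisibility", "ExternalWeatherValue", "decimal", (), 0),
    ("hasWindSpeed", "ExternalWeatherValue", "decimal", (), 0),
    # preference payload
    ("hasGoalType", "Goal", "string", (), 0),
    ("hasGoalStyle", "Goal", "string", (), 0),
    ("hasStepTarget", "Goal", "integer", (), 0),
    ("hasSleepTargetMinutes", "Goal", "integer", (), 0),
    ("hasSedentaryCapMinutes", "Goal", "integer", (), 0),
    ("hasPaTotalTargetMinutes", "Goal", "integer", (), 0),
    ("hasResponseTypeValue", "ResponseType", "string", (), 0),
    ("hasInteractionMode", "Interaction", "string", (), 0),
    ("hasInteractionMedium", "Interaction", "string", (), 0),
    ("hasInteractionFrequency", "Interaction", "string", (), 0),
    ("hasNotificationPersistent", "Interaction", "boolean", (), 0),
    # recommendation payload
    ("hasMessageCode", "ActivityRecommendation", "string", (), 0),
    ("hasRecommendationDateTime", "ActivityRecommendation", "dateTime", (), 0),
    ("hasFiredRule", "ActivityRecommendation", "string", (), 0),
]

_DISJOINT_SETS = [
    frozenset({"ToDo", "Informal"}),
    frozenset({"Daily", "Weekly"}),
    frozenset({"ActivityDataValue", "ExternalWeatherValue"}),
    frozenset({"Human", "Recommendation"}),
]


def default_schema() -> SchemaDef:
    """The canonical e-coaching schema.

    Covers participants (with credentials, profile and preferences), wearable
    activity observations (steps, LPA/MPA/VPA, sedentary and sleep minutes),
    contextual weather observations, temporal stamps, preference qualifiers
    (goal / interaction / response type) and recommendation messages with
    intent and components.  Deterministic: repeated calls build identical
    structures.
    """
    schema = SchemaDef(
        classes=set(_HIERARCHY) | {ROOT},
        subclass_of=dict(_HIERARCHY),
        disjoint_sets=list(_DISJOINT_SETS),
        object_properties=[
            PropertyDef(n, "object", d, r, frozenset(ch), mc)
            for n, d, r, ch, mc in _OBJECT_PROPERTIES
        ],
        data_properties=[
            PropertyDef(n, "data", d, r, frozenset(ch), mc)
            for n, d, r, ch, mc in _DATA_PROPERTIES
        ],
    )
    schema.validate()
    return schema


def levels(schema: SchemaDef) -> int:
    """Depth L of the deepest class; the root sits at level 0."""
    schema.validate()
    return max(schema._depth(cls) for cls in schema.classes)


def nodes_at_level(schema: SchemaDef, n: int) -> set[str]:
    """All classes at root distance exactly ``n``; levels partition the classes."""
    total = levels(schema)
    if not 0 <= n <= total:
        raise ValueError(f"level {n} out of range [0, {total}]")
    return {cls for cls in schema.classes if schema._depth(cls) == n}


# ---------------------------------------------------------------------------
# Turtle export (RDFS/OWL vocabulary)
# ---------------------------------------------------------------------------

_XSD_MAP = {
    "string": XSD.string,
    "integer": XSD.integer,
    "decimal": XSD.decimal,
    "boolean": XSD.boolean,
    "dateTime": XSD.dateTime,
    "date": XSD.date,
}

_CHAR_CLASS = {
    "functional": OWL.FunctionalProperty,
    "inverse_functional": OWL.InverseFunctionalProperty,
    "transitive": OWL.TransitiveProperty,
    "symmetric": OWL.SymmetricProperty,
    "reflexive": OWL.ReflexiveProperty,
}


def schema_to_turtle(schema: SchemaDef) -> str:
    """Serialize the schema as Turtle using rdfs:subClassOf / owl:disjointWith
    / owl:ObjectProperty / owl:DatatypeProperty with rdfs:domain and range."""
    schema.validate()
    g = Graph()
    g.bind("onto", ONTO)
    g.bind("owl", OWL)
    for cls in sorted(schema.classes):
        node = OWL.Thing if cls == ROOT else ONTO[cls]
        g.add((node, RDF.type, OWL.Class))
        parent = schema.subclass_of.get(cls)
        if parent is not None:
            pnode = OWL.Thing if parent == ROOT else ONTO[parent]
            g.add((node, RDFS.subClassOf, pnode))
    for dset in schema.disjoint_sets:
        members = sorted(dset)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                g.add((ONTO[a], OWL.disjointWith, ONTO[b]))
    for prop in schema.object_properties:
        node = ONTO[prop.name]
        g.add((node, RDF.type, OWL.ObjectProperty))
        g.add((node, RDFS.domain, ONTO[prop.domain]))
        g.add((node, RDFS.range, ONTO[prop.range]))
        for ch in sorted(prop.characteristics):
            g.add((node, RDF.type, _CHAR_CLASS[ch]))
        if prop.min_cardinality:
            g.add((node, ONTO.minCardinality, Literal(prop.min_cardinality)))
    for prop in schema.data_properties:
        node = ONTO[prop.name]
        g.add((node, RDF.type, OWL.DatatypeProperty))
        g.add((node, RDFS.domain, ONTO[prop.domain]))
        g.add((node, RDFS.range, _XSD_MAP[prop.range]))
        for ch in sorted(prop.characteristics):
            g.add((node, RDF.type, _CHAR_CLASS[ch]))
        if prop.min_cardinality:
            g.add((node, ONTO.minCardinality, Literal(prop.min_cardinality)))
    return g.serialize(format="turtle")
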