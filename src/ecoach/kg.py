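"""RDF knowledge-graph export and SPARQL querying.

Participants, their daily activity observations, preferences and weekly
recommendations are projected into an RDF graph following the activity
eCoaching ontology structure: each participant links to a personal
activity-data container (``hasPersonalData``), whose values
(``hasbeenCollectedBy``) are daily observations time-stamped via
``hasTimeStamp``; preferences attach via ``hasPreferences`` and weekly
recommendation messages via ``hasReceivedRecommendation``.

The graph is a faithful data projection: rule logic runs natively in the
recommendation engine, and no OWL reasoning is performed here.
Cardinalities (Some/Only) are recorded as schema metadata and checked only
as minimum counts where decidable at the data level.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

from rdflib import Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import XSD

from .core_data import ActivityDataset
from .labeling import label_day, daily_score
from .recommend import Preferences, WeeklyReport

__all__ = [
    "GraphSchema",
    "DEFAULT_BASE_IRI",
    "default_schema",
    "build_graph",
    "validate_graph",
    "to_turtle",
    "parse_turtle",
    "query",
]

DEFAULT_BASE_IRI = "https://ecoach.example.org/ontology#"


@dataclasses.dataclass(frozen=True)
class GraphSchema:
    """Classes, object properties (with domain/range/cardinality) and data
    properties the exporter is allowed to emit."""

    base_iri: str
    classes: frozenset[str]
    #: name -> (domains, range, cardinality)
    object_properties: Mapping[str, tuple[tuple[str, ...], str, str]]
    data_properties: frozenset[str]

    @property
    def ns(self) -> Namespace:
        return Namespace(self.base_iri)


def default_schema(base_iri: str = DEFAULT_BASE_IRI) -> GraphSchema:
    classes = frozenset({
        "Participant", "HealthRecord", "PersonalData", "Preferences",
        "Recommendation", "ParticipantStatus", "ActivityData",
        "ActivityDataValue", "ActivityDevice", "Observation", "SensorOutput",
        "TemporalEntity", "MeasurementCapability", "Property", "Stimulus",
        "FeatureOfInterest", "Sensor", "Questionnaire",
    })
    object_properties = {
        "hasHealthRecord": (("Participant",), "HealthRecord", "Some"),
        "hasPersonalData": (("Participant",), "PersonalData", "Some"),
        "hasPreferences": (("Participant",), "Preferences", "Some"),
        "hasReceivedRecommendation": (("Participant",), "Recommendation", "Some"),
        "hasStatus": (("Participant",), "ParticipantStatus", "Some"),
        "hasbeenCollectedBy": (("ActivityData",), "ActivityDataValue", "Some"),
        "hasTimeStamp": (("ActivityDataValue", "Questionnaire", "Recommendation"),
                         "TemporalEntity", "Some"),
        "hasMeasurementCapability": (("ActivityDevice",),
                                     "MeasurementCapability", "Only"),
        "hasOutput": (("ActivityDevice",), "SensorOutput", "Some"),
        "observes": (("ActivityDevice",), "Property", "Only"),
        "detects": (("ActivityDevice",), "Stimulus", "Only"),
        "featureOfInterest": (("Observation",), "FeatureOfInterest", "Only"),
        "observationResult": (("Observation",), "SensorOutput", "Only"),
        "observedBy": (("Observation",), "Sensor", "Only"),
        "isPropertyOf": (("Property",), "FeatureOfInterest", "Some"),
        "hasProperty": (("FeatureOfInterest",), "Property", "Some"),
    }
    data_properties = frozenset({
        "steps", "lpaMinutes", "mpaMinutes", "vpaMinutes", "sedentaryMinutes",
        "activityLevel", "dailyScore", "dateValue", "achievedScore",
        "targetScore", "differenceScore", "formalMessage", "informalMessage",
        "emojiCategory", "goalSetting", "deliveryMode", "deliveryTime",
        "isActive",
    })
    return GraphSchema(base_iri, classes, object_properties, data_properties)


def _participant_iri(ns: Namespace, pid: str) -> URIRef:
    return ns[f"participant/{pid}"]


def build_graph(
    dataset: ActivityDataset | None = None,
    reports: Sequence[WeeklyReport] = (),
    prefs: Mapping[str, Preferences] | None = None,
    schema: GraphSchema | None = None,
) -> Graph:
    """Project datasets, weekly reports and preferences into an RDF graph.

    One Participant node per id; each daily summary becomes an
    ActivityDataValue with its measured quantities, derived activity level
    and score, linked to a TemporalEntity carrying the date; each weekly
    report becomes a Recommendation node holding the message texts and the
    achieved/target/difference scores.
    """
    schema = schema or default_schema()
    ns = schema.ns
    g = Graph()
    g.bind("ecoach", ns)

    seen: set[str] = set()

    def participant(pid: str) -> URIRef:
        node = _participant_iri(ns, pid)
        if pid not in seen:
            g.add((node, RDF.type, ns.Participant))
            status = ns[f"status/{pid}"]
            g.add((node, ns.hasStatus, status))
            g.add((status, RDF.type, ns.ParticipantStatus))
            g.add((status, ns.isActive, Literal(True)))
            seen.add(pid)
        return node

    if dataset is not None and len(dataset):
        for summary in dataset.to_summaries():
            pid = summary.participant_id
            p = participant(pid)
            container = ns[f"activitydata/{pid}"]
            if (container, RDF.type, ns.ActivityData) not in g:
                # typed as both so Participant->container and
                # container->values respect the printed domains/ranges
                g.add((container, RDF.type, ns.PersonalData))
                g.add((container, RDF.type, ns.ActivityData))
                g.add((p, ns.hasPersonalData, container))
            obs = ns[f"observation/{pid}/{summary.date.isoformat()}"]
            g.add((obs, RDF.type, ns.ActivityDataValue))
            g.add((container, ns.hasbeenCollectedBy, obs))
            ts = ns[f"time/{pid}/{summary.date.isoformat()}"]
            g.add((ts, RDF.type, ns.TemporalEntity))
            g.add((ts, ns.dateValue, Literal(summary.date, datatype=XSD.date)))
            g.add((obs, ns.hasTimeStamp, ts))
            g.add((obs, ns.steps, Literal(summary.steps)))
            g.add((obs, ns.lpaMinutes, Literal(summary.lpa_min)))
            g.add((obs, ns.mpaMinutes, Literal(summary.mpa_min)))
            g.add((obs, ns.vpaMinutes, Literal(summary.vpa_min)))
            g.add((obs, ns.sedentaryMinutes, Literal(summary.sedentary_min)))
            level = label_day(summary)
            g.add((obs, ns.activityLevel, Literal(level.label)))
            g.add((obs, ns.dailyScore, Literal(daily_score(level))))

    for pid, pref in (prefs or {}).items():
        p = participant(pid)
        node = ns[f"preferences/{pid}"]
        g.add((p, ns.hasPreferences, node))
        g.add((node, RDF.type, ns.Preferences))
        g.add((node, ns.goalSetting, Literal(pref.goal_setting)))
        g.add((node, ns.targetScore, Literal(pref.target_score)))
        g.add((node, ns.deliveryMode, Literal(pref.mode)))
        g.add((node, ns.deliveryTime,
               Literal(pref.delivery_time.isoformat(timespec="minutes"))))

    for i, report in enumerate(reports):
        p = participant(report.participant_id)
        node = ns[f"recommendation/{report.participant_id}/{i}"]
        g.add((p, ns.hasReceivedRecommendation, node))
        g.add((node, RDF.type, ns.Recommendation))
        g.add((node, ns.achievedScore, Literal(report.achieved)))
        g.add((node, ns.targetScore, Literal(report.target)))
        g.add((node, ns.differenceScore, Literal(report.difference)))
        g.add((node, ns.formalMessage, Literal(report.formal_message)))
        g.add((node, ns.informalMessage, Literal(report.informal_message)))
        g.add((node, ns.emojiCategory, Literal(report.emoji_category)))

    validate_graph(g, schema)
    return g


def validate_graph(g: Graph, schema: GraphSchema | None = None) -> None:
    """Check every emitted triple against the schema.

    Predicates in the ontology namespace must be declared object or data
    properties (``rdf:type`` objects must be declared classes); object
    properties must connect nodes whose types are compatible with the
    declared domain and range. Raises ValueError naming the offending
    triple.
    """
    schema = schema or default_schema()
    ns = schema.ns
    base = str(ns)

    def types_of(node) -> set[str]:
        return {str(o)[len(base):] for o in g.objects(node, RDF.type)
                if str(o).startswith(base)}

    for s, p, o in g:
        if p == RDF.type:
            name = str(o)[len(base):] if str(o).startswith(base) else str(o)
            if name not in schema.classes:
                raise ValueError(f"undeclared class in triple ({s}, rdf:type, {o})")
            continue
        if not str(p).startswith(base):
            continue
        name = str(p)[len(base):]
        if name in schema.data_properties:
            continue
        if name not in schema.object_properties:
            raise ValueError(f"undeclared predicate in triple ({s}, {p}, {o})")
        domains, rng, _card = schema.object_properties[name]
        if not types_of(s) & set(domains):
            raise ValueError(
                f"domain violation: subject of ({s}, {name}, {o}) is not "
                f"typed as any of {domains}"
            )
        if rng not in types_of(o):
            raise ValueError(
                f"range violation: object of ({s}, {name}, {o}) is not "
                f"typed as {rng}"
            )


def to_turtle(graph: Graph) -> str:
    """Serialize to Turtle; parse ∘ serialize preserves the triple set."""
    return graph.serialize(format="turtle")


def parse_turtle(text: str) -> Graph:
    g = Graph()
    g.parse(data=text, format="turtle")
    return g


def query(graph: Graph, sparql: str) -> list[dict]:
    """Run a SPARQL SELECT/ASK query; SELECT rows come back as dicts.

    ASK queries return ``[{"ask": bool}]``.
    """
    result = graph.query(sparql)
    if result.type == "ASK":
        return [{"ask": bool(result.askAnswer)}]
    rows = []
    for binding in result:
        rows.append({str(var): binding[i].toPython() if binding[i] is not None else None
                     for i, var in enumerate(result.vars)})
    return rows
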