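"""Semantic-network substrate: object kinds, dynamic types, instances,
relation classes, annotations and contexts.

The knowledge base is a typed property graph.  Nodes (instances) belong to
dynamically defined object types, each derived from one of five static
object kinds (element, context, experiment, ontology, annotation).  Edges
(relation instances) belong to relation classes that carry a forward and a
backward traversal label, e.g. a patient *is assessed by* an fMRI and the
fMRI *assesses* the patient.  A relation may itself act as the source of
further structure (most importantly as the subject of an experiment entry,
see :mod:`semconnectome.experiments`), which is what lets a measured brain
connection carry per-modality measurements.

Everything lives in memory; the whole knowledge base serializes to a single
JSON document with stable ordering so that exports are diff-able.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

logger = logging.getLogger("semconnectome")

__all__ = [
    "ObjectKind",
    "AttributeKind",
    "AttributeDef",
    "AnnotationSchema",
    "AnnotationValue",
    "ObjectTypeDef",
    "Instance",
    "RelationClassDef",
    "RelationInstance",
    "KnowledgeBase",
    "KBError",
    "DefinitionError",
    "ValidationError",
    "RelationError",
    "QueryError",
    "DataError",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class KBError(Exception):
    """Base class for all knowledge-base errors."""


class DefinitionError(KBError):
    """Invalid or duplicate schema-level definition (type, class, schema)."""


class ValidationError(KBError):
    """A value violates its declared kind or range."""


class RelationError(KBError):
    """Relation endpoints do not satisfy the relation class definition."""


class QueryError(KBError):
    """A query references names that do not resolve."""


class DataError(KBError):
    """Malformed input data (tables, matrices, fixtures)."""


# ---------------------------------------------------------------------------
# Static object kinds and annotation machinery
# ---------------------------------------------------------------------------

class ObjectKind(Enum):
    """The five static kinds every dynamic object type derives from."""

    ELEMENT = "element"
    CONTEXT = "context"
    EXPERIMENT = "experiment"
    ONTOLOGY = "ontology"
    ANNOTATION = "annotation"


class AttributeKind(Enum):
    TEXT = "text"
    INTEGER = "integer"
    REAL = "real"
    FLAG = "flag"
    ENUMERATION = "enumeration"


@dataclass(frozen=True)
class AttributeDef:
    """One attribute of an annotation schema or experiment format.

    ``range`` is an inclusive (lo, hi) bound for numeric kinds; either side
    may be ``None`` for an open bound.  ``choices`` lists the admissible
    values of an enumeration.
    """

    name: str
    kind: AttributeKind = AttributeKind.REAL
    range: Optional[tuple[Optional[float], Optional[float]]] = None
    choices: Optional[tuple[str, ...]] = None

    def validate(self, value: Any) -> Any:
        if self.kind is AttributeKind.TEXT:
            if not isinstance(value, str):
                raise ValidationError(f"attribute {self.name!r}: expected text, got {value!r}")
            return value
        if self.kind is AttributeKind.FLAG:
            if isinstance(value, bool):
                return int(value)
            if value in (0, 1):
                return int(value)
            raise ValidationError(f"attribute {self.name!r}: expected flag 0/1, got {value!r}")
        if self.kind is AttributeKind.ENUMERATION:
            if self.choices is None or value not in self.choices:
                raise ValidationError(
                    f"attribute {self.name!r}: {value!r} not in {self.choices}")
            return value
        # numeric kinds
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ValidationError(f"attribute {self.name!r}: expected number, got {value!r}")
        if self.kind is AttributeKind.INTEGER and int(value) != value:
            raise ValidationError(f"attribute {self.name!r}: expected integer, got {value!r}")
        if self.range is not None:
            lo, hi = self.range
            if lo is not None and value < lo:
                raise ValidationError(
                    f"attribute {self.name!r}: {value!r} below lower bound {lo}")
            if hi is not None and value > hi:
                raise ValidationError(
                    f"attribute {self.name!r}: {value!r} above upper bound {hi}")
        return int(value) if self.kind is AttributeKind.INTEGER else float(value)


@dataclass
class AnnotationSchema:
    """Named bundle of typed attributes attachable to types or relation classes."""

    name: str
    attributes: tuple[AttributeDef, ...] = ()

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(names) != len(set(names)):
            raise DefinitionError(f"schema {self.name!r}: duplicate attribute names")
        self._by_name = {a.name: a for a in self.attributes}

    def validate_values(self, values: Mapping[str, Any]) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for key, val in values.items():
            if key not in self._by_name:
                raise ValidationError(f"schema {self.name!r} has no attribute {key!r}")
            out[key] = self._by_name[key].validate(val)
        return out


@dataclass
class AnnotationValue:
    schema: str
    values: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Types, instances, relations
# ---------------------------------------------------------------------------

@dataclass
class ObjectTypeDef:
    name: str
    kind: ObjectKind
    annotation_schemas: list[str] = field(default_factory=list)


@dataclass
class Instance:
    """An instance of a dynamic object type.

    ``labels`` are free-text display names matched case-insensitively by
    queries; ``props`` holds small typed payloads such as MNI coordinates.
    """

    type_name: str
    identifier: str
    labels: list[str] = field(default_factory=list)
    props: dict[str, Any] = field(default_factory=dict)
    annotations: list[AnnotationValue] = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return ("I", self.type_name, self.identifier)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Instance({self.type_name}:{self.identifier})"


@dataclass
class RelationClassDef:
    """A class of directed semantic relations.

    ``allowed_pairs`` lists (source name, target type name) pairs; a source
    name may be another relation class, which allows experiments to hang
    measurements off connections.  Forward and backward labels must differ
    so that traversal direction is always unambiguous.
    """

    name: str
    forward_label: str
    backward_label: str
    allowed_pairs: list[tuple[str, str]] = field(default_factory=list)
    annotation_schemas: list[str] = field(default_factory=list)


@dataclass
class RelationInstance:
    class_name: str
    source: Union[Instance, "RelationInstance"]
    target: Instance
    annotations: list[AnnotationValue] = field(default_factory=list)

    @property
    def source_name(self) -> str:
        """Type name (instances) or class name (relations) of the source."""
        if isinstance(self.source, RelationInstance):
            return self.source.class_name
        return self.source.type_name

    @property
    def key(self) -> tuple:
        return ("R", self.class_name, self.source.key, self.target.key)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Relation({self.class_name}: {self.source!r} -> {self.target!r})"


SemanticObject = Union[Instance, RelationInstance]


# ---------------------------------------------------------------------------
# The knowledge base
# ---------------------------------------------------------------------------

class KnowledgeBase:
    """In-memory registry of types, instances, relations and experiments.

    The experiment store (methods, experiments, data entries) and the
    ontology graphs physically live here so that one JSON document captures
    the whole knowledge base, but their operation layer is in
    :mod:`semconnectome.experiments` and
    :mod:`semconnectome.atlas_ontology`.
    """

    def __init__(self) -> None:
        self.types: dict[str, ObjectTypeDef] = {}
        self.schemas: dict[str, AnnotationSchema] = {}
        self.relation_classes: dict[str, RelationClassDef] = {}
        self.instances: dict[tuple, Instance] = {}
        self.relations: dict[tuple, RelationInstance] = {}
        self._by_source: dict[tuple, list[tuple]] = {}
        self._by_target: dict[tuple, list[tuple]] = {}
        self._instances_by_type: dict[str, list[tuple]] = {}
        self.context_members: dict[tuple, list[tuple]] = {}
        # experiment store (see semconnectome.experiments)
        self.methods: dict[str, Any] = {}
        self.experiments: dict[tuple[str, str], Any] = {}
        self.entries: dict[tuple, Any] = {}
        # ontology graphs: name -> networkx.DiGraph with child->parent edges
        self.ontologies: dict[str, Any] = {}
        # differential-expression links: sorted (a, b) -> count
        self.deg_links: dict[tuple[str, str], int] = {}

    # -- definitions -------------------------------------------------------

    def define_object_type(self, name: str, kind: ObjectKind) -> ObjectTypeDef:
        if name in self.types:
            raise DefinitionError(f"object type {name!r} already defined")
        if not isinstance(kind, ObjectKind):
            kind = ObjectKind(kind)
        tdef = ObjectTypeDef(name=name, kind=kind)
        self.types[name] = tdef
        return tdef

    def ensure_object_type(self, name: str, kind: ObjectKind) -> ObjectTypeDef:
        """Define the type if absent; error if present with another kind."""
        if name in self.types:
            existing = self.types[name]
            if existing.kind is not kind:
                raise DefinitionError(
                    f"type {name!r} exists with kind {existing.kind.value}, "
                    f"not {kind.value}")
            return existing
        return self.define_object_type(name, kind)

    def define_annotation_schema(
        self, name: str, attributes: Sequence[AttributeDef]
    ) -> AnnotationSchema:
        if name in self.schemas:
            raise DefinitionError(f"annotation schema {name!r} already defined")
        schema = AnnotationSchema(name=name, attributes=tuple(attributes))
        self.schemas[name] = schema
        return schema

    def attach_annotation_schema(self, target_name: str, schema_name: str) -> None:
        """Attach a schema to an object type or a relation class by name."""
        if schema_name not in self.schemas:
            raise DefinitionError(f"unknown annotation schema {schema_name!r}")
        if target_name in self.types:
            holder = self.types[target_name].annotation_schemas
        elif target_name in self.relation_classes:
            holder = self.relation_classes[target_name].annotation_schemas
        else:
            raise DefinitionError(f"unknown type or relation class {target_name!r}")
        if schema_name not in holder:
            holder.append(schema_name)

    def define_relation_class(
        self,
        name: str,
        forward_label: str,
        backward_label: str,
        allowed_pairs: Sequence[tuple[str, str]],
    ) -> RelationClassDef:
        if name in self.relation_classes:
            raise DefinitionError(f"relation class {name!r} already defined")
        if forward_label == backward_label:
            raise DefinitionError(
                f"relation class {name!r}: forward and backward labels must differ")
        pairs = [tuple(p) for p in allowed_pairs]
        if not pairs:
            raise DefinitionError(f"relation class {name!r}: allowed_pairs is empty")
        for src, tgt in pairs:
            if src not in self.types and src not in self.relation_classes:
                raise DefinitionError(
                    f"relation class {name!r}: unknown source {src!r}")
            if tgt not in self.types:
                raise DefinitionError(
                    f"relation class {name!r}: unknown target type {tgt!r}")
        cdef = RelationClassDef(name, forward_label, backward_label, pairs)
        self.relation_classes[name] = cdef
        return cdef

    def extend_relation_class(self, name: str, pair: tuple[str, str]) -> None:
        """Add an allowed (source, target) pair to an existing class."""
        cdef = self.relation_classes[name]
        pair = tuple(pair)
        if pair not in cdef.allowed_pairs:
            src, tgt = pair
            if src not in self.types and src not in self.relation_classes:
                raise DefinitionError(f"unknown source {src!r}")
            if tgt not in self.types:
                raise DefinitionError(f"unknown target type {tgt!r}")
            cdef.allowed_pairs.append(pair)

    # -- instances ---------------------------------------------------------

    def create_instance(
        self,
        type_name: str,
        identifier: str,
        labels: Iterable[str] = (),
        props: Optional[Mapping[str, Any]] = None,
    ) -> Instance:
        if type_name not in self.types:
            raise DefinitionError(f"unknown object type {type_name!r}")
        key = ("I", type_name, identifier)
        if key in self.instances:
            raise DefinitionError(
                f"instance {identifier!r} of type {type_name!r} already exists")
        inst = Instance(type_name, identifier, list(labels), dict(props or {}))
        self.instances[key] = inst
        self._instances_by_type.setdefault(type_name, []).append(key)
        return inst

    def get_instance(self, type_name: str, identifier: str) -> Instance:
        key = ("I", type_name, identifier)
        try:
            return self.instances[key]
        except KeyError:
            raise KBError(f"no instance {identifier!r} of type {type_name!r}") from None

    def has_instance(self, type_name: str, identifier: str) -> bool:
        return ("I", type_name, identifier) in self.instances

    def instances_of(self, type_name: str) -> list[Instance]:
        keys = sorted(self._instances_by_type.get(type_name, []))
        return [self.instances[k] for k in keys]

    def ensure_instance(
        self,
        type_name: str,
        identifier: str,
        labels: Iterable[str] = (),
        props: Optional[Mapping[str, Any]] = None,
    ) -> Instance:
        if self.has_instance(type_name, identifier):
            return self.get_instance(type_name, identifier)
        return self.create_instance(type_name, identifier, labels, props)

    # -- relations ---------------------------------------------------------

    def relate(
        self, class_name: str, source: SemanticObject, target: Instance
    ) -> RelationInstance:
        """Create (or return the existing) relation of a class between two
        endpoints.  At most one relation instance exists per
        (class, source, target) triple; re-relating is idempotent.
        """
        if class_name not in self.relation_classes:
            raise DefinitionError(f"unknown relation class {class_name!r}")
        cdef = self.relation_classes[class_name]
        if isinstance(source, RelationInstance):
            src_name = source.class_name
            if source.key not in self.relations:
                raise RelationError("source relation is not registered")
        else:
            src_name = source.type_name
            if source.key not in self.instances:
                raise RelationError(f"source {source!r} is not registered")
        if not isinstance(target, Instance):
            raise RelationError("relation targets must be object instances")
        if target.key not in self.instances:
            raise RelationError(f"target {target!r} is not registered")
        if (src_name, target.type_name) not in {tuple(p) for p in cdef.allowed_pairs}:
            raise RelationError(
                f"pair ({src_name!r}, {target.type_name!r}) not allowed for "
                f"relation class {class_name!r}")
        rel = RelationInstance(class_name, source, target)
        existing = self.relations.get(rel.key)
        if existing is not None:
            return existing
        self.relations[rel.key] = rel
        self._by_source.setdefault(source.key, []).append(rel.key)
        self._by_target.setdefault(target.key, []).append(rel.key)
        return rel

    def relations_of_class(self, class_name: str) -> list[RelationInstance]:
        return [self.relations[k] for k in sorted(self.relations) if k[1] == class_name]

    def resolve_label(self, label: str) -> tuple[RelationClassDef, bool]:
        """Map a traversal label to (relation class, is_forward).

        Raises :class:`QueryError` when the label is unknown or resolves to
        more than one class/direction.
        """
        hits: list[tuple[RelationClassDef, bool]] = []
        for cdef in self.relation_classes.values():
            if cdef.forward_label == label:
                hits.append((cdef, True))
            if cdef.backward_label == label:
                hits.append((cdef, False))
        if not hits:
            raise QueryError(f"traversal label {label!r} does not resolve")
        if len(hits) > 1:
            raise QueryError(f"traversal label {label!r} is ambiguous")
        return hits[0]

    def neighbors(self, obj: SemanticObject, label: str) -> list[SemanticObject]:
        """Objects reachable from ``obj`` via a forward or backward label.

        Forward labels walk source->target, backward labels target->source.
        The returned list is sorted by key and may contain relation
        instances (when a relation is the source of another relation).
        """
        cdef, forward = self.resolve_label(label)
        out: list[SemanticObject] = []
        if forward:
            for rk in self._by_source.get(obj.key, ()):
                rel = self.relations[rk]
                if rel.class_name == cdef.name:
                    out.append(rel.target)
        else:
            for rk in self._by_target.get(obj.key, ()):
                rel = self.relations[rk]
                if rel.class_name == cdef.name:
                    out.append(rel.source)
        return sorted(out, key=lambda o: o.key)

    def relations_from(self, obj: SemanticObject, class_name: Optional[str] = None
                       ) -> list[RelationInstance]:
        rels = [self.relations[k] for k in self._by_source.get(obj.key, ())]
        if class_name is not None:
            rels = [r for r in rels if r.class_name == class_name]
        return sorted(rels, key=lambda r: r.key)

    def relations_to(self, obj: Instance, class_name: Optional[str] = None
                     ) -> list[RelationInstance]:
        rels = [self.relations[k] for k in self._by_target.get(obj.key, ())]
        if class_name is not None:
            rels = [r for r in rels if r.class_name == class_name]
        return sorted(rels, key=lambda r: r.key)

    # -- annotations and contexts ------------------------------------------

    def annotate(
        self, target: SemanticObject, schema_name: str, values: Mapping[str, Any]
    ) -> AnnotationValue:
        if schema_name not in self.schemas:
            raise DefinitionError(f"unknown annotation schema {schema_name!r}")
        if isinstance(target, RelationInstance):
            attached = self.relation_classes[target.class_name].annotation_schemas
            what = f"relation class {target.class_name!r}"
        else:
            attached = self.types[target.type_name].annotation_schemas
            what = f"type {target.type_name!r}"
        if schema_name not in attached:
            raise ValidationError(f"schema {schema_name!r} is not attached to {what}")
        checked = self.schemas[schema_name].validate_values(values)
        ann = AnnotationValue(schema=schema_name, values=checked)
        target.annotations.append(ann)
        return ann

    def find_annotated(
        self, schema_name: str, attr: str, value: Any
    ) -> list[SemanticObject]:
        """All objects carrying an annotation with ``attr == value``."""
        out: list[SemanticObject] = []
        everything: list[SemanticObject] = list(self.instances.values())
        everything += list(self.relations.values())
        for obj in everything:
            for ann in obj.annotations:
                if ann.schema == schema_name and ann.values.get(attr) == value:
                    out.append(obj)
                    break
        return sorted(out, key=lambda o: o.key)

    def add_to_context(self, context: Instance, member: Instance) -> None:
        """Record context membership; idempotent."""
        if self.types[context.type_name].kind is not ObjectKind.CONTEXT:
            raise RelationError(
                f"{context!r} is of kind "
                f"{self.types[context.type_name].kind.value!r}, not a context")
        if member.key not in self.instances:
            raise KBError(f"member {member!r} is not registered")
        members = self.context_members.setdefault(context.key, [])
        if member.key not in members:
            members.append(member.key)

    def members_of(self, context: Instance) -> list[Instance]:
        return [self.instances[k] for k in self.context_members.get(context.key, ())]

    def contexts_of(self, member: Instance) -> list[Instance]:
        out = []
        for ckey, members in self.context_members.items():
            if member.key in members:
                out.append(self.instances[ckey])
        return sorted(out, key=lambda o: o.key)

    # -- audits ------------------------------------------------------------

    def audit(self) -> None:
        """Full-scan structural audit; raises on the first violation.

        Checks that every relation's endpoint names are among its class's
        allowed pairs and that all endpoints are registered.
        """
        for rel in self.relations.values():
            cdef = self.relation_classes[rel.class_name]
            pair = (rel.source_name, rel.target.type_name)
            if pair not in {tuple(p) for p in cdef.allowed_pairs}:
                raise RelationError(
                    f"audit: relation {rel!r} pair {pair} not allowed")
            src_key = rel.source.key
            store = self.relations if src_key[0] == "R" else self.instances
            if src_key not in store or rel.target.key not in self.instances:
                raise RelationError(f"audit: dangling endpoint on {rel!r}")

    # -- serialization -----------------------------------------------------

    @staticmethod
    def _ref(obj: SemanticObject) -> Any:
        if isinstance(obj, RelationInstance):
            return {"relation": [obj.class_name,
                                 KnowledgeBase._ref(obj.source),
                                 KnowledgeBase._ref(obj.target)]}
        return {"instance": [obj.type_name, obj.identifier]}

    def _deref(self, ref: Mapping[str, Any]) -> SemanticObject:
        if "instance" in ref:
            tname, ident = ref["instance"]
            return self.get_instance(tname, ident)
        cname, sref, tref = ref["relation"]
        source = self._deref(sref)
        target = self._deref(tref)
        key = ("R", cname, source.key, target.key)
        try:
            return self.relations[key]
        except KeyError:
            raise KBError(f"dangling relation reference {ref!r}") from None

    def to_dict(self) -> dict[str, Any]:
        from . import experiments as _exp  # deferred: avoids import cycle

        def anns(obj: SemanticObject) -> list[dict[str, Any]]:
            return [{"schema": a.schema, "values": a.values} for a in obj.annotations]

        doc: dict[str, Any] = {
            "types": [
                {"name": t.name, "kind": t.kind.value,
                 "annotation_schemas": sorted(t.annotation_schemas)}
                for t in sorted(self.types.values(), key=lambda t: t.name)
            ],
            "annotation_schemas": [
                {"name": s.name,
                 "attributes": [
                     {"name": a.name, "kind": a.kind.value,
                      "range": list(a.range) if a.range else None,
                      "choices": list(a.choices) if a.choices else None}
                     for a in s.attributes]}
                for s in sorted(self.schemas.values(), key=lambda s: s.name)
            ],
            "relation_classes": [
                {"name": c.name, "forward_label": c.forward_label,
                 "backward_label": c.backward_label,
                 "allowed_pairs": sorted(map(list, c.allowed_pairs)),
                 "annotation_schemas": sorted(c.annotation_schemas)}
                for c in sorted(self.relation_classes.values(), key=lambda c: c.name)
            ],
            "instances": [
                {"type": i.type_name, "id": i.identifier, "labels": i.labels,
                 "props": i.props, "annotations": anns(i)}
                for i in (self.instances[k] for k in sorted(self.instances))
            ],
            "relations": [
                {"class": r.class_name, "source": self._ref(r.source),
                 "target": self._ref(r.target), "annotations": anns(r)}
                for r in (self.relations[k] for k in sorted(self.relations))
            ],
            "contexts": [
                {"context": [k[1], k[2]],
                 "members": [[m[1], m[2]] for m in members]}
                for k, members in sorted(self.context_members.items())
            ],
            "ontologies": [
                {"name": name,
                 "terms": sorted(g.nodes()),
                 "edges": sorted(map(list, g.edges()))}
                for name, g in sorted(self.ontologies.items())
            ],
            "deg_links": [[a, b, int(c)] for (a, b), c in sorted(self.deg_links.items())],
        }
        doc.update(_exp.experiments_to_dict(self))
        return doc

    def to_json(self, **kwargs: Any) -> str:
        kwargs.setdefault("indent", 1)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "KnowledgeBase":
        import networkx as nx
        from . import experiments as _exp

        kb = cls()
        for s in doc.get("annotation_schemas", ()):
            attrs = [
                AttributeDef(
                    a["name"], AttributeKind(a["kind"]),
                    tuple(a["range"]) if a.get("range") else None,
                    tuple(a["choices"]) if a.get("choices") else None)
                for a in s["attributes"]]
            kb.define_annotation_schema(s["name"], attrs)
        for t in doc.get("types", ()):
            tdef = kb.define_object_type(t["name"], ObjectKind(t["kind"]))
            tdef.annotation_schemas = list(t.get("annotation_schemas", []))
        for c in doc.get("relation_classes", ()):
            cdef = kb.define_relation_class(
                c["name"], c["forward_label"], c["backward_label"],
                [tuple(p) for p in c["allowed_pairs"]])
            cdef.annotation_schemas = list(c.get("annotation_schemas", []))
        for i in doc.get("instances", ()):
            inst = kb.create_instance(i["type"], i["id"], i.get("labels", ()),
                                      i.get("props"))
            for a in i.get("annotations", ()):
                inst.annotations.append(AnnotationValue(a["schema"], dict(a["values"])))
        # relations may reference relations; plain instance-sourced ones first
        pending = list(doc.get("relations", ()))
        guard = len(pending) + 1
        while pending and guard:
            guard -= 1
            still = []
            for r in pending:
                try:
                    source = kb._deref(r["source"])
                except KBError:
                    still.append(r)
                    continue
                target = kb._deref(r["target"])
                rel = kb.relate(r["class"], source, target)
                for a in r.get("annotations", ()):
                    rel.annotations.append(AnnotationValue(a["schema"], dict(a["values"])))
            pending = still
        if pending:
            raise DataError("unresolvable relation references in document")
        for c in doc.get("contexts", ()):
            ctx = kb.get_instance(*c["context"])
            for m in c["members"]:
                kb.add_to_context(ctx, kb.get_instance(*m))
        for o in doc.get("ontologies", ()):
            g = nx.DiGraph()
            g.add_nodes_from(o["terms"])
            g.add_edges_from(o["edges"])
            kb.ontologies[o["name"]] = g
        for a, b, count in doc.get("deg_links", ()):
            kb.deg_links[(a, b)] = int(count)
        _exp.experiments_from_dict(kb, doc)
        return kb

    @classmethod
    def load(cls, path: str) -> "KnowledgeBase":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
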