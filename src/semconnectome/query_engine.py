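"""Existential path queries over the knowledge base.

A query names a start type and a condition tree; an instance of the start
type is returned iff the condition holds for it.  ``Related`` is
existential: *there exists* a relation with the given traversal label
whose other endpoint satisfies the nested condition — matching the way
prose queries read ("a patient which *is assessed by* an fMRI").  The only
built-in inference is ``OntologyWithin``, membership of a matched term in
the is-a transitive closure of a root term.

Conditions can be composed programmatically or parsed from a small JSON
syntax (:func:`parse_query`)::

    {"find": "patient",
     "where": {"and": [
         {"in_context": "NKI Rockland"},
         {"related": {"label": "is assessed by",
                      "where": {"id_is": "rs-fMRI"}}}]}}

Condition nodes: ``related`` (``label`` + optional ``where``), ``and`` /
``or`` (lists), ``not``, ``in_context``, ``label_is``, ``id_is``,
``has_entry`` (``method``, ``attr``, ``op``, ``value``) and
``ontology_within`` (``ontology``, ``root``, ``include_self``).
"""

from __future__ import annotations

import csv
import operator
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence, Union

from . import atlas_ontology as ao
from .kgcore import (
    Instance,
    KnowledgeBase,
    ObjectKind,
    QueryError,
    RelationInstance,
    SemanticObject,
)
from .experiments import entries_for_subject

__all__ = [
    "Query",
    "Condition",
    "Related",
    "InContext",
    "HasEntry",
    "OntologyWithin",
    "LabelIs",
    "IdIs",
    "And",
    "Or",
    "Not",
    "Any_",
    "evaluate",
    "availability_table",
    "parse_query",
    "write_results_tsv",
]


class Condition:
    """Base class of the condition tree."""


@dataclass(frozen=True)
class Any_(Condition):
    """Trivially true (the ANY endpoint condition)."""


@dataclass(frozen=True)
class Related(Condition):
    """There exists a relation with this traversal label from/to the
    object whose other endpoint satisfies ``nested`` (default: any)."""

    label: str
    nested: Condition = field(default_factory=Any_)


@dataclass(frozen=True)
class InContext(Condition):
    """The object is a member of the context with this identifier."""

    identifier: str
    context_type: Optional[str] = None


@dataclass(frozen=True)
class HasEntry(Condition):
    """The object is the subject of a data entry in ``method`` whose
    ``attr`` satisfies ``op`` against ``value``."""

    method: str
    attr: str
    op: str
    value: Any


@dataclass(frozen=True)
class OntologyWithin(Condition):
    """The object is a term of ``ontology`` lying in the is-a transitive
    closure under ``root`` (optionally including the root itself)."""

    ontology: str
    root: str
    include_self: bool = True


@dataclass(frozen=True)
class LabelIs(Condition):
    """Case-insensitive match against any of the object's labels."""

    text: str


@dataclass(frozen=True)
class IdIs(Condition):
    """Exact, case-sensitive identifier match."""

    text: str


@dataclass(frozen=True)
class And(Condition):
    children: tuple[Condition, ...]

    def __init__(self, *children: Condition):
        object.__setattr__(self, "children", tuple(children))


@dataclass(frozen=True)
class Or(Condition):
    children: tuple[Condition, ...]

    def __init__(self, *children: Condition):
        object.__setattr__(self, "children", tuple(children))


@dataclass(frozen=True)
class Not(Condition):
    child: Condition


@dataclass(frozen=True)
class Query:
    start_type: str
    condition: Condition = field(default_factory=Any_)


_OPS = {
    "<": operator.lt, "<=": operator.le,
    "=": operator.eq, "==": operator.eq,
    ">=": operator.ge, ">": operator.gt,
    "!=": operator.ne, "≠": operator.ne,
}


def _validate(kb: KnowledgeBase, cond: Condition) -> None:
    """Resolve every name up front so that typos raise a QueryError
    instead of silently producing an empty result."""
    if isinstance(cond, Related):
        kb.resolve_label(cond.label)
        _validate(kb, cond.nested)
    elif isinstance(cond, InContext):
        _resolve_context(kb, cond)
    elif isinstance(cond, HasEntry):
        if cond.method not in kb.methods:
            raise QueryError(f"unknown experiment method {cond.method!r}")
        if cond.op not in _OPS:
            raise QueryError(f"unknown comparator {cond.op!r}")
    elif isinstance(cond, OntologyWithin):
        if cond.ontology not in kb.ontologies:
            raise QueryError(f"unknown ontology {cond.ontology!r}")
        if cond.root not in kb.ontologies[cond.ontology]:
            raise QueryError(
                f"unknown term {cond.root!r} in ontology {cond.ontology!r}")
    elif isinstance(cond, (And, Or)):
        for c in cond.children:
            _validate(kb, c)
    elif isinstance(cond, Not):
        _validate(kb, cond.child)
    elif isinstance(cond, (Any_, LabelIs, IdIs)):
        pass
    else:
        raise QueryError(f"unknown condition {cond!r}")


def _resolve_context(kb: KnowledgeBase, cond: InContext) -> Instance:
    hits = []
    for tname, tdef in kb.types.items():
        if tdef.kind is not ObjectKind.CONTEXT:
            continue
        if cond.context_type is not None and tname != cond.context_type:
            continue
        if kb.has_instance(tname, cond.identifier):
            hits.append(kb.get_instance(tname, cond.identifier))
    if not hits:
        raise QueryError(f"context {cond.identifier!r} does not resolve")
    if len(hits) > 1:
        raise QueryError(
            f"context {cond.identifier!r} is ambiguous; give context_type")
    return hits[0]


def _holds(kb: KnowledgeBase, obj: SemanticObject, cond: Condition) -> bool:
    if isinstance(cond, Any_):
        return True
    if isinstance(cond, Related):
        return any(_holds(kb, other, cond.nested)
                   for other in kb.neighbors(obj, cond.label))
    if isinstance(cond, InContext):
        if not isinstance(obj, Instance):
            return False
        ctx = _resolve_context(kb, cond)
        return obj.key in kb.context_members.get(ctx.key, ())
    if isinstance(cond, HasEntry):
        cmp = _OPS[cond.op]
        for e in entries_for_subject(kb, obj, cond.method):
            if cond.attr in e.values:
                try:
                    if cmp(e.values[cond.attr], cond.value):
                        return True
                except TypeError:
                    pass
        return False
    if isinstance(cond, OntologyWithin):
        if not isinstance(obj, Instance) or obj.type_name != cond.ontology:
            return False
        allowed = ao.ontology_descendants(
            kb, cond.ontology, cond.root, include_self=cond.include_self)
        return obj.identifier in allowed
    if isinstance(cond, LabelIs):
        if not isinstance(obj, Instance):
            return False
        return any(lb.lower() == cond.text.lower() for lb in obj.labels)
    if isinstance(cond, IdIs):
        return isinstance(obj, Instance) and obj.identifier == cond.text
    if isinstance(cond, And):
        return all(_holds(kb, obj, c) for c in cond.children)
    if isinstance(cond, Or):
        return any(_holds(kb, obj, c) for c in cond.children)
    if isinstance(cond, Not):
        return not _holds(kb, obj, cond.child)
    raise QueryError(f"unknown condition {cond!r}")


def evaluate(kb: KnowledgeBase, query: Query) -> list[Instance]:
    """All instances of the start type satisfying the condition, sorted by
    (type, identifier) for reproducibility."""
    if query.start_type not in kb.types:
        raise QueryError(f"unknown start type {query.start_type!r}")
    _validate(kb, query.condition)
    hits = [inst for inst in kb.instances_of(query.start_type)
            if _holds(kb, inst, query.condition)]
    return sorted(hits, key=lambda i: (i.type_name, i.identifier))


# ---------------------------------------------------------------------------
# Availability tables
# ---------------------------------------------------------------------------

PathStep = Union[str, Mapping[str, Any]]


def _render(obj: SemanticObject, how: str) -> str:
    if how == "label" and isinstance(obj, Instance) and obj.labels:
        return obj.labels[0]
    if isinstance(obj, RelationInstance):
        return f"{_render(obj.source, how)}->{_render(obj.target, how)}"
    return obj.identifier


def _path_bindings(kb: KnowledgeBase, obj: SemanticObject,
                   path: Sequence[PathStep]) -> list[Any]:
    """All cell values reachable from ``obj`` along a column path.

    Steps: a relation label (traversal), ``"id"`` / ``"label"`` (terminal
    rendering) or ``{"entry": {"method": m, "attr": a}}`` which yields the
    entry values stored for the current object as an experiment subject.
    """
    frontier: list[SemanticObject] = [obj]
    render = "id"
    for step in path:
        if isinstance(step, Mapping):
            if "entry" not in step:
                raise QueryError(f"unknown path step {step!r}")
            spec = step["entry"]
            method, attr = spec["method"], spec.get("attr", "value")
            if method not in kb.methods:
                raise QueryError(f"unknown experiment method {method!r}")
            values: list[Any] = []
            for cur in frontier:
                for e in entries_for_subject(kb, cur, method):
                    if attr in e.values:
                        values.append(e.values[attr])
            return values
        if step in ("id", "label"):
            render = step
            continue
        nxt: list[SemanticObject] = []
        for cur in frontier:
            nxt.extend(kb.neighbors(cur, step))
        frontier = nxt
    return [_render(o, render) for o in frontier]


def availability_table(
    kb: KnowledgeBase,
    query: Query,
    column_paths: Optional[Sequence[Sequence[PathStep]]] = None,
    column_names: Optional[Sequence[str]] = None,
):
    """Expand query results into a table, one row per binding.

    For each result instance the bindings of every column path are
    enumerated and crossed (nested-loop join); a path with no binding
    contributes an empty cell.  Without column paths the table is a single
    column of result identifiers.
    """
    import itertools

    import pandas as pd

    results = evaluate(kb, query)
    column_paths = list(column_paths or [])
    if column_names is None:
        column_names = [f"col{i + 1}" for i in range(len(column_paths))]
    if len(column_names) != len(column_paths):
        raise QueryError("column_names and column_paths differ in length")
    rows = []
    for inst in results:
        per_path = []
        for path in column_paths:
            vals = _path_bindings(kb, inst, path)
            per_path.append(vals if vals else [None])
        for combo in itertools.product(*per_path):
            rows.append([inst.identifier, *combo])
    return pd.DataFrame(rows, columns=["result", *column_names])


# ---------------------------------------------------------------------------
# JSON query syntax
# ---------------------------------------------------------------------------

def _parse_condition(node: Any) -> Condition:
    if node is None or node == {} or node == "any":
        return Any_()
    if not isinstance(node, Mapping) or len(node) != 1:
        raise QueryError(f"malformed condition node {node!r}")
    (kind, body), = node.items()
    if kind == "related":
        return Related(body["label"], _parse_condition(body.get("where")))
    if kind == "and":
        return And(*(_parse_condition(c) for c in body))
    if kind == "or":
        return Or(*(_parse_condition(c) for c in body))
    if kind == "not":
        return Not(_parse_condition(body))
    if kind == "in_context":
        if isinstance(body, Mapping):
            return InContext(body["id"], body.get("type"))
        return InContext(str(body))
    if kind == "label_is":
        return LabelIs(str(body))
    if kind == "id_is":
        return IdIs(str(body))
    if kind == "has_entry":
        return HasEntry(body["method"], body.get("attr", "value"),
                        body.get("op", "="), body["value"])
    if kind == "ontology_within":
        return OntologyWithin(body["ontology"], body["root"],
                              bool(body.get("include_self", True)))
    raise QueryError(f"unknown condition kind {kind!r}")


def parse_query(doc: Mapping[str, Any]) -> Query:
    """Build a :class:`Query` from the JSON syntax described above."""
    if "find" not in doc:
        raise QueryError("query document lacks 'find'")
    return Query(doc["find"], _parse_condition(doc.get("where")))


def write_results_tsv(results: Sequence[Instance], path: str) -> int:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["type", "identifier", "labels"])
        for inst in results:
            w.writerow([inst.type_name, inst.identifier, "; ".join(inst.labels)])
    return len(results)
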