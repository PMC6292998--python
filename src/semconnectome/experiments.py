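"""Subject-indexed measurement store.

An *experiment method* fixes a subject specification and one or more data
formats; an *experiment* is one run of a method (e.g. one donor brain, one
averaged connectivity data set); a *data entry* is one measurement, keyed
by the experiment, the subject and the format.  The subject may be an
object instance (a patient, a probe, a brain coordinate) or — crucially for
connectivity — a relation instance, so that a measured brain connection can
itself carry a fiber density and a correlation value.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .kgcore import (
    AttributeDef,
    AttributeKind,
    DataError,
    DefinitionError,
    Instance,
    KnowledgeBase,
    RelationInstance,
    SemanticObject,
    ValidationError,
)

__all__ = [
    "SubjectKind",
    "SubjectSpec",
    "FormatDef",
    "ExperimentMethodDef",
    "Experiment",
    "DataEntry",
    "STANDARD_FORMATS",
    "standard_format",
    "define_experiment_method",
    "create_experiment",
    "add_data_entry",
    "get_entry",
    "entries_for_method",
    "entries_for_subject",
    "tabulate",
    "export_entries_tsv",
    "audit_entries",
]


class SubjectKind(Enum):
    OBJECT_TYPE = "object_type"
    RELATION_CLASS = "relation_class"


@dataclass(frozen=True)
class SubjectSpec:
    kind: SubjectKind
    name: str


@dataclass(frozen=True)
class FormatDef:
    """A named measurement format with typed, range-checked attributes."""

    name: str
    attributes: tuple[AttributeDef, ...]

    @property
    def primary_attr(self) -> str:
        return self.attributes[0].name


def _fmt(name: str, *attrs: AttributeDef) -> FormatDef:
    return FormatDef(name, tuple(attrs))


#: Formats used throughout the brain-science knowledge model, with the
#: value ranges the modality dictates: correlation values live in [-1, 1],
#: normalized densities and tracking probabilities in [0, 1], absolute
#: densities are non-negative, expression levels carry a validity flag
#: (PACall) next to the log-intensity value.
STANDARD_FORMATS: dict[str, FormatDef] = {
    f.name: f
    for f in (
        _fmt("normalized correlation value",
             AttributeDef("value", AttributeKind.REAL, (-1.0, 1.0))),
        _fmt("absolute correlation value",
             AttributeDef("value", AttributeKind.REAL, (-1.0, 1.0))),
        _fmt("normalized fiber density",
             AttributeDef("value", AttributeKind.REAL, (0.0, 1.0))),
        _fmt("absolute fiber density",
             AttributeDef("value", AttributeKind.REAL, (0.0, None))),
        _fmt("probability",
             AttributeDef("value", AttributeKind.REAL, (0.0, 1.0))),
        _fmt("expression level",
             AttributeDef("value", AttributeKind.REAL),
             AttributeDef("pacall", AttributeKind.FLAG)),
        _fmt("18FDG",
             AttributeDef("value", AttributeKind.REAL, (0.0, None)),
             AttributeDef("unit", AttributeKind.TEXT)),
        _fmt("receptor density",
             AttributeDef("value", AttributeKind.REAL, (0.0, None)),
             AttributeDef("unit", AttributeKind.TEXT)),
    )
}


def standard_format(name: str) -> FormatDef:
    try:
        return STANDARD_FORMATS[name]
    except KeyError:
        raise DefinitionError(f"unknown standard format {name!r}") from None


@dataclass
class ExperimentMethodDef:
    name: str
    subject: SubjectSpec
    formats: dict[str, FormatDef]


@dataclass
class Experiment:
    method_name: str
    name: str
    metadata: dict[str, Any] = field(default_factory=dict)


@dataclass
class DataEntry:
    method_name: str
    experiment_name: str
    subject: SemanticObject
    format_name: str
    values: dict[str, Any]

    @property
    def key(self) -> tuple:
        return (self.method_name, self.experiment_name,
                self.subject.key, self.format_name)


def _coerce_subject(kb: KnowledgeBase, subject: Union[SubjectSpec, tuple, str]
                    ) -> SubjectSpec:
    if isinstance(subject, SubjectSpec):
        spec = subject
    elif isinstance(subject, tuple):
        kind, name = subject
        spec = SubjectSpec(SubjectKind(kind) if not isinstance(kind, SubjectKind)
                           else kind, name)
    else:
        # bare name: resolve against types first, then relation classes
        if subject in kb.types:
            spec = SubjectSpec(SubjectKind.OBJECT_TYPE, subject)
        elif subject in kb.relation_classes:
            spec = SubjectSpec(SubjectKind.RELATION_CLASS, subject)
        else:
            raise DefinitionError(f"unknown experiment subject {subject!r}")
    if spec.kind is SubjectKind.OBJECT_TYPE and spec.name not in kb.types:
        raise DefinitionError(f"unknown subject object type {spec.name!r}")
    if spec.kind is SubjectKind.RELATION_CLASS and spec.name not in kb.relation_classes:
        raise DefinitionError(f"unknown subject relation class {spec.name!r}")
    return spec


def define_experiment_method(
    kb: KnowledgeBase,
    name: str,
    subject: Union[SubjectSpec, tuple, str],
    formats: Sequence[Union[FormatDef, str]],
) -> ExperimentMethodDef:
    if name in kb.methods:
        raise DefinitionError(f"experiment method {name!r} already defined")
    spec = _coerce_subject(kb, subject)
    fdefs = [standard_format(f) if isinstance(f, str) else f for f in formats]
    if not fdefs:
        raise DefinitionError(f"method {name!r}: at least one format is required")
    names = [f.name for f in fdefs]
    if len(names) != len(set(names)):
        raise DefinitionError(f"method {name!r}: duplicate format names")
    mdef = ExperimentMethodDef(name, spec, {f.name: f for f in fdefs})
    kb.methods[name] = mdef
    return mdef


def ensure_experiment_method(
    kb: KnowledgeBase, name: str, subject: Any, formats: Sequence[Any]
) -> ExperimentMethodDef:
    if name in kb.methods:
        mdef = kb.methods[name]
        for f in formats:
            fdef = standard_format(f) if isinstance(f, str) else f
            mdef.formats.setdefault(fdef.name, fdef)
        return mdef
    return define_experiment_method(kb, name, subject, formats)


def create_experiment(
    kb: KnowledgeBase, method: str, name: str,
    metadata: Optional[Mapping[str, Any]] = None,
) -> Experiment:
    if method not in kb.methods:
        raise DefinitionError(f"unknown experiment method {method!r}")
    key = (method, name)
    if key in kb.experiments:
        raise DefinitionError(f"experiment {name!r} already exists in {method!r}")
    exp = Experiment(method, name, dict(metadata or {}))
    kb.experiments[key] = exp
    return exp


def _check_subject(kb: KnowledgeBase, spec: SubjectSpec, subject: SemanticObject) -> None:
    if spec.kind is SubjectKind.OBJECT_TYPE:
        if not isinstance(subject, Instance) or subject.type_name != spec.name:
            raise ValidationError(
                f"subject {subject!r} does not match object type {spec.name!r}")
    else:
        if not isinstance(subject, RelationInstance) or subject.class_name != spec.name:
            raise ValidationError(
                f"subject {subject!r} does not match relation class {spec.name!r}")


def add_data_entry(
    kb: KnowledgeBase,
    experiment: Experiment,
    subject: SemanticObject,
    format_name: str,
    values: Union[Mapping[str, Any], int, float],
    replace: bool = False,
) -> DataEntry:
    """Store one measurement.  ``values`` may be a scalar, which is taken as
    the format's primary (first) attribute.  Writing a second entry for the
    same (experiment, subject, format) is an error unless ``replace``.
    """
    mdef: ExperimentMethodDef = kb.methods[experiment.method_name]
    if format_name not in mdef.formats:
        raise ValidationError(
            f"method {mdef.name!r} has no format {format_name!r}")
    fdef = mdef.formats[format_name]
    _check_subject(kb, mdef.subject, subject)
    if not isinstance(values, Mapping):
        values = {fdef.primary_attr: values}
    checked: dict[str, Any] = {}
    by_name = {a.name: a for a in fdef.attributes}
    for attr, val in values.items():
        if attr not in by_name:
            raise ValidationError(f"format {format_name!r} has no attribute {attr!r}")
        checked[attr] = by_name[attr].validate(val)
    entry = DataEntry(experiment.method_name, experiment.name, subject,
                      format_name, checked)
    if entry.key in kb.entries and not replace:
        raise DataError(
            f"entry already exists for {entry.key}; pass replace=True to overwrite")
    kb.entries[entry.key] = entry
    return entry


def get_entry(
    kb: KnowledgeBase, method: str, experiment: str,
    subject: SemanticObject, format_name: str,
) -> Optional[DataEntry]:
    return kb.entries.get((method, experiment, subject.key, format_name))


def entries_for_method(kb: KnowledgeBase, method: str) -> list[DataEntry]:
    return [kb.entries[k] for k in sorted(kb.entries) if k[0] == method]


def entries_for_subject(
    kb: KnowledgeBase, subject: SemanticObject, method: Optional[str] = None
) -> list[DataEntry]:
    out = [e for e in kb.entries.values() if e.subject.key == subject.key]
    if method is not None:
        out = [e for e in out if e.method_name == method]
    return sorted(out, key=lambda e: e.key)


def subject_id(subject: SemanticObject) -> str:
    """Human-readable row label for a subject."""
    if isinstance(subject, RelationInstance):
        return f"{subject_id(subject.source)}->{subject_id(subject.target)}"
    return subject.identifier


def tabulate(
    kb: KnowledgeBase,
    method: str,
    experiments: Optional[Sequence[str]] = None,
    value_attr: Optional[str] = None,
) -> pd.DataFrame:
    """Expand a method into a subjects x experiments table.

    Rows are the distinct subjects seen in the method's entries, columns
    the experiment names; each populated cell is the entry's primary value
    (or ``value_attr``).  Missing measurements stay NaN.
    """
    if method not in kb.methods:
        raise DefinitionError(f"unknown experiment method {method!r}")
    if experiments is None:
        experiments = sorted(n for (m, n) in kb.experiments if m == method)
    entries = entries_for_method(kb, method)
    rows: dict[str, dict[str, Any]] = {}
    for e in entries:
        if e.experiment_name not in experiments:
            continue
        attr = value_attr or kb.methods[method].formats[e.format_name].primary_attr
        if attr in e.values:
            rows.setdefault(subject_id(e.subject), {})[e.experiment_name] = e.values[attr]
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=object)
    table = table.reindex(columns=list(experiments))
    return table.sort_index()


def export_entries_tsv(kb: KnowledgeBase, path: str,
                       method: Optional[str] = None) -> int:
    """Write entries in long form: method, experiment, subject, format,
    attribute, value.  Returns the number of rows written."""
    keys = sorted(kb.entries)
    if method is not None:
        keys = [k for k in keys if k[0] == method]
    n = 0
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["method", "experiment", "subject", "format", "attribute", "value"])
        for k in keys:
            e = kb.entries[k]
            for attr in sorted(e.values):
                w.writerow([e.method_name, e.experiment_name, subject_id(e.subject),
                            e.format_name, attr, e.values[attr]])
                n += 1
    return n


def audit_entries(kb: KnowledgeBase) -> None:
    """Global audit: every entry's subject matches its method's subject
    spec and every value re-validates against its format."""
    for e in kb.entries.values():
        mdef = kb.methods[e.method_name]
        _check_subject(kb, mdef.subject, e.subject)
        fdef = mdef.formats[e.format_name]
        by_name = {a.name: a for a in fdef.attributes}
        for attr, val in e.values.items():
            by_name[attr].validate(val)


# -- serialization hooks used by KnowledgeBase ------------------------------

def _subject_from_ref(kb: KnowledgeBase, ref: Mapping[str, Any]) -> SemanticObject:
    return kb._deref(ref)


def experiments_to_dict(kb: KnowledgeBase) -> dict[str, Any]:
    def fmt_doc(f: FormatDef) -> dict[str, Any]:
        return {"name": f.name,
                "attributes": [
                    {"name": a.name, "kind": a.kind.value,
                     "range": list(a.range) if a.range else None,
                     "choices": list(a.choices) if a.choices else None}
                    for a in f.attributes]}

    return {
        "methods": [
            {"name": m.name,
             "subject": {"kind": m.subject.kind.value, "name": m.subject.name},
             "formats": [fmt_doc(f) for _, f in sorted(m.formats.items())]}
            for m in sorted(kb.methods.values(), key=lambda m: m.name)
        ],
        "experiments": [
            {"method": e.method_name, "name": e.name, "metadata": e.metadata}
            for e in (kb.experiments[k] for k in sorted(kb.experiments))
        ],
        "entries": [
            {"method": e.method_name, "experiment": e.experiment_name,
             "subject": KnowledgeBase._ref(e.subject),
             "format": e.format_name, "values": e.values}
            for e in (kb.entries[k] for k in sorted(kb.entries))
        ],
    }


def experiments_from_dict(kb: KnowledgeBase, doc: Mapping[str, Any]) -> None:
    for m in doc.get("methods", ()):
        fdefs = [
            FormatDef(f["name"], tuple(
                AttributeDef(a["name"], AttributeKind(a["kind"]),
                             tuple(a["range"]) if a.get("range") else None,
                             tuple(a["choices"]) if a.get("choices") else None)
                for a in f["attributes"]))
            for f in m["formats"]]
        define_experiment_method(
            kb, m["name"],
            SubjectSpec(SubjectKind(m["subject"]["kind"]), m["subject"]["name"]),
            fdefs)
    for e in doc.get("experiments", ()):
        create_experiment(kb, e["method"], e["name"], e.get("metadata"))
    for e in doc.get("entries", ()):
        exp = kb.experiments[(e["method"], e["experiment"])]
        subject = _subject_from_ref(kb, e["subject"])
        add_data_entry(kb, exp, subject, e["format"], dict(e["values"]))
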