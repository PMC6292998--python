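"""Shared fixtures: small hand-built knowledge bases and a random
knowledge-base generator used by the query-engine oracle tests."""

from __future__ import annotations

import numpy as np
import pytest

import semconnectome as sc
from semconnectome import query_engine as qe
from semconnectome.experiments import (
    FormatDef,
    add_data_entry,
    create_experiment,
    define_experiment_method,
)
from semconnectome.kgcore import AttributeDef, AttributeKind, KnowledgeBase, ObjectKind


@pytest.fixture
def clinical_kb() -> KnowledgeBase:
    """Five patients in a study, with rs-fMRI / DTI assessments mirroring
    the patient-availability use case."""
    kb = KnowledgeBase()
    kb.define_object_type("patient", ObjectKind.ELEMENT)
    kb.define_object_type("scan", ObjectKind.EXPERIMENT)
    kb.define_object_type("study", ObjectKind.CONTEXT)
    kb.define_relation_class("brain imaging", "is assessed by", "assesses",
                             [("patient", "scan")])
    study = kb.create_instance("study", "NKI Rockland")
    fmri = kb.create_instance("scan", "rs-fMRI")
    dti = kb.create_instance("scan", "DTI")
    for i in range(1, 6):
        p = kb.create_instance("patient", f"P{i}")
        kb.add_to_context(study, p)
    # P1, P2 have both modalities; P3 only fMRI; P4 only DTI; P5 none
    for pid, scans in (("P1", (fmri, dti)), ("P2", (fmri, dti)),
                       ("P3", (fmri,)), ("P4", (dti,))):
        for s in scans:
            kb.relate("brain imaging", kb.get_instance("patient", pid), s)
    return kb


LABEL_POOL = ["alpha", "beta", "gamma", "delta"]


def random_kb(rng: np.random.Generator) -> KnowledgeBase:
    """A small random knowledge base: patients/scans/studies with random
    relations, context memberships, lab entries and a random is-a DAG."""
    kb = KnowledgeBase()
    kb.define_object_type("patient", ObjectKind.ELEMENT)
    kb.define_object_type("scan", ObjectKind.EXPERIMENT)
    kb.define_object_type("study", ObjectKind.CONTEXT)
    kb.define_object_type("anatomy", ObjectKind.ONTOLOGY)
    kb.define_relation_class("brain imaging", "is assessed by", "assesses",
                             [("patient", "scan")])
    kb.define_relation_class("referral", "refers to", "is referred by",
                             [("patient", "patient")])
    n_pat = int(rng.integers(2, 15))
    n_scan = int(rng.integers(1, 6))
    patients = [
        kb.create_instance(
            "patient", f"P{i}",
            labels=list(rng.choice(LABEL_POOL, size=rng.integers(0, 3),
                                   replace=False)))
        for i in range(n_pat)
    ]
    scans = [kb.create_instance("scan", f"S{i}") for i in range(n_scan)]
    studies = [kb.create_instance("study", f"St{i}") for i in range(2)]
    for p in patients:
        for s in scans:
            if rng.random() < 0.3:
                kb.relate("brain imaging", p, s)
        for q in patients:
            if p is not q and rng.random() < 0.1:
                kb.relate("referral", p, q)
        if rng.random() < 0.6:
            kb.add_to_context(studies[int(rng.integers(0, 2))], p)
    # lab entries
    define_experiment_method(
        kb, "laboratory", ("object_type", "patient"),
        [FormatDef("blood value", (AttributeDef("value", AttributeKind.REAL),))])
    exp = create_experiment(kb, "laboratory", "visit1")
    for p in patients:
        if rng.random() < 0.5:
            add_data_entry(kb, exp, p, "blood value",
                           float(rng.uniform(0, 10)))
    # random is-a DAG over a handful of anatomy terms
    import pandas as pd

    from semconnectome.atlas_ontology import load_ontology

    n_terms = int(rng.integers(3, 9))
    terms = pd.DataFrame({"term_id": [f"T{i}" for i in range(n_terms)],
                          "name": [f"term {i}" for i in range(n_terms)]})
    edges = [(f"T{i}", f"T{int(rng.integers(i + 1, n_terms))}")
             for i in range(n_terms - 1) if rng.random() < 0.8]
    load_ontology(kb, "anatomy",
                  terms, pd.DataFrame(edges, columns=["child_id", "parent_id"]))
    return kb


def random_condition(rng: np.random.Generator, kb: KnowledgeBase,
                     depth: int = 0) -> qe.Condition:
    """A random condition tree of depth <= 4 over ``random_kb`` names."""
    leaf_kinds = ["any", "label", "id", "context", "entry", "ontology"]
    branch_kinds = ["related", "and", "or", "not"]
    kinds = leaf_kinds if depth >= 3 else leaf_kinds + branch_kinds * 2
    kind = rng.choice(kinds)
    if kind == "any":
        return qe.Any_()
    if kind == "label":
        return qe.LabelIs(str(rng.choice(LABEL_POOL)))
    if kind == "id":
        return qe.IdIs(f"P{int(rng.integers(0, 15))}")
    if kind == "context":
        return qe.InContext(f"St{int(rng.integers(0, 2))}")
    if kind == "entry":
        return qe.HasEntry("laboratory", "value",
                           str(rng.choice(["<", "<=", ">=", ">"])),
                           float(rng.uniform(0, 10)))
    if kind == "ontology":
        terms = sorted(kb.ontologies["anatomy"].nodes)
        return qe.OntologyWithin("anatomy", str(rng.choice(terms)),
                                 include_self=bool(rng.random() < 0.5))
    if kind == "related":
        label = str(rng.choice(["is assessed by", "assesses", "refers to",
                                "is referred by"]))
        return qe.Related(label, random_condition(rng, kb, depth + 1))
    if kind == "not":
        return qe.Not(random_condition(rng, kb, depth + 1))
    n = int(rng.integers(2, 4))
    children = [random_condition(rng, kb, depth + 1) for _ in range(n)]
    return qe.And(*children) if kind == "and" else qe.Or(*children)


def oracle_holds(kb: KnowledgeBase, obj, cond: qe.Condition) -> bool:
    """Independent condition checker: full scans over the raw relation,
    context, entry and ontology stores — no traversal indexes, no shared
    code with the engine's ``_holds``."""
    from semconnectome.kgcore import Instance

    if isinstance(cond, qe.Any_):
        return True
    if isinstance(cond, qe.Related):
        # resolve the label by scanning all classes
        for cdef in kb.relation_classes.values():
            if cdef.forward_label == cond.label:
                for rel in kb.relations.values():
                    if rel.class_name == cdef.name and rel.source.key == obj.key \
                            and oracle_holds(kb, rel.target, cond.nested):
                        return True
            if cdef.backward_label == cond.label:
                for rel in kb.relations.values():
                    if rel.class_name == cdef.name and rel.target.key == obj.key \
                            and oracle_holds(kb, rel.source, cond.nested):
                        return True
        return False
    if isinstance(cond, qe.InContext):
        if not isinstance(obj, Instance):
            return False
        for ckey, members in kb.context_members.items():
            if ckey[2] == cond.identifier and obj.key in members:
                return True
        return False
    if isinstance(cond, qe.HasEntry):
        import operator as op

        cmp = {"<": op.lt, "<=": op.le, "=": op.eq, "==": op.eq,
               ">=": op.ge, ">": op.gt, "!=": op.ne}[cond.op]
        for e in kb.entries.values():
            if e.method_name == cond.method and e.subject.key == obj.key \
                    and cond.attr in e.values and cmp(e.values[cond.attr],
                                                     cond.value):
                return True
        return False
    if isinstance(cond, qe.OntologyWithin):
        if not isinstance(obj, Instance) or obj.type_name != cond.ontology:
            return False
        g = kb.ontologies[cond.ontology]
        edges = set(g.edges())

        def reaches(node: str, goal: str, seen: frozenset) -> bool:
            if node == goal:
                return True
            return any(reaches(p, goal, seen | {node})
                       for (c, p) in edges if c == node and p not in seen)

        if obj.identifier == cond.root:
            return cond.include_self
        return reaches(obj.identifier, cond.root, frozenset())
    if isinstance(cond, qe.LabelIs):
        return isinstance(obj, Instance) and \
            cond.text.lower() in [lb.lower() for lb in obj.labels]
    if isinstance(cond, qe.IdIs):
        return isinstance(obj, Instance) and obj.identifier == cond.text
    if isinstance(cond, qe.And):
        return all(oracle_holds(kb, obj, c) for c in cond.children)
    if isinstance(cond, qe.Or):
        return any(oracle_holds(kb, obj, c) for c in cond.children)
    if isinstance(cond, qe.Not):
        return not oracle_holds(kb, obj, cond.child)
    raise AssertionError(f"oracle: unknown condition {cond!r}")


def oracle_evaluate(kb: KnowledgeBase, query: qe.Query) -> list:
    return sorted(
        (i for i in kb.instances.values() if i.type_name == query.start_type
         and oracle_holds(kb, i, query.condition)),
        key=lambda i: (i.type_name, i.identifier))
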