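"""Brain atlases, MNI coordinates, parcellation and mapping relations,
and ontology transitive closure.

Three naming layers are joined here:

* *measured brain coordinates* — 3D points (millimetres) in a coordinate
  frame such as MNI-152, one semantic object per point;
* *atlas entries* — rows of a flat parcellation atlas (Craddock200, AAL,
  ...) or terms of a hierarchical atlas ontology (FreeSurfer, Allen Human
  Brain Atlas, FMA, Brede);
* *brain structures* — an atlas-independent repository of canonical
  structures to which atlas entries and ontology terms map ("best match").

The chain coordinate --belongs to--> atlas entry --maps to--> brain
structure --maps to--> ontology term is what lets a connectivity
measurement taken at raw coordinates be queried by anatomical name, and
the is-a transitive closure (``ontology_descendants``) is the single
built-in inference used to expand a coarse term into all its sub-regions.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd

from .kgcore import (
    DataError,
    DefinitionError,
    Instance,
    KBError,
    KnowledgeBase,
    ObjectKind,
    logger,
)

__all__ = [
    "COORDINATE_TYPE",
    "STRUCTURE_TYPE",
    "PARCELLATION_CLASS",
    "MAPPING_CLASS",
    "ensure_coordinate",
    "load_flat_atlas",
    "load_ontology",
    "ontology_roots",
    "ontology_descendants",
    "parcellate_coordinates",
    "register_brain_mapping",
    "coordinate_terms",
]

COORDINATE_TYPE = "measured brain coordinates"
STRUCTURE_TYPE = "brain structure"
PARCELLATION_CLASS = "image parcellation"
MAPPING_CLASS = "brain mapping"

DEFAULT_FRAME = "MNI152"


def ensure_coordinate(
    kb: KnowledgeBase,
    identifier: str,
    x: float,
    y: float,
    z: float,
    frame: str = DEFAULT_FRAME,
    labels: Iterable[str] = (),
) -> Instance:
    """Register a measured brain coordinate (idempotent by identifier)."""
    if not frame:
        raise DataError("coordinate frame must be non-empty")
    kb.ensure_object_type(COORDINATE_TYPE, ObjectKind.ELEMENT)
    if kb.has_instance(COORDINATE_TYPE, identifier):
        return kb.get_instance(COORDINATE_TYPE, identifier)
    return kb.create_instance(
        COORDINATE_TYPE, identifier, labels,
        {"frame": frame, "x": float(x), "y": float(y), "z": float(z)})


def load_flat_atlas(kb: KnowledgeBase, name: str, table: pd.DataFrame
                    ) -> list[Instance]:
    """Register a flat atlas as an ELEMENT type with one instance per row.

    ``table`` needs ``entry_id`` and ``label`` columns; optional ``x, y,
    z`` columns (MNI millimetres) are kept as instance properties.
    """
    for col in ("entry_id", "label"):
        if col not in table.columns:
            raise DataError(f"atlas table lacks required column {col!r}")
    ids = table["entry_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise DataError(f"atlas {name!r}: duplicate entry id {dup!r}")
    kb.ensure_object_type(name, ObjectKind.ELEMENT)
    out = []
    has_xyz = {"x", "y", "z"}.issubset(table.columns)
    for _, row in table.iterrows():
        props = {}
        if has_xyz:
            props = {"x": float(row["x"]), "y": float(row["y"]), "z": float(row["z"])}
        out.append(kb.create_instance(name, str(row["entry_id"]),
                                      [str(row["label"])], props))
    return out


def load_ontology(
    kb: KnowledgeBase,
    name: str,
    terms: pd.DataFrame,
    edges: pd.DataFrame,
) -> nx.DiGraph:
    """Register an ontology: terms plus an acyclic is-a edge list.

    ``terms`` needs ``term_id`` and ``name`` columns, ``edges`` needs
    ``child_id`` and ``parent_id`` (child *is a* parent).  The is-a graph
    may be a DAG (multiple parents); cycles are rejected naming a member.
    """
    for col in ("term_id", "name"):
        if col not in terms.columns:
            raise DataError(f"ontology term table lacks column {col!r}")
    for col in ("child_id", "parent_id"):
        if col not in edges.columns:
            raise DataError(f"ontology edge table lacks column {col!r}")
    ids = terms["term_id"].astype(str)
    if ids.duplicated().any():
        raise DataError(f"ontology {name!r}: duplicate term ids")
    declared = set(ids)
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    for _, row in edges.iterrows():
        child, parent = str(row["child_id"]), str(row["parent_id"])
        if child not in declared or parent not in declared:
            raise DataError(
                f"ontology {name!r}: edge ({child!r}, {parent!r}) references "
                "an undeclared term")
        g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        member = nx.find_cycle(g)[0][0]
        raise DataError(f"ontology {name!r}: is-a cycle involving term {member!r}")
    kb.ensure_object_type(name, ObjectKind.ONTOLOGY)
    for _, row in terms.iterrows():
        kb.ensure_instance(name, str(row["term_id"]), [str(row["name"])])
    kb.ontologies[name] = g
    return g


def _graph(kb: KnowledgeBase, ontology: str) -> nx.DiGraph:
    try:
        return kb.ontologies[ontology]
    except KeyError:
        raise KBError(f"unknown ontology {ontology!r}") from None


def ontology_roots(kb: KnowledgeBase, ontology: str) -> set[str]:
    """Terms without parents (is-a edges point child -> parent)."""
    g = _graph(kb, ontology)
    return {n for n in g.nodes if g.out_degree(n) == 0}


def ontology_descendants(
    kb: KnowledgeBase, ontology: str, term_id: str, include_self: bool = False
) -> set[str]:
    """Transitive closure of is-a children of ``term_id``.

    A term d is a descendant of t iff a chain d is-a ... is-a t exists;
    this is the "is inferred from" expansion used by the cross-modal join.
    """
    g = _graph(kb, ontology)
    if term_id not in g:
        raise KBError(f"unknown term {term_id!r} in ontology {ontology!r}")
    # edges run child -> parent, so descendants are the graph-ancestors
    out = set(nx.ancestors(g, term_id))
    if include_self:
        out.add(term_id)
    return out


def _ensure_parcellation_class(kb: KnowledgeBase, atlas: str) -> None:
    if PARCELLATION_CLASS not in kb.relation_classes:
        kb.define_relation_class(PARCELLATION_CLASS, "belongs to", "parcellates",
                                 [(COORDINATE_TYPE, atlas)])
    else:
        kb.extend_relation_class(PARCELLATION_CLASS, (COORDINATE_TYPE, atlas))


def parcellate_coordinates(
    kb: KnowledgeBase,
    coordinate_ids: Sequence[str],
    lookup: Union[pd.DataFrame, Mapping[str, str]],
    atlas: str,
    frame: str = DEFAULT_FRAME,
) -> list:
    """Create image-parcellation relations coordinate -> atlas entry.

    ``lookup`` maps coordinate identifiers to atlas entry ids (DataFrame
    with ``coordinate_id``/``entry_id`` columns, or a plain mapping).  All
    coordinates must share the frame of the lookup table; a coordinate may
    simultaneously be parcellated by several atlases.
    """
    if isinstance(lookup, pd.DataFrame):
        pairs = [(str(r["coordinate_id"]), str(r["entry_id"]))
                 for _, r in lookup.iterrows()]
    else:
        pairs = [(str(c), str(e)) for c, e in lookup.items()]
    if atlas not in kb.types:
        raise KBError(f"unknown atlas {atlas!r}")
    coords = [kb.get_instance(COORDINATE_TYPE, cid) for cid in coordinate_ids]
    frames = {c.props.get("frame") for c in coords}
    if len(frames) > 1:
        raise DataError(f"coordinates span multiple frames: {sorted(frames)}")
    if coords and frames != {frame}:
        raise DataError(
            f"coordinate frame {frames.pop()!r} does not match lookup frame {frame!r}")
    wanted = set(coordinate_ids)
    _ensure_parcellation_class(kb, atlas)
    rels = []
    for cid, eid in pairs:
        if cid not in wanted:
            continue
        coord = kb.get_instance(COORDINATE_TYPE, cid)
        entry = kb.get_instance(atlas, eid)
        rels.append(kb.relate(PARCELLATION_CLASS, coord, entry))
    return rels


def register_brain_mapping(kb: KnowledgeBase, mapping: pd.DataFrame) -> list:
    """Create brain-mapping relations from a curated "best match" table.

    Columns: ``atlas``, ``entry_id``, ``structure_name`` and optionally
    ``ontology``, ``term_id``.  Builds atlas entry --maps to--> brain
    structure and brain structure --maps to--> ontology term relations;
    brain structures are created on first sight (canonical names unique).
    Endpoints that do not exist raise.
    """
    for col in ("atlas", "entry_id", "structure_name"):
        if col not in mapping.columns:
            raise DataError(f"mapping table lacks column {col!r}")
    kb.ensure_object_type(STRUCTURE_TYPE, ObjectKind.CONTEXT)
    rels = []
    for _, row in mapping.iterrows():
        atlas, eid = str(row["atlas"]), str(row["entry_id"])
        sname = str(row["structure_name"])
        if atlas not in kb.types:
            raise KBError(f"unknown atlas {atlas!r} in mapping table")
        entry = kb.get_instance(atlas, eid)  # raises on unknown entry
        structure = kb.ensure_instance(STRUCTURE_TYPE, sname, [sname])
        if MAPPING_CLASS not in kb.relation_classes:
            kb.define_relation_class(MAPPING_CLASS, "maps to", "is mapped by",
                                     [(atlas, STRUCTURE_TYPE)])
        kb.extend_relation_class(MAPPING_CLASS, (atlas, STRUCTURE_TYPE))
        rels.append(kb.relate(MAPPING_CLASS, entry, structure))
        if "ontology" in mapping.columns and not pd.isna(row.get("ontology")):
            onto, tid = str(row["ontology"]), str(row["term_id"])
            if onto not in kb.types:
                raise KBError(f"unknown ontology {onto!r} in mapping table")
            term = kb.get_instance(onto, tid)
            kb.extend_relation_class(MAPPING_CLASS, (STRUCTURE_TYPE, onto))
            rels.append(kb.relate(MAPPING_CLASS, structure, term))
    return rels


def coordinate_terms(
    kb: KnowledgeBase,
    coordinate: Instance,
    atlas: str,
    ontology: str,
) -> set[str]:
    """Resolve a coordinate to ontology term ids through the mapping chain
    coordinate -> atlas entry -> brain structure -> ontology term.
    Returns the (possibly empty) set of term ids reached.
    """
    terms: set[str] = set()
    for entry in kb.neighbors(coordinate, "belongs to"):
        if entry.type_name != atlas:
            continue
        for structure in kb.neighbors(entry, "maps to"):
            if structure.type_name != STRUCTURE_TYPE:
                continue
            for term in kb.neighbors(structure, "maps to"):
                if term.type_name == ontology:
                    terms.add(term.identifier)
    return terms


def coordinate_atlas_labels(kb: KnowledgeBase, coordinate: Instance, atlas: str
                            ) -> list[str]:
    """Labels of the atlas entries a coordinate belongs to (sorted)."""
    labels = []
    for entry in kb.neighbors(coordinate, "belongs to"):
        if entry.type_name == atlas:
            labels.append(entry.labels[0] if entry.labels else entry.identifier)
    return sorted(labels)


def audit_parcellation_frames(kb: KnowledgeBase) -> None:
    """No parcellation relation may cross coordinate frames: all source
    coordinates of the class must share one frame."""
    frames = set()
    for rel in kb.relations_of_class(PARCELLATION_CLASS):
        frames.add(rel.source.props.get("frame"))
    if len(frames) > 1:
        raise DataError(f"parcellation relations cross frames: {sorted(frames)}")
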