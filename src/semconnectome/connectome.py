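"""Connectivity-matrix import, functional-brain-network templates,
functional classification and lattice-graph export.

A connectivity matrix (DTI fiber densities or rs-fMRI correlations over a
parcellation) becomes a set of *measured brain connectivity* relations
between coordinate objects, with the per-modality strengths stored as data
entries of a relation-subject experiment.  Because the relation — not the
matrix cell — is the carrier, re-importing a second modality on the same
coordinates adds measurements to the *same* connections, which is what
makes cross-modal joins a graph traversal instead of a matrix alignment
problem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from io import StringIO
from typing import Any, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import atlas_ontology as ao
from .experiments import (
    add_data_entry,
    create_experiment,
    ensure_experiment_method,
    get_entry,
)
from .kgcore import (
    DataError,
    Instance,
    KBError,
    KnowledgeBase,
    RelationInstance,
    ValidationError,
    logger,
)

__all__ = [
    "CONNECTIVITY_CLASS",
    "FunctionalCategory",
    "ConnectionRecord",
    "import_connectivity_matrix",
    "read_matrix_file",
    "read_region_file",
    "extract_fbn",
    "classify_functional",
    "export_lattice",
    "records_to_frame",
    "write_records_tsv",
    "read_records_tsv",
]

CONNECTIVITY_CLASS = "measured brain connectivity"
FORWARD_LABEL = "connects to"
BACKWARD_LABEL = "is connected from"

#: formats whose exact-zero cells are informative (an uncorrelated pair is
#: still a measurement) versus formats where zero means "no tract".
_ZERO_KEEP_FORMATS = {"normalized correlation value", "absolute correlation value"}

SYMMETRY_TOL = 1e-9


class FunctionalCategory(Enum):
    """Discretization of functional connectivity used for edge coloring:
    correlated activity (>= 0.5), uncorrelated ([0, 0.5)) and
    anticorrelated (< 0)."""

    CORRELATED = "correlated"
    UNCORRELATED = "uncorrelated"
    ANTICORRELATED = "anticorrelated"


def classify_functional(value: float) -> FunctionalCategory:
    """Bin a correlation value; the three bins partition [-1, 1] with the
    closed bounds exactly as printed (>= 0.5 correlated, < 0
    anticorrelated)."""
    if not -1.0 <= value <= 1.0:
        raise ValidationError(f"functional connectivity {value!r} outside [-1, 1]")
    if value >= 0.5:
        return FunctionalCategory.CORRELATED
    if value < 0.0:
        return FunctionalCategory.ANTICORRELATED
    return FunctionalCategory.UNCORRELATED


@dataclass
class ConnectionRecord:
    """One connection between two brain structures with whatever modality
    values are available — the row type of the joined connectivity /
    differential-expression tables."""

    origin: str
    target: str
    structural: Optional[float] = None
    functional: Optional[float] = None
    deg_average: Optional[float] = None
    n_subpairs: int = 0
    origin_coord: Optional[str] = None
    target_coord: Optional[str] = None
    origin_xyz: Optional[tuple[float, float, float]] = None
    target_xyz: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.structural is None and self.functional is None \
                and self.deg_average is None:
            raise ValidationError(
                f"record {self.origin!r}->{self.target!r} carries no modality value")


# ---------------------------------------------------------------------------
# Matrix import
# ---------------------------------------------------------------------------

def read_matrix_file(path: str) -> np.ndarray:
    """Read an n x n connectivity matrix (whitespace- or comma-separated,
    USC Multimodal Connectivity Database style)."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    delim = "," if "," in text.splitlines()[0] else None
    mat = np.loadtxt(StringIO(text), delimiter=delim)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise DataError(f"matrix file {path!r} is not square: {mat.shape}")
    return mat


def read_region_file(path: str) -> pd.DataFrame:
    """Read a region file with one ``label x y z`` line per matrix row
    (MNI millimetres); returns columns label, x, y, z."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 4:
                raise DataError(f"region line lacks label + 3 coordinates: {line!r}")
            label = " ".join(parts[:-3])
            x, y, z = (float(v) for v in parts[-3:])
            rows.append((label, x, y, z))
    return pd.DataFrame(rows, columns=["label", "x", "y", "z"])


def default_coordinate_ids(labels: Sequence[str]) -> list[str]:
    """Stable coordinate identifiers: zero-padded row index + region label,
    so the canonical (ascending-identifier) edge direction follows the
    original row order."""
    return [f"{i:03d} {lab}" for i, lab in enumerate(labels)]


def import_connectivity_matrix(
    kb: KnowledgeBase,
    values: np.ndarray,
    labels: Sequence[str],
    coordinates: pd.DataFrame,
    method: str,
    format_name: str,
    experiment_name: Optional[str] = None,
    symmetric: bool = True,
    zero_policy: Optional[str] = None,
    frame: str = ao.DEFAULT_FRAME,
    coordinate_ids: Optional[Sequence[str]] = None,
) -> tuple[Any, int, int]:
    """Import one connectivity matrix as relations plus data entries.

    ``coordinates`` holds x, y, z per row (same order as the matrix).  For
    a symmetric matrix each unordered pair i < j becomes one directed
    relation with the canonical direction given by ascending coordinate
    identifier; asymmetric matrices keep both ordered directions.
    Diagonal cells are always dropped.  ``zero_policy`` ("keep"/"drop")
    controls exact-zero cells; the default keeps zeros for correlation
    formats and drops them for fiber densities, so an absent tract is an
    absent entry rather than a zero.

    Returns (experiment, n relations newly created, n entries stored).
    """
    values = np.asarray(values, dtype=float)
    n = len(labels)
    if values.shape != (n, n):
        raise DataError(
            f"matrix shape {values.shape} does not match {n} region labels")
    if len(coordinates) != n:
        raise DataError(
            f"{len(coordinates)} coordinate rows for {n} regions")
    if symmetric and not np.allclose(values, values.T, atol=SYMMETRY_TOL, rtol=0.0):
        raise DataError("matrix declared symmetric but is not (tolerance 1e-9)")
    if zero_policy is None:
        zero_policy = "keep" if format_name in _ZERO_KEEP_FORMATS else "drop"
    if zero_policy not in ("keep", "drop"):
        raise DataError(f"unknown zero_policy {zero_policy!r}")

    if coordinate_ids is None:
        coordinate_ids = default_coordinate_ids(labels)
    coords = [
        ao.ensure_coordinate(kb, cid, row["x"], row["y"], row["z"], frame, [lab])
        for cid, lab, (_, row) in zip(coordinate_ids, labels, coordinates.iterrows())
    ]
    frames = {c.props["frame"] for c in coords}
    if frames != {frame}:
        raise DataError(f"coordinates span frames {sorted(frames)}, expected {frame!r}")

    if CONNECTIVITY_CLASS not in kb.relation_classes:
        kb.define_relation_class(
            CONNECTIVITY_CLASS, FORWARD_LABEL, BACKWARD_LABEL,
            [(ao.COORDINATE_TYPE, ao.COORDINATE_TYPE)])
    ensure_experiment_method(kb, method, ("relation_class", CONNECTIVITY_CLASS),
                             [format_name])
    experiment = create_experiment(
        kb, method, experiment_name or f"{method} import",
        {"format": format_name, "n_regions": n, "frame": frame})

    if symmetric:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        pairs = [(i, j) for i in range(n) for j in range(n) if i != j]

    n_new_rel = 0
    n_entries = 0
    for i, j in pairs:
        v = values[i, j]
        if v == 0.0 and zero_policy == "drop":
            continue
        a, b = coords[i], coords[j]
        if symmetric and b.identifier < a.identifier:
            a, b = b, a  # canonical direction: ascending coordinate id
        before = ("R", CONNECTIVITY_CLASS, a.key, b.key) in kb.relations
        rel = kb.relate(CONNECTIVITY_CLASS, a, b)
        if not before:
            n_new_rel += 1
        add_data_entry(kb, experiment, rel, format_name, float(v))
        n_entries += 1
    return experiment, n_new_rel, n_entries


# ---------------------------------------------------------------------------
# FBN template extraction
# ---------------------------------------------------------------------------

def _relation_values(kb: KnowledgeBase, rel: RelationInstance
                     ) -> tuple[Optional[float], Optional[float]]:
    """(structural, functional) values attached to a connectivity relation,
    scanning every relation-subject method; first experiment wins when a
    modality was imported more than once."""
    structural = functional = None
    for mname in sorted(kb.methods):
        mdef = kb.methods[mname]
        if mdef.subject.name != CONNECTIVITY_CLASS:
            continue
        for (m, ename) in sorted(kb.experiments):
            if m != mname:
                continue
            for fname in sorted(mdef.formats):
                e = get_entry(kb, mname, ename, rel, fname)
                if e is None:
                    continue
                v = e.values.get("value")
                if fname in _ZERO_KEEP_FORMATS:
                    if functional is None:
                        functional = v
                elif structural is None:
                    structural = v
    return structural, functional


def _endpoint_record_fields(kb: KnowledgeBase, coord: Instance, atlas: str
                            ) -> tuple[str, str, tuple[float, float, float]]:
    labels = ao.coordinate_atlas_labels(kb, coord, atlas)
    label = labels[0] if labels else (coord.labels[0] if coord.labels
                                      else coord.identifier)
    xyz = (coord.props.get("x"), coord.props.get("y"), coord.props.get("z"))
    return label, coord.identifier, xyz


def extract_fbn(
    kb: KnowledgeBase,
    ontology: str,
    root_term: str,
    atlas: str,
    include_self: bool = True,
) -> list[ConnectionRecord]:
    """Extract a functional-brain-network template: every measured brain
    connectivity relation whose *both* endpoints resolve — coordinate ->
    atlas entry -> brain structure -> ontology term — to a term inside the
    is-a closure of ``root_term``.  Records carry origin/target atlas
    labels, coordinates, and whatever structural/functional values were
    imported."""
    allowed = ao.ontology_descendants(kb, ontology, root_term,
                                      include_self=include_self)
    records: list[ConnectionRecord] = []
    for rel in kb.relations_of_class(CONNECTIVITY_CLASS):
        src, tgt = rel.source, rel.target
        if not isinstance(src, Instance):
            continue
        src_terms = ao.coordinate_terms(kb, src, atlas, ontology)
        tgt_terms = ao.coordinate_terms(kb, tgt, atlas, ontology)
        if not (src_terms & allowed) or not (tgt_terms & allowed):
            continue
        structural, functional = _relation_values(kb, rel)
        if structural is None and functional is None:
            continue
        o_label, o_id, o_xyz = _endpoint_record_fields(kb, src, atlas)
        t_label, t_id, t_xyz = _endpoint_record_fields(kb, tgt, atlas)
        records.append(ConnectionRecord(
            origin=o_label, target=t_label,
            structural=structural, functional=functional,
            origin_coord=o_id, target_coord=t_id,
            origin_xyz=o_xyz, target_xyz=t_xyz))
    return records


# ---------------------------------------------------------------------------
# Lattice-graph export
# ---------------------------------------------------------------------------

def build_lattice(records: Sequence[ConnectionRecord],
                  edge_color_by: str = "functional") -> nx.Graph:
    """Build the styled lattice graph: nodes are coordinates positioned at
    MNI millimetres, edge width is structural connectivity and edge color
    functional connectivity or differential gene expression."""
    if edge_color_by not in ("functional", "deg"):
        raise DataError(f"edge_color_by must be 'functional' or 'deg'")
    g = nx.Graph()
    for rec in sorted(records, key=lambda r: (r.origin_coord or r.origin,
                                              r.target_coord or r.target)):
        if rec.origin_xyz is None or rec.target_xyz is None or \
                rec.origin_coord is None or rec.target_coord is None:
            raise DataError(
                f"record {rec.origin!r}->{rec.target!r} lacks coordinates")
        for cid, label, xyz in ((rec.origin_coord, rec.origin, rec.origin_xyz),
                                (rec.target_coord, rec.target, rec.target_xyz)):
            if cid not in g:
                g.add_node(cid, label=label,
                           x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]))
        attrs: dict[str, Any] = {"width": float(rec.structural or 0.0)}
        color = rec.functional if edge_color_by == "functional" else rec.deg_average
        if color is not None:
            attrs["color_value"] = float(color)
        if edge_color_by == "functional" and rec.functional is not None:
            attrs["color_category"] = classify_functional(rec.functional).value
        g.add_edge(rec.origin_coord, rec.target_coord, **attrs)
    return g


def export_lattice(
    records: Sequence[ConnectionRecord],
    path: str,
    edge_color_by: str = "functional",
    fmt: Optional[str] = None,
) -> nx.Graph:
    """Write the lattice graph as GraphML or a JSON node-link document.

    Node and edge order is sorted, so re-export of the same records is
    byte-identical.
    """
    g = build_lattice(records, edge_color_by)
    if fmt is None:
        fmt = "json" if str(path).endswith(".json") else "graphml"
    if fmt == "graphml":
        nx.write_graphml(g, path, infer_numeric_types=True)
    elif fmt == "json":
        doc = {
            "directed": False,
            "nodes": [{"id": n, **g.nodes[n]} for n in sorted(g.nodes)],
            "edges": [{"source": u, "target": v, **g.edges[u, v]}
                      for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges))],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise DataError(f"unknown graph format {fmt!r}")
    return g


# ---------------------------------------------------------------------------
# Record table I/O (shared with the cross-modal join)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "origin", "target", "normalized structural connectivity",
    "functional connectivity", "deg average", "n_subpairs",
    "origin_coord", "target_coord",
    "origin_x", "origin_y", "origin_z", "target_x", "target_y", "target_z",
]


def records_to_frame(records: Sequence[ConnectionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        o_xyz = r.origin_xyz or (None, None, None)
        t_xyz = r.target_xyz or (None, None, None)
        rows.append([r.origin, r.target, r.structural, r.functional,
                     r.deg_average, r.n_subpairs, r.origin_coord, r.target_coord,
                     *o_xyz, *t_xyz])
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_records_tsv(records: Sequence[ConnectionRecord], path: str) -> int:
    frame = records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False)
    return len(frame)


def read_records_tsv(path: str) -> list[ConnectionRecord]:
    frame = pd.read_csv(path, sep="\t")
    records = []

    def opt(row: pd.Series, col: str) -> Optional[float]:
        v = row.get(col)
        return None if v is None or pd.isna(v) else float(v)

    for _, row in frame.iterrows():
        o_xyz = tuple(opt(row, c) for c in ("origin_x", "origin_y", "origin_z"))
        t_xyz = tuple(opt(row, c) for c in ("target_x", "target_y", "target_z"))
        records.append(ConnectionRecord(
            origin=str(row["origin"]), target=str(row["target"]),
            structural=opt(row, "normalized structural connectivity"),
            functional=opt(row, "functional connectivity"),
            deg_average=opt(row, "deg average"),
            n_subpairs=int(row["n_subpairs"]) if "n_subpairs" in row and
            not pd.isna(row.get("n_subpairs")) else 0,
            origin_coord=None if pd.isna(row.get("origin_coord"))
            else str(row["origin_coord"]),
            target_coord=None if pd.isna(row.get("target_coord"))
            else str(row["target_coord"]),
            origin_xyz=None if any(v is None for v in o_xyz) else o_xyz,
            target_xyz=None if any(v is None for v in t_xyz) else t_xyz,
        ))
    return records
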