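"""Gene expression, differential-expression links and the cross-modal
connectome x transcriptome join.

Expression values enter as probe-level measurements (donor, location,
probe, value, PACall validity flag); each (donor, location) pair becomes
one experiment with the probe as subject, and probes relate to genes via
"is detected by" / "binds to".  Differential expression is consumed
pre-computed as counts of differentially expressed genes (DEG) between
pairs of brain structures.

The join walks every measured brain connection, resolves both endpoints to
ontology terms through the parcellation/mapping chain, expands each term
into its is-a descendants (connectivity is measured between coarse
parcels, DEG between fine structures — without the expansion the join is
empty), and averages the DEG counts over all matched descendant structure
pairs.
"""

from __future__ import annotations

from typing import Any, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import atlas_ontology as ao
from .connectome import (
    CONNECTIVITY_CLASS,
    ConnectionRecord,
    _endpoint_record_fields,
    _relation_values,
)
from .experiments import (
    add_data_entry,
    create_experiment,
    ensure_experiment_method,
    entries_for_subject,
)
from .kgcore import (
    DataError,
    Instance,
    KBError,
    KnowledgeBase,
    ObjectKind,
    logger,
)

__all__ = [
    "PROBE_TYPE",
    "DNA_TYPE",
    "EXPRESSION_METHOD",
    "import_expression",
    "import_deg",
    "deg_lookup",
    "localized_expression",
    "crossmodal_join",
    "filter_connections",
]

PROBE_TYPE = "probe"
DNA_TYPE = "DNA"
DNA_PROBE_CLASS = "DNA to probe"
DNA_PROBE_FORWARD = "is detected by"   # DNA -> probe
DNA_PROBE_BACKWARD = "binds to"        # probe -> DNA
EXPRESSION_METHOD = "gene expression"
DEG_CLASS = "differential expression of genes"

_EXPRESSION_COLUMNS = ("donor", "structure_id", "probe_id", "gene_symbol",
                       "expression", "pacall")


def _split_genes(cell: Any) -> list[str]:
    genes = [g.strip() for g in str(cell).replace(";", ",").split(",")]
    genes = [g for g in genes if g]
    if not genes:
        raise DataError(f"probe row without gene symbol: {cell!r}")
    return genes


def import_expression(
    kb: KnowledgeBase,
    table: pd.DataFrame,
    method: str = EXPRESSION_METHOD,
) -> tuple[list, int]:
    """Import a probe-level expression table (Allen microarray style).

    Required columns: donor, structure_id, probe_id, gene_symbol,
    expression, pacall; optional mni_x/mni_y/mni_z.  One experiment is
    created per (donor, structure) location, one "expression level" entry
    per probe, and probe -> gene relations are created ("is detected by" /
    "binds to").  Returns (experiments, number of entries).
    """
    for col in _EXPRESSION_COLUMNS:
        if col not in table.columns:
            raise DataError(f"expression table lacks column {col!r}")
    bad = set(table["pacall"]) - {0, 1}
    if bad:
        raise DataError(f"PACall values outside {{0, 1}}: {sorted(bad)}")

    kb.ensure_object_type(PROBE_TYPE, ObjectKind.ELEMENT)
    kb.ensure_object_type(DNA_TYPE, ObjectKind.CONTEXT)
    if DNA_PROBE_CLASS not in kb.relation_classes:
        kb.define_relation_class(DNA_PROBE_CLASS, DNA_PROBE_FORWARD,
                                 DNA_PROBE_BACKWARD, [(DNA_TYPE, PROBE_TYPE)])
    ensure_experiment_method(kb, method, ("object_type", PROBE_TYPE),
                             ["expression level"])

    has_xyz = {"mni_x", "mni_y", "mni_z"}.issubset(table.columns)
    experiments = []
    n_entries = 0
    for (donor, structure), group in table.groupby(
            ["donor", "structure_id"], sort=True):
        meta: dict[str, Any] = {"donor": str(donor), "structure_id": str(structure)}
        if has_xyz:
            first = group.iloc[0]
            meta.update(mni_x=float(first["mni_x"]), mni_y=float(first["mni_y"]),
                        mni_z=float(first["mni_z"]))
        exp = create_experiment(kb, method, f"{donor}|{structure}", meta)
        experiments.append(exp)
        for _, row in group.iterrows():
            probe = kb.ensure_instance(PROBE_TYPE, str(row["probe_id"]))
            for gene in _split_genes(row["gene_symbol"]):
                dna = kb.ensure_instance(DNA_TYPE, gene, [gene])
                kb.relate(DNA_PROBE_CLASS, dna, probe)
            add_data_entry(kb, exp, probe, "expression level",
                           {"value": float(row["expression"]),
                            "pacall": int(row["pacall"])})
            n_entries += 1
    return experiments, n_entries


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _structure_exists(kb: KnowledgeBase, sid: str, ontology: Optional[str]) -> bool:
    if ontology is not None:
        return kb.has_instance(ontology, sid)
    if kb.has_instance(ao.STRUCTURE_TYPE, sid):
        return True
    for tname, tdef in kb.types.items():
        if tdef.kind is ObjectKind.ONTOLOGY and kb.has_instance(tname, sid):
            return True
    return False


def import_deg(
    kb: KnowledgeBase,
    table: pd.DataFrame,
    ontology: Optional[str] = None,
) -> int:
    """Import a pre-computed differential-expression pair table with
    columns structure_a, structure_b, deg_count.  Pairs are unordered:
    querying (B, A) returns the (A, B) count.  Conflicting duplicates
    raise; identical duplicates are idempotent.  Returns pairs stored.
    """
    for col in ("structure_a", "structure_b", "deg_count"):
        if col not in table.columns:
            raise DataError(f"DEG table lacks column {col!r}")
    n = 0
    for _, row in table.iterrows():
        a, b = str(row["structure_a"]), str(row["structure_b"])
        count = row["deg_count"]
        if count < 0 or int(count) != count:
            raise DataError(f"DEG count for ({a!r}, {b!r}) must be a "
                            f"non-negative integer, got {count!r}")
        for sid in (a, b):
            if not _structure_exists(kb, sid, ontology):
                raise KBError(f"unknown structure {sid!r} in DEG table")
        key = tuple(sorted((a, b)))
        if key in kb.deg_links:
            if kb.deg_links[key] != int(count):
                raise DataError(
                    f"conflicting DEG counts for pair {key}: "
                    f"{kb.deg_links[key]} vs {int(count)}")
            continue
        kb.deg_links[key] = int(count)
        n += 1
    return n


def deg_lookup(kb: KnowledgeBase, a: str, b: str) -> Optional[int]:
    """Symmetric lookup of the DEG count for a structure pair."""
    return kb.deg_links.get(tuple(sorted((str(a), str(b)))))


# ---------------------------------------------------------------------------
# Localized expression filters
# ---------------------------------------------------------------------------

def localized_expression(
    kb: KnowledgeBase,
    gene: str,
    min_value: float = 8.0,
    require_pacall: bool = True,
    method: str = EXPRESSION_METHOD,
) -> pd.DataFrame:
    """Probe/location records for a gene with expression strictly greater
    than ``min_value`` and, by default, a signal significantly above
    background (PACall = 1), sorted by value descending.

    Columns: gene, probe, donor, structure_id, value, pacall (plus MNI
    coordinates when the experiments carry them).
    """
    if not kb.has_instance(DNA_TYPE, gene):
        raise KBError(f"unknown gene {gene!r}")
    dna = kb.get_instance(DNA_TYPE, gene)
    rows = []
    for probe in kb.neighbors(dna, DNA_PROBE_FORWARD):
        for e in entries_for_subject(kb, probe, method):
            value = e.values.get("value")
            pacall = e.values.get("pacall")
            if value is None or value <= min_value:
                continue
            if require_pacall and pacall != 1:
                continue
            meta = kb.experiments[(e.method_name, e.experiment_name)].metadata
            rows.append({
                "gene": gene, "probe": probe.identifier,
                "donor": meta.get("donor"),
                "structure_id": meta.get("structure_id"),
                "value": value, "pacall": pacall,
                **{k: meta[k] for k in ("mni_x", "mni_y", "mni_z") if k in meta},
            })
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(
            ["value", "structure_id", "probe"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# Cross-modal join
# ---------------------------------------------------------------------------

def crossmodal_join(
    kb: KnowledgeBase,
    ontology: str,
    atlas: str,
    include_self: bool = True,
) -> list[ConnectionRecord]:
    """Join every measured brain connection with differential expression.

    Each connectivity relation's endpoints are resolved to ontology terms
    O and T; DEG links with one structure in descendants(O) and the other
    in descendants(T) (``include_self`` keeps the terms themselves) are
    collected, each unordered structure pair once, and averaged.
    Connections without any matched DEG pair are excluded; endpoints with
    no mapping chain are skipped with a warning.  One output record per
    connectivity relation — coordinates sharing atlas labels yield
    duplicate label rows by design.
    """
    if ontology not in kb.ontologies:
        raise KBError(f"unknown ontology {ontology!r}")
    desc_cache: dict[str, set[str]] = {}

    def expand(terms: set[str]) -> set[str]:
        out: set[str] = set()
        for t in terms:
            if t not in desc_cache:
                desc_cache[t] = ao.ontology_descendants(
                    kb, ontology, t, include_self=include_self)
            out |= desc_cache[t]
        return out

    records: list[ConnectionRecord] = []
    for rel in kb.relations_of_class(CONNECTIVITY_CLASS):
        src, tgt = rel.source, rel.target
        if not isinstance(src, Instance):
            continue
        src_terms = ao.coordinate_terms(kb, src, atlas, ontology)
        tgt_terms = ao.coordinate_terms(kb, tgt, atlas, ontology)
        if not src_terms or not tgt_terms:
            logger.warning("crossmodal_join: no mapping chain for endpoint of "
                           "%s -> %s; skipped", src.identifier, tgt.identifier)
            continue
        desc_o, desc_t = expand(src_terms), expand(tgt_terms)
        counts = [
            c for (a, b), c in kb.deg_links.items()
            if (a in desc_o and b in desc_t) or (a in desc_t and b in desc_o)
        ]
        if not counts:
            continue
        structural, functional = _relation_values(kb, rel)
        o_label, o_id, o_xyz = _endpoint_record_fields(kb, src, atlas)
        t_label, t_id, t_xyz = _endpoint_record_fields(kb, tgt, atlas)
        records.append(ConnectionRecord(
            origin=o_label, target=t_label,
            structural=structural, functional=functional,
            deg_average=float(np.mean(counts)), n_subpairs=len(counts),
            origin_coord=o_id, target_coord=t_id,
            origin_xyz=o_xyz, target_xyz=t_xyz))
    return records


def filter_connections(
    records: Sequence[ConnectionRecord],
    min_struct: Optional[float] = None,
    min_func: Optional[float] = None,
    max_deg: Optional[float] = None,
    min_deg: Optional[float] = None,
) -> list[ConnectionRecord]:
    """Threshold connection records, preserving order.

    Comparisons follow the printed inequalities exactly: structural and
    functional thresholds and ``max_deg`` are inclusive (>=, <=) while
    ``min_deg`` is strict (> 200 selects "more than 200").  A record
    lacking a thresholded field fails that threshold.
    """
    out = []
    for r in records:
        if min_struct is not None and (r.structural is None
                                       or r.structural < min_struct):
            continue
        if min_func is not None and (r.functional is None
                                     or r.functional < min_func):
            continue
        if max_deg is not None and (r.deg_average is None
                                    or r.deg_average > max_deg):
            continue
        if min_deg is not None and (r.deg_average is None
                                    or r.deg_average <= min_deg):
            continue
        out.append(r)
    return out
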