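"""Matrix import, functional classification, FBN extraction, lattice
export."""

import numpy as np
import pandas as pd
import pytest

import semconnectome.atlas_ontology as ao
import semconnectome.connectome as conn
from semconnectome.kgcore import DataError, KnowledgeBase, ValidationError


def coords_frame(n, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(rng.uniform(-60, 60, size=(n, 3)),
                        columns=["x", "y", "z"])


class TestClassifyFunctional:
    @pytest.mark.parametrize("value, expected", [
        # printed connectivity values from the published tables
        (0.73615919, conn.FunctionalCategory.CORRELATED),
        (-0.01262453, conn.FunctionalCategory.ANTICORRELATED),
        (0.020203011, conn.FunctionalCategory.UNCORRELATED),
        # boundary behaviour: closed bounds exactly as printed
        (0.5, conn.FunctionalCategory.CORRELATED),
        (0.0, conn.FunctionalCategory.UNCORRELATED),
        (-1.0, conn.FunctionalCategory.ANTICORRELATED),
        (1.0, conn.FunctionalCategory.CORRELATED),
    ])
    def test_binning(self, value, expected):
        assert conn.classify_functional(value) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            conn.classify_functional(1.0001)

    def test_bins_partition_interval(self):
        """Every admissible value maps to exactly one category."""
        rng = np.random.default_rng(99)
        values = rng.uniform(-1, 1, size=10_000)
        for v in values:
            cats = [c for c in conn.FunctionalCategory
                    if conn.classify_functional(v) is c]
            assert len(cats) == 1


class TestMatrixImport:
    def symmetric3(self):
        m = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, -0.2],
                      [0.5, -0.2, 0.0]])
        return m

    def test_symmetric_counts(self):
        kb = KnowledgeBase()
        _, n_rel, n_ent = conn.import_connectivity_matrix(
            kb, self.symmetric3(), ["a", "b", "c"], coords_frame(3),
            "rs-fMRI", "normalized correlation value")
        assert n_rel == 3 and n_ent == 3

    def test_asymmetric_counts(self):
        kb = KnowledgeBase()
        m = self.symmetric3().copy()
        m[0, 1] = 0.9
        _, n_rel, n_ent = conn.import_connectivity_matrix(
            kb, m, ["a", "b", "c"], coords_frame(3),
            "rs-fMRI", "normalized correlation value", symmetric=False)
        assert n_rel == 6 and n_ent == 6

    def test_symmetry_violation_rejected(self):
        kb = KnowledgeBase()
        m = self.symmetric3()
        m[0, 1] += 1e-6
        with pytest.raises(DataError):
            conn.import_connectivity_matrix(
                kb, m, ["a", "b", "c"], coords_frame(3),
                "rs-fMRI", "normalized correlation value")

    def test_second_modality_shares_relations(self):
        """Re-importing another modality on the same coordinates adds
        entries but no new relations."""
        kb = KnowledgeBase()
        coords = coords_frame(4)
        s = np.abs(np.random.default_rng(1).uniform(0.1, 1, (4, 4)))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0)
        labels = list("abcd")
        ids = conn.default_coordinate_ids(labels)
        conn.import_connectivity_matrix(kb, s, labels, coords, "DTI",
                                        "normalized fiber density",
                                        coordinate_ids=ids)
        f = np.clip(s - 0.2, -1, 1)
        np.fill_diagonal(f, 0)
        _, n_rel, n_ent = conn.import_connectivity_matrix(
            kb, f, labels, coords, "rs-fMRI",
            "normalized correlation value", coordinate_ids=ids)
        assert n_rel == 0 and n_ent == 6

    def test_zero_policy_drop_vs_keep(self):
        m = np.array([[0.0, 0.0], [0.0, 0.0]])
        for policy, expected in (("keep", 1), ("drop", 0)):
            kb = KnowledgeBase()
            _, n_rel, n_ent = conn.import_connectivity_matrix(
                kb, m, ["a", "b"], coords_frame(2), "rs-fMRI",
                "normalized correlation value", zero_policy=policy)
            assert n_ent == expected

    def test_default_zero_policy_by_modality(self):
        """Zeros are kept for correlations, dropped for fiber density."""
        m = np.array([[0.0, 0.0], [0.0, 0.0]])
        kb = KnowledgeBase()
        _, _, n_func = conn.import_connectivity_matrix(
            kb, m, ["a", "b"], coords_frame(2), "rs-fMRI",
            "normalized correlation value")
        kb2 = KnowledgeBase()
        _, _, n_struct = conn.import_connectivity_matrix(
            kb2, m, ["a", "b"], coords_frame(2), "DTI",
            "normalized fiber density")
        assert (n_func, n_struct) == (1, 0)

    def test_permutation_invariance(self):
        """Permuting matrix rows/columns together with their labels and
        coordinates yields the same relation and entry set."""
        rng = np.random.default_rng(8)
        n = 5
        m = rng.uniform(0.01, 1, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"r{i}" for i in range(n)]
        coords = coords_frame(n, rng)
        ids = [f"c{i}" for i in range(n)]

        def imported(order):
            kb = KnowledgeBase()
            conn.import_connectivity_matrix(
                kb, m[np.ix_(order, order)], [labels[i] for i in order],
                coords.iloc[list(order)].reset_index(drop=True),
                "DTI", "normalized fiber density",
                coordinate_ids=[ids[i] for i in order])
            rels = sorted(kb.relations)
            entries = sorted((k, kb.entries[k].values["value"])
                             for k in kb.entries)
            return rels, entries

        perm = list(rng.permutation(n))
        assert imported(list(range(n))) == imported(perm)

    def test_dimension_mismatch_rejected(self):
        kb = KnowledgeBase()
        with pytest.raises(DataError):
            conn.import_connectivity_matrix(
                kb, self.symmetric3(), ["a", "b"], coords_frame(2),
                "rs-fMRI", "normalized correlation value")


def limbic_style_kb():
    """Four coordinates: three mapped under a 'limbic' term, one outside;
    fully connected functional matrix."""
    kb = KnowledgeBase()
    n = 4
    rng = np.random.default_rng(0)
    m = rng.uniform(0.1, 0.9, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    labels = ["hippocampus", "amygdala", "cingulate", "precentral"]
    ids = conn.default_coordinate_ids(labels)
    conn.import_connectivity_matrix(kb, m, labels, coords_frame(n), "rs-fMRI",
                                    "normalized correlation value",
                                    coordinate_ids=ids)
    ao.load_flat_atlas(kb, "atlas", pd.DataFrame(
        {"entry_id": [f"e{i}" for i in range(n)], "label": labels}))
    terms = pd.DataFrame({
        "term_id": ["root", "limbic", "motor", "hip", "amy", "cin", "pre"],
        "name": ["brain", "limbic lobe", "motor", "hippocampus", "amygdala",
                 "cingulate", "precentral"]})
    edges = pd.DataFrame({
        "child_id": ["limbic", "motor", "hip", "amy", "cin", "pre"],
        "parent_id": ["root", "root", "limbic", "limbic", "limbic", "motor"]})
    ao.load_ontology(kb, "onto", terms, edges)
    ao.parcellate_coordinates(
        kb, ids, {ids[i]: f"e{i}" for i in range(n)}, "atlas")
    ao.register_brain_mapping(kb, pd.DataFrame({
        "atlas": "atlas", "entry_id": [f"e{i}" for i in range(n)],
        "structure_name": labels, "ontology": "onto",
        "term_id": ["hip", "amy", "cin", "pre"]}))
    return kb, ids


class TestExtractFbn:
    def test_limbic_subnetwork(self):
        kb, ids = limbic_style_kb()
        records = conn.extract_fbn(kb, "onto", "limbic", "atlas")
        # three limbic coordinates fully connected -> 3 pairs
        assert len(records) == 3
        members = {r.origin for r in records} | {r.target for r in records}
        assert members == {"hippocampus", "amygdala", "cingulate"}

    def test_root_with_no_mapped_structures_empty(self):
        kb, _ = limbic_style_kb()
        # 'motor' subtree has one coordinate -> no pairs fully inside it
        assert conn.extract_fbn(kb, "onto", "pre", "atlas") == []

    def test_matches_brute_force_pair_filter(self):
        """FBN pair set equals a nested-loop filter over all relations."""
        kb, ids = limbic_style_kb()
        records = conn.extract_fbn(kb, "onto", "limbic", "atlas")
        allowed = ao.ontology_descendants(kb, "onto", "limbic",
                                          include_self=True)
        expected = set()
        for rel in kb.relations_of_class(conn.CONNECTIVITY_CLASS):
            t_src = ao.coordinate_terms(kb, rel.source, "atlas", "onto")
            t_tgt = ao.coordinate_terms(kb, rel.target, "atlas", "onto")
            if t_src & allowed and t_tgt & allowed:
                expected.add((rel.source.identifier, rel.target.identifier))
        assert {(r.origin_coord, r.target_coord) for r in records} == expected

    def test_monotone_in_ontology(self):
        """The network under a term is contained in the network under any
        of its ancestors."""
        kb, _ = limbic_style_kb()
        sub = {(r.origin_coord, r.target_coord)
               for r in conn.extract_fbn(kb, "onto", "limbic", "atlas")}
        sup = {(r.origin_coord, r.target_coord)
               for r in conn.extract_fbn(kb, "onto", "root", "atlas")}
        assert sub <= sup


class TestLatticeExport:
    def records(self):
        kb, _ = limbic_style_kb()
        return conn.extract_fbn(kb, "onto", "root", "atlas")

    def test_attributes_populated(self, tmp_path):
        records = self.records()[:3]
        g = conn.export_lattice(records, str(tmp_path / "g.graphml"))
        assert g.number_of_edges() == 3
        assert g.number_of_nodes() <= 6
        for _, data in g.nodes(data=True):
            assert {"x", "y", "z"} <= set(data)
        for _, _, data in g.edges(data=True):
            assert "width" in data and "color_value" in data
            assert data["color_category"] in {"correlated", "uncorrelated",
                                              "anticorrelated"}

    def test_empty_record_set_valid_file(self, tmp_path):
        path = tmp_path / "empty.json"
        conn.export_lattice([], str(path), fmt="json")
        import json
        doc = json.loads(path.read_text())
        assert doc["nodes"] == [] and doc["edges"] == []

    def test_re_export_byte_identical(self, tmp_path):
        records = self.records()
        p1, p2 = tmp_path / "a.graphml", tmp_path / "b.graphml"
        conn.export_lattice(records, str(p1))
        conn.export_lattice(list(reversed(records)), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_coordinates_rejected(self, tmp_path):
        rec = conn.ConnectionRecord(origin="a", target="b", functional=0.1)
        with pytest.raises(DataError):
            conn.export_lattice([rec], str(tmp_path / "g.graphml"))


def test_records_tsv_round_trip(tmp_path):
    kb, _ = limbic_style_kb()
    records = conn.extract_fbn(kb, "onto", "root", "atlas")
    path = tmp_path / "records.tsv"
    conn.write_records_tsv(records, str(path))
    back = conn.read_records_tsv(str(path))
    assert [(r.origin, r.target, r.functional) for r in back] == \
        [(r.origin, r.target, pytest.approx(r.functional)) for r in records]


def test_matrix_and_region_file_readers(tmp_path):
    mat = tmp_path / "m.txt"
    mat.write_text("0 0.5\n0.5 0\n")
    m = conn.read_matrix_file(str(mat))
    assert m.shape == (2, 2) and m[0, 1] == 0.5
    reg = tmp_path / "r.txt"
    reg.write_text("left putamen -25 0 1\nright putamen 27 2 1\n")
    t = conn.read_region_file(str(reg))
    assert list(t["label"]) == ["left putamen", "right putamen"]
    assert t.loc[0, "x"] == -25
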