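import json

import pytest

from ontotab import annotation, fixtures
from ontotab.metrics import quality_tally
from ontotab.annotation import FULL, SearchConfig, categorize, search
from ontotab.fixtures import ConceptSpec, FixtureSpec
from ontotab.rdf_enhance import load_nquads
from ontotab.tabular_io import read_table


def _tiny_spec(n_rows=10, seed=0):
    return FixtureSpec(
        n_rows=n_rows,
        seed=seed,
        concepts=[
            ConceptSpec("gene_symbol", "symbol", 1, [("d1", "symbol"), ("d1", "Symbol")]),
            ConceptSpec("date", "date", 0, [("d1", "date modified")]),
        ],
    )


class TestGenerateTables:
    def test_shared_concept_columns_draw_from_one_pool(self):
        spec = _tiny_spec()
        by_ds = fixtures.generate_columns(spec)
        cols = {c.name: c for c in by_ds["d1"]}
        assert len(cols) == 3
        pool_a = set(cols["symbol"].values)
        pool_b = set(cols["Symbol"].values)
        assert pool_a & pool_b  # overlapping values from the shared pool
        assert not pool_a & set(cols["date modified"].values)

    def test_same_seed_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            fixtures.generate_tables(_tiny_spec(seed=5), tmp_path / sub)
        fa = sorted((tmp_path / "a").iterdir())
        fb = sorted((tmp_path / "b").iterdir())
        assert [p.name for p in fa] == [p.name for p in fb]
        for pa, pb in zip(fa, fb):
            assert pa.read_bytes() == pb.read_bytes()

    def test_written_tables_reparse(self, tmp_path):
        spec = _tiny_spec(n_rows=7)
        (path,) = fixtures.generate_tables(spec, tmp_path)
        profile, cols = read_table(path)
        assert profile.n_rows == 7
        assert profile.n_columns == 3

    def test_value_patterns(self):
        spec = FixtureSpec(
            n_rows=20,
            seed=1,
            concepts=[
                ConceptSpec("sym", "symbol", 1, [("d", "s")]),
                ConceptSpec("num", "numeric_id", 1, [("d", "n")]),
                ConceptSpec("dt", "date", 0, [("d", "t")]),
                ConceptSpec("coord", "coordinate", 0, [("d", "c")]),
            ],
        )
        cols = {c.name: c for c in fixtures.generate_columns(spec)["d"]}
        assert all(2 <= len(v) <= 6 and v[0].isalpha() and v.isupper() for v in cols["s"].values)
        assert all(v.isdigit() for v in cols["n"].values)
        assert all(len(v) == 10 and v[4] == v[7] == "-" for v in cols["t"].values)
        assert all(1_000 <= int(v) <= 250_000_000 for v in cols["c"].values)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FixtureSpec(concepts=[ConceptSpec("only_pos", "symbol", 1, [("d", "s")])])
        with pytest.raises(ValueError):
            FixtureSpec(
                concepts=[
                    ConceptSpec("a", "symbol", 1, [("d", "x")]),
                    ConceptSpec("b", "date", 0, [("e", "x")]),  # duplicate column name
                ]
            )

    def test_ground_truth_maps(self):
        spec = _tiny_spec()
        assert spec.class_labels() == {"symbol": 1, "Symbol": 1, "date modified": 0}
        assert spec.categories()["Symbol"] == "gene_symbol"


class TestMockOntology:
    def test_full_matchable_property_exists_for_positive_concepts(self, fixture_spec, mock_index_data):
        index = annotation.MockTermIndex(mock_index_data["terms"])
        for concept in fixture_spec.concepts:
            if concept.label != 1:
                continue
            for _, col in concept.columns:
                hits = [
                    categorize(m, col)
                    for m in search(index, col, SearchConfig(longest_match=True))
                ]
                assert any(
                    m.category == FULL and m.ontology_acronym == "GENEMOCK" for m in hits
                ), col

    def test_semi_matchable_term_exists(self, mock_index_data):
        index = annotation.MockTermIndex(mock_index_data["terms"])
        hits = [categorize(m, "hgnc id") for m in search(index, "hgnc id", SearchConfig())]
        assert any(m.category == "SEMI" for m in hits)

    def test_negative_concepts_have_no_full_match(self, fixture_spec, mock_index_data):
        index = annotation.MockTermIndex(mock_index_data["terms"])
        for concept in fixture_spec.concepts:
            if concept.label != 0:
                continue
            for _, col in concept.columns:
                hits = [categorize(m, col) for m in search(index, col, SearchConfig())]
                assert not any(m.category == FULL for m in hits), col

    def test_frequency_mode_selects_gene_ontology(self, fixture_spec, fixture_columns, mock_index_data):
        index = annotation.MockTermIndex(mock_index_data["terms"])
        matches = []
        for col in fixture_columns:
            matches.extend(search(index, col.name, SearchConfig()))
        freq = annotation.build_frequency(matches, "mode")
        assert "GENEMOCK" in freq.selected
        assert freq.counts["GENEMOCK"] == max(freq.counts.values())

    def test_json_round_trip(self, fixture_spec, tmp_path):
        path = tmp_path / "onto.json"
        data = fixtures.generate_mock_ontology(fixture_spec, path)
        assert json.loads(path.read_text()) == data


class TestGenericRdf:
    def test_quad_shape_contract(self, tmp_path):
        spec = _tiny_spec(n_rows=10)
        by_ds = fixtures.generate_columns(spec)
        path = fixtures.generate_generic_rdf(by_ds, tmp_path / "g.nq")
        ds, ov = load_nquads(path)
        quads = list(ds.quads((None, None, None, None)))
        assert len(quads) == 30 + 10  # data + type quads
        assert ov.n_instances == 10

    def test_deterministic_under_seed(self, tmp_path):
        for sub in ("a", "b"):
            spec = _tiny_spec(seed=9)
            by_ds = fixtures.generate_columns(spec)
            (tmp_path / sub).mkdir()
            fixtures.generate_generic_rdf(by_ds, tmp_path / sub / "g.nq")
        assert (tmp_path / "a/g.nq").read_bytes() == (tmp_path / "b/g.nq").read_bytes()

    def test_predicates_minted_from_column_names(self, tmp_path):
        spec = _tiny_spec(n_rows=2)
        by_ds = fixtures.generate_columns(spec)
        path = fixtures.generate_generic_rdf(by_ds, tmp_path / "g.nq")
        text = path.read_text()
        assert fixtures.generic_predicate("d1", "date modified") in text
        assert "date_modified" in fixtures.generic_predicate("d1", "date modified")


class TestEndToEndGroundTruth:
    def test_ut_count_equals_columns_without_full_matches(
        self, fixture_spec, fixture_columns, mock_index_data
    ):
        """Quality tally recovers the generator's ground truth."""
        index = annotation.MockTermIndex(mock_index_data["terms"])
        mapped = []
        for col in fixture_columns:
            hits = [categorize(m, col.name) for m in search(index, col.name, SearchConfig())]
            if annotation.select_property(hits) is not None:
                mapped.append(col.name)
        all_names = [c.name for c in fixture_columns]
        q = quality_tally(all_names, mapped)
        n_negative = sum(1 for c in fixture_spec.concepts if c.label == 0 for _ in c.columns)
        assert q.undefined_terminology == n_negative
        assert q.total_added_properties == len(all_names) - n_negative
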