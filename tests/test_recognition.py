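import itertools

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from ontotab import encoding, recognition
from ontotab.encoding import CONTINUOUS, PairDataset
from ontotab.recognition import (
    EmbeddingModel,
    EvalReport,
    TrainingConfig,
    UnknownIdError,
    column_similarity,
    evaluate,
    evaluate_repeated,
    precision_summary,
    top_similar,
    train_name_classifier,
    train_nne,
)


class TestNameClassifier:
    @pytest.fixture
    def clusters(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(30, 3, (50, 8)), rng.normal(90, 3, (50, 8))])
        y = np.array([0] * 50 + [1] * 50)
        return X, y

    def test_separable_clusters_learned(self, clusters):
        X, y = clusters
        # independent oracle: the clusters really are linearly separable
        oracle = LogisticRegression().fit(X, y)
        assert oracle.score(X, y) >= 0.95
        clf = train_name_classifier(X, y, TrainingConfig(seed=0))
        assert (clf.predict(X) == y).mean() >= 0.95

    def test_all_zero_vector_yields_valid_probability(self, clusters):
        X, y = clusters
        clf = train_name_classifier(X, y, TrainingConfig(seed=0))
        p = clf.predict_proba(np.zeros((1, 8)))
        assert 0.0 <= p[0] <= 1.0

    def test_wrong_width_rejected(self, clusters):
        X, y = clusters
        clf = train_name_classifier(X, y, TrainingConfig(seed=0))
        with pytest.raises(ValueError):
            clf.predict(np.zeros((1, 5)))

    def test_single_class_data_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError):
            train_name_classifier(X, np.ones(10, dtype=int))


def _tiny_model(column_embeddings):
    C = np.asarray(column_embeddings, dtype=float)
    return EmbeddingModel(
        column_embeddings=C,
        value_embeddings=np.zeros((1, C.shape[1])),
        dense_weight=1.0,
        dense_bias=0.0,
        column_index_map={f"c{i}": i for i in range(C.shape[0])},
        value_index_map={},
        indexing_method=CONTINUOUS,
        embedding_dim=C.shape[1],
    )


class TestColumnSimilarity:
    def test_self_similarity_is_one(self):
        m = _tiny_model([[3.0, 4.0], [1.0, 2.0]])
        assert column_similarity(m, 0, 0) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        m = _tiny_model([[1.0, 0.0], [0.0, 1.0]])
        assert column_similarity(m, 0, 1) == pytest.approx(0.0)

    def test_hand_computed_cosine(self):
        # cos([3,4],[4,3]) = 24/25
        m = _tiny_model([[3.0, 4.0], [4.0, 3.0]])
        assert column_similarity(m, 0, 1) == pytest.approx(0.96)

    def test_symmetry(self):
        m = _tiny_model([[1.0, 2.0], [-3.0, 0.5]])
        assert column_similarity(m, 0, 1) == column_similarity(m, 1, 0)

    def test_unknown_id_raises(self):
        m = _tiny_model([[1.0, 0.0]])
        with pytest.raises(UnknownIdError):
            column_similarity(m, 0, 5)

    def test_top_similar_query_first_with_unit_similarity(self):
        m = _tiny_model([[3.0, 4.0], [4.0, 3.0], [-3.0, -4.0]])
        ranked = top_similar(m, 0, k=1)
        assert ranked == [(0, pytest.approx(1.0))]

    def test_top_similar_descending_with_id_tiebreak(self):
        m = _tiny_model([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        ranked = top_similar(m, 0, k=3)
        assert [cid for cid, _ in ranked] == [0, 1, 2]
        sims = [s for _, s in ranked]
        assert sims == sorted(sims, reverse=True)

    def test_top_similar_unknown_query(self):
        m = _tiny_model([[1.0, 0.0]])
        with pytest.raises(UnknownIdError):
            top_similar(m, 9, k=1)


class TestTrainNNE:
    def test_synthetic_separable_pairs_reach_high_accuracy(self, fixture_split):
        """Held-out accuracy on the shared-value fixture exceeds 0.9."""
        train, test = fixture_split
        model = train_nne(train, TrainingConfig(seed=11, epochs=10))
        assert evaluate(model, test).accuracy >= 0.9

    def test_zero_epochs_reproducible_initial_predictions(self, fixture_pairs):
        cfg = TrainingConfig(seed=5, epochs=0)
        m1 = train_nne(fixture_pairs, cfg)
        m2 = train_nne(fixture_pairs, cfg)
        ids = fixture_pairs.column_ids[:100], fixture_pairs.value_ids[:100]
        assert np.array_equal(m1.predict_proba(*ids), m2.predict_proba(*ids))

    def test_seeded_training_is_deterministic(self, fixture_split):
        train, test = fixture_split
        cfg = TrainingConfig(seed=3, epochs=2)
        r1 = evaluate(train_nne(train, cfg), test)
        r2 = evaluate(train_nne(train, cfg), test)
        assert r1.confusion == r2.confusion
        assert r1.accuracy == r2.accuracy

    def test_empty_pairs_rejected(self):
        empty = PairDataset(
            column_ids=np.array([], dtype=np.int64),
            value_ids=np.array([], dtype=np.int64),
            labels=np.array([], dtype=np.int64),
            column_index_map={},
            value_index_map={},
            indexing_method=CONTINUOUS,
        )
        with pytest.raises(ValueError):
            train_nne(empty)

    def test_unknown_value_id_at_prediction_is_error(self, trained_model):
        with pytest.raises(UnknownIdError):
            trained_model.predict(np.array([0]), np.array([10**6]))

    def test_save_load_round_trip(self, trained_model, tmp_path):
        path = tmp_path / "model.npz"
        trained_model.save(path)
        back = EmbeddingModel.load(path)
        assert np.array_equal(back.column_embeddings, trained_model.column_embeddings)
        assert back.column_index_map == trained_model.column_index_map
        assert back.indexing_method == trained_model.indexing_method


class TestConceptRecovery:
    def test_within_concept_similarity_exceeds_cross_concept(
        self, fixture_spec, trained_model
    ):
        """Columns generated from one shared concept cluster together."""
        cats = fixture_spec.categories()
        cmap = trained_model.column_index_map
        within, cross = [], []
        for a, b in itertools.combinations(cmap, 2):
            s = column_similarity(trained_model, cmap[a], cmap[b])
            (within if cats[a] == cats[b] else cross).append(s)
        assert np.mean(within) > np.mean(cross)

    def test_concept_mates_outrank_cross_concept_columns(
        self, fixture_spec, trained_model
    ):
        cats = fixture_spec.categories()
        cmap = trained_model.column_index_map
        inverse = {v: k for k, v in cmap.items()}
        multi = [
            n for n in cmap if sum(1 for m in cmap if cats[m] == cats[n]) > 1
        ]
        for name in multi:
            ranked = top_similar(trained_model, cmap[name], k=len(cmap))
            mates = {m for m in cmap if cats[m] == cats[name]}
            top_names = [inverse[cid] for cid, _ in ranked[: len(mates)]]
            assert set(top_names) == mates


class TestEvaluate:
    def test_perfect_predictor(self):
        r = EvalReport.from_predictions([0, 1, 1, 0], [0, 1, 1, 0])
        assert r.accuracy == 1.0
        assert r.confusion[0][1] == r.confusion[1][0] == 0

    def test_constant_positive_predictor_on_balanced_set(self):
        r = EvalReport.from_predictions([0, 1] * 10, [1] * 20)
        assert r.accuracy == 0.5
        assert r.precision == 0.5

    def test_precision_undefined_without_positive_predictions(self):
        r = EvalReport.from_predictions([1, 0], [0, 0])
        assert r.precision is None

    def test_report_recomputable_from_confusion(self, trained_model, fixture_split):
        _, test = fixture_split
        r = evaluate(trained_model, test)
        tp, fp = r.confusion[1][1], r.confusion[0][1]
        tn = r.confusion[0][0]
        assert sum(map(sum, r.confusion)) == r.n_test
        assert r.accuracy == pytest.approx((tp + tn) / r.n_test)
        if tp + fp:
            assert r.precision == pytest.approx(tp / (tp + fp))

    def test_repeated_evaluation_protocol(self, trained_model, fixture_split):
        """100 seeded subsample iterations; precision never drops below 0.5."""
        _, test = fixture_split
        reports = evaluate_repeated(trained_model, test, n_iter=100, subsample=0.5, seed=7)
        assert len(reports) == 100
        summary = precision_summary(reports)
        assert summary["min_precision"] > 0.5

    def test_repeated_evaluation_seeded(self, trained_model, fixture_split):
        _, test = fixture_split
        a = evaluate_repeated(trained_model, test, n_iter=5, seed=3)
        b = evaluate_repeated(trained_model, test, n_iter=5, seed=3)
        assert [r.confusion for r in a] == [r.confusion for r in b]

    def test_empty_test_set_rejected(self, trained_model):
        empty = PairDataset(
            column_ids=np.array([], dtype=np.int64),
            value_ids=np.array([], dtype=np.int64),
            labels=np.array([], dtype=np.int64),
            column_index_map={},
            value_index_map={},
            indexing_method=CONTINUOUS,
        )
        with pytest.raises(ValueError):
            evaluate(trained_model, empty)
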