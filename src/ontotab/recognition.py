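"""Concept-recognition classifiers and embedding-based column similarity.

Two binary classifiers decide whether the gene concept is present:

* a name-only classifier — a small feed-forward network over fixed-width
  ASCII vectors of column titles;
* a neural network with embeddings (NNE) — two parallel embedding
  lookups (column id, value id) combined by a dot product, reshaped to a
  scalar and passed through a dense sigmoid unit. The trained column
  embedding table doubles as a similarity space over columns: cosine
  similarity between embedding rows recovers which columns denote the
  same attribute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier

from ontotab.corpus_expansion import NameCorpus
from ontotab.encoding import NameVector, PairDataset


class UnknownIdError(KeyError):
    """A column or value id with no embedding row was supplied at inference."""


@dataclass
class TrainingConfig:
    """Shared training hyperparameters for both classifiers."""

    seed: int = 0
    epochs: int = 10
    batch_size: int = 256
    learning_rate: float = 0.01
    embedding_dim: int = 50
    hidden_layers: tuple[int, ...] = (64,)
    threshold: float = 0.5


# ---------------------------------------------------------------------------
# Name-only classifier
# ---------------------------------------------------------------------------


@dataclass
class NameClassifier:
    """Binary classifier over fixed-width ASCII name vectors."""

    input_width: int
    hidden_layers: tuple[int, ...]
    model: MLPClassifier
    seed: int
    threshold: float = 0.5
    _scale: float = 127.0

    def predict_proba(self, vectors: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each row."""
        X = np.atleast_2d(np.asarray(vectors, dtype=float))
        if X.shape[1] != self.input_width:
            raise ValueError(
                f"expected vectors of width {self.input_width}, got {X.shape[1]}"
            )
        return self.model.predict_proba(X / self._scale)[:, 1]

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        return (self.predict_proba(vectors) >= self.threshold).astype(int)


def _stack(vectors: Sequence[NameVector] | np.ndarray) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return vectors
    return np.stack([v.codes for v in vectors])


def train_name_classifier(
    vectors: Sequence[NameVector] | np.ndarray,
    labels: Sequence[int],
    config: TrainingConfig | None = None,
) -> NameClassifier:
    """Train the name-only network; training is seeded and reproducible."""
    config = config or TrainingConfig()
    X = _stack(vectors).astype(float)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    model = MLPClassifier(
        hidden_layer_sizes=config.hidden_layers,
        random_state=config.seed,
        max_iter=max(500, config.epochs * 50),
        learning_rate_init=config.learning_rate / 10,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X / 127.0, y)
    return NameClassifier(
        input_width=X.shape[1],
        hidden_layers=config.hidden_layers,
        model=model,
        seed=config.seed,
        threshold=config.threshold,
    )


# ---------------------------------------------------------------------------
# Neural network with embeddings (NNE)
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class EmbeddingModel:
    """Dual-embedding dot-product classifier.

    Forward pass: look up the column embedding and the value embedding,
    take their dot product, reshape to a scalar and apply a dense layer
    with a sigmoid squashing to a probability. The embeddings are the
    network weights adjusted during training.
    """

    column_embeddings: np.ndarray  # (n_columns, d)
    value_embeddings: np.ndarray  # (n_value_ids, d)
    dense_weight: float
    dense_bias: float
    column_index_map: dict[str, int]
    value_index_map: dict[str, dict[str, int]]
    indexing_method: str
    embedding_dim: int = 50
    threshold: float = 0.5

    def _check_ids(self, ids: np.ndarray, table: np.ndarray, kind: str) -> None:
        ids = np.asarray(ids)
        if ids.size and (ids.min() < 0 or ids.max() >= table.shape[0]):
            bad = int(ids.min()) if ids.min() < 0 else int(ids.max())
            raise UnknownIdError(f"unknown {kind} id {bad}")

    def predict_proba(self, column_ids: np.ndarray, value_ids: np.ndarray) -> np.ndarray:
        column_ids = np.asarray(column_ids, dtype=np.int64)
        value_ids = np.asarray(value_ids, dtype=np.int64)
        self._check_ids(column_ids, self.column_embeddings, "column")
        self._check_ids(value_ids, self.value_embeddings, "value")
        dot = np.einsum(
            "ij,ij->i", self.column_embeddings[column_ids], self.value_embeddings[value_ids]
        )
        return _sigmoid(self.dense_weight * dot + self.dense_bias)

    def predict(self, column_ids: np.ndarray, value_ids: np.ndarray) -> np.ndarray:
        return (self.predict_proba(column_ids, value_ids) >= self.threshold).astype(int)

    def save(self, path: str | Path) -> None:
        """Persist as a single archive: embedding tables + dense weights + maps."""
        np.savez(
            path,
            column_embeddings=self.column_embeddings,
            value_embeddings=self.value_embeddings,
            dense=np.array([self.dense_weight, self.dense_bias]),
            meta=np.array(
                json.dumps(
                    {
                        "column_index_map": self.column_index_map,
                        "value_index_map": self.value_index_map,
                        "indexing_method": self.indexing_method,
                        "embedding_dim": self.embedding_dim,
                        "threshold": self.threshold,
                    }
                )
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with np.load(path, allow_pickle=False) as arc:
            meta = json.loads(str(arc["meta"]))
            return cls(
                column_embeddings=arc["column_embeddings"],
                value_embeddings=arc["value_embeddings"],
                dense_weight=float(arc["dense"][0]),
                dense_bias=float(arc["dense"][1]),
                column_index_map=meta["column_index_map"],
                value_index_map=meta["value_index_map"],
                indexing_method=meta["indexing_method"],
                embedding_dim=meta["embedding_dim"],
                threshold=meta["threshold"],
            )


def train_nne(pairs: PairDataset, config: TrainingConfig | None = None) -> EmbeddingModel:
    """Train the embedding network on integer pairs (seeded, from scratch).

    Optimized with Adam on the binary cross-entropy; with
    ``config.epochs == 0`` the model carries its seeded initial weights,
    so zero-epoch predictions are reproducible.
    """
    config = config or TrainingConfig()
    if len(pairs) == 0:
        raise ValueError("pair dataset is empty")
    classes = set(np.unique(pairs.labels).tolist())
    if config.epochs > 0 and classes != {0, 1}:
        raise ValueError("training data must contain both classes")

    d = config.embedding_dim
    n_cols = pairs.n_columns
    n_vals = pairs.n_value_ids
    rng = np.random.default_rng(config.seed)
    C = rng.normal(0, 0.1, size=(n_cols, d))
    V = rng.normal(0, 0.1, size=(n_vals, d))
    w, b = 1.0, 0.0

    ci = pairs.column_ids
    vi = pairs.value_ids
    y = pairs.labels.astype(float)
    n = len(pairs)

    # Adam state
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    mC = np.zeros_like(C); vC = np.zeros_like(C)
    mV = np.zeros_like(V); vV = np.zeros_like(V)
    mw = vw = mb = vb = 0.0
    t = 0
    lr = config.learning_rate

    for _ in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            bc, bv, by = ci[idx], vi[idx], y[idx]
            Cb, Vb = C[bc], V[bv]
            dot = np.einsum("ij,ij->i", Cb, Vb)
            p = _sigmoid(w * dot + b)
            dz = (p - by) / len(idx)

            gw = float(dz @ dot)
            gb = float(dz.sum())
            gC = np.zeros_like(C)
            gV = np.zeros_like(V)
            np.add.at(gC, bc, (w * dz)[:, None] * Vb)
            np.add.at(gV, bv, (w * dz)[:, None] * Cb)

            t += 1
            corr1 = 1 - beta1**t
            corr2 = 1 - beta2**t
            mC = beta1 * mC + (1 - beta1) * gC; vC = beta2 * vC + (1 - beta2) * gC**2
            mV = beta1 * mV + (1 - beta1) * gV; vV = beta2 * vV + (1 - beta2) * gV**2
            mw = beta1 * mw + (1 - beta1) * gw; vw = beta2 * vw + (1 - beta2) * gw**2
            mb = beta1 * mb + (1 - beta1) * gb; vb = beta2 * vb + (1 - beta2) * gb**2
            C -= lr * (mC / corr1) / (np.sqrt(vC / corr2) + eps)
            V -= lr * (mV / corr1) / (np.sqrt(vV / corr2) + eps)
            w -= lr * (mw / corr1) / (np.sqrt(vw / corr2) + eps)
            b -= lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps)

    return EmbeddingModel(
        column_embeddings=C,
        value_embeddings=V,
        dense_weight=w,
        dense_bias=b,
        column_index_map=pairs.column_index_map,
        value_index_map=pairs.value_index_map,
        indexing_method=pairs.indexing_method,
        embedding_dim=d,
        threshold=config.threshold,
    )


# ---------------------------------------------------------------------------
# Column similarity
# ---------------------------------------------------------------------------


def _embedding_row(model: EmbeddingModel, column_id: int) -> np.ndarray:
    if not 0 <= column_id < model.column_embeddings.shape[0]:
        raise UnknownIdError(f"unknown column id {column_id}")
    return model.column_embeddings[column_id]


def column_similarity(model: EmbeddingModel, a: int, b: int) -> float:
    """Cosine similarity of two column-embedding vectors (symmetric)."""
    va, vb = _embedding_row(model, a), _embedding_row(model, b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(va, vb) / (na * nb))


def top_similar(model: EmbeddingModel, query: int, k: int) -> list[tuple[int, float]]:
    """Top-k columns by descending similarity to the query (query included).

    Ties break by column id.
    """
    _embedding_row(model, query)
    sims = [
        (cid, column_similarity(model, query, cid))
        for cid in range(model.column_embeddings.shape[0])
    ]
    sims.sort(key=lambda t: (-t[1], t[0]))
    return sims[:k]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Confusion-matrix summary of a binary evaluation.

    ``confusion[i][j]`` counts pairs with true label i predicted as j.
    Precision is positive-class precision; the 0/0 case is None.
    """

    confusion: list[list[int]]
    accuracy: float
    precision: float | None
    n_test: int

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "EvalReport":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        conf = [[0, 0], [0, 0]]
        for t, p in zip(y_true, y_pred):
            conf[t][p] += 1
        n = len(y_true)
        tp, fp, tn = conf[1][1], conf[0][1], conf[0][0]
        acc = (tp + tn) / n if n else 0.0
        prec = tp / (tp + fp) if (tp + fp) else None
        return cls(confusion=conf, accuracy=acc, precision=prec, n_test=n)

    def to_json(self) -> str:
        return json.dumps(
            {
                "confusion": self.confusion,
                "accuracy": self.accuracy,
                "precision": self.precision,
                "n_test": self.n_test,
            }
        )


def evaluate(model: EmbeddingModel, test: PairDataset) -> EvalReport:
    """Evaluate on a held-out pair set."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    pred = model.predict(test.column_ids, test.value_ids)
    return EvalReport.from_predictions(test.labels, pred)


def evaluate_repeated(
    model: EmbeddingModel,
    test: PairDataset,
    n_iter: int = 100,
    subsample: float = 0.5,
    seed: int = 0,
) -> list[EvalReport]:
    """Repeated evaluation on independent seeded subsamples of the test set.

    Each iteration draws a different random sample of the test set and
    scores it; the list of reports exposes the precision trajectory
    (mean and minimum are the usual summaries).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(test) == 0:
        raise ValueError("test set is empty")
    rng = np.random.default_rng(seed)
    n_sub = max(1, int(round(subsample * len(test))))
    reports = []
    for _ in range(n_iter):
        idx = rng.choice(len(test), size=n_sub, replace=False)
        reports.append(evaluate(model, test.subset(idx)))
    return reports


def precision_summary(reports: Sequence[EvalReport]) -> dict[str, float]:
    """Mean and min positive-class precision over defined iterations."""
    precs = [r.precision for r in reports if r.precision is not None]
    if not precs:
        raise ValueError("precision undefined in every iteration")
    return {
        "mean_precision": float(np.mean(precs)),
        "min_precision": float(np.min(precs)),
        "mean_accuracy": float(np.mean([r.accuracy for r in reports])),
    }
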