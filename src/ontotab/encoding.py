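"""Integer representations consumed by the classifiers.

Names become fixed-width ASCII-code vectors (zero padded to the longest
name in the corpus). Column/value pairs become (column_id, value_id,
label) triples: one pair per cell, with value ids assigned per semantic
category either restarting at 0 in each category ("per_category") or
increasing globally ("continuous"). The two indexing methods matter:
per-category ids collide across categories, which is exactly what makes
the resulting column-similarity space conflate distinct attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ontotab.corpus_expansion import NameCorpus
from ontotab.tabular_io import ColumnRecord

PER_CATEGORY = "per_category"
CONTINUOUS = "continuous"


@dataclass
class NameVector:
    """Fixed-length ASCII encoding of one name."""

    codes: np.ndarray  # shape (width,), non-negative ints
    source: str


def encode_names(corpus: NameCorpus) -> list[NameVector]:
    """Encode every corpus name as a fixed-width ASCII-code vector.

    Width is the corpus-wide maximum name length; positions beyond the
    name hold 0. Non-ASCII characters also map to 0 (the scheme is
    ASCII-only; collisions with padding are acceptable at corpus scale).
    """
    if not corpus.entries:
        raise ValueError("corpus is empty")
    width = max(len(e.name) for e in corpus.entries)
    out = []
    for e in corpus.entries:
        codes = np.zeros(width, dtype=np.int64)
        for i, ch in enumerate(e.name):
            cp = ord(ch)
            codes[i] = cp if cp < 128 else 0
        out.append(NameVector(codes=codes, source=e.name))
    return out


def decode_name(vector: NameVector | np.ndarray) -> str:
    """Inverse of encode_names for printable-ASCII names (stops at padding)."""
    codes = vector.codes if isinstance(vector, NameVector) else vector
    chars = []
    for c in codes:
        if c == 0:
            break
        chars.append(chr(int(c)))
    return "".join(chars)


@dataclass
class PairDataset:
    """Integer-encoded (column_id, value_id, label) triples.

    ``column_index_map`` maps column name -> consecutive id from 0;
    ``value_index_map`` maps (category, value) -> id, nested as
    {category: {value: id}}. Under per-category indexing ids restart at
    0 within each category; under continuous indexing they are globally
    unique across categories.
    """

    column_ids: np.ndarray
    value_ids: np.ndarray
    labels: np.ndarray
    column_index_map: dict[str, int]
    value_index_map: dict[str, dict[str, int]]
    indexing_method: str

    def __post_init__(self) -> None:
        if not (len(self.column_ids) == len(self.value_ids) == len(self.labels)):
            raise ValueError("column_ids, value_ids and labels must align 1:1")
        if self.indexing_method not in (PER_CATEGORY, CONTINUOUS):
            raise ValueError(f"unknown indexing method: {self.indexing_method}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_columns(self) -> int:
        return len(self.column_index_map)

    @property
    def n_value_ids(self) -> int:
        ids = [i for cat in self.value_index_map.values() for i in cat.values()]
        return (max(ids) + 1) if ids else 0

    def subset(self, idx: np.ndarray) -> "PairDataset":
        return PairDataset(
            column_ids=self.column_ids[idx],
            value_ids=self.value_ids[idx],
            labels=self.labels[idx],
            column_index_map=self.column_index_map,
            value_index_map=self.value_index_map,
            indexing_method=self.indexing_method,
        )

    def to_files(self, prefix: str | Path) -> None:
        """Serialize as TSV (column_id, value_id, label) + JSON index maps."""
        prefix = Path(prefix)
        with open(prefix.with_suffix(".tsv"), "w", encoding="utf-8") as fh:
            fh.write("column_id\tvalue_id\tlabel\n")
            for c, v, l in zip(self.column_ids, self.value_ids, self.labels):
                fh.write(f"{c}\t{v}\t{l}\n")
        with open(prefix.with_suffix(".columns.json"), "w", encoding="utf-8") as fh:
            json.dump(
                {"column_index_map": self.column_index_map, "indexing_method": self.indexing_method},
                fh,
                indent=1,
            )
        with open(prefix.with_suffix(".values.json"), "w", encoding="utf-8") as fh:
            json.dump(self.value_index_map, fh, indent=1)

    @classmethod
    def from_files(cls, prefix: str | Path) -> "PairDataset":
        prefix = Path(prefix)
        rows = np.loadtxt(prefix.with_suffix(".tsv"), dtype=np.int64, skiprows=1, ndmin=2)
        with open(prefix.with_suffix(".columns.json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        with open(prefix.with_suffix(".values.json"), encoding="utf-8") as fh:
            value_map = json.load(fh)
        if rows.size == 0:
            rows = rows.reshape(0, 3)
        return cls(
            column_ids=rows[:, 0],
            value_ids=rows[:, 1],
            labels=rows[:, 2],
            column_index_map=meta["column_index_map"],
            value_index_map=value_map,
            indexing_method=meta["indexing_method"],
        )


def build_pairs(
    columns: Sequence[ColumnRecord],
    class_labels: Mapping[str, int],
    method: str = CONTINUOUS,
    categories: Mapping[str, str] | None = None,
) -> PairDataset:
    """Construct the pair dataset from labeled columns.

    Each column contributes one pair per cell, so the total pair count
    is the sum of column sizes. ``categories`` groups columns into
    semantic attribute kinds (e.g. all gene-symbol columns form one
    category and draw value ids from one shared map); when omitted,
    every column is its own category. Duplicate values within a category
    share one id — similarity learning requires shared ids for shared
    values.
    """
    if method not in (PER_CATEGORY, CONTINUOUS):
        raise ValueError(f"unknown indexing method: {method}")
    for col in columns:
        if col.name not in class_labels:
            raise KeyError(f"column {col.name!r} missing from class_labels")
    cat_of = dict(categories) if categories is not None else {}

    column_index_map = {c.name: i for i, c in enumerate(columns)}
    value_index_map: dict[str, dict[str, int]] = {}
    next_global = 0

    col_ids, val_ids, labels = [], [], []
    for col in columns:
        cid = column_index_map[col.name]
        cat = cat_of.get(col.name, col.name)
        cat_map = value_index_map.setdefault(cat, {})
        label = int(class_labels[col.name])
        for v in col.values:
            if v not in cat_map:
                if method == PER_CATEGORY:
                    cat_map[v] = len(cat_map)
                else:
                    cat_map[v] = next_global
                    next_global += 1
            col_ids.append(cid)
            val_ids.append(cat_map[v])
            labels.append(label)
    return PairDataset(
        column_ids=np.asarray(col_ids, dtype=np.int64),
        value_ids=np.asarray(val_ids, dtype=np.int64),
        labels=np.asarray(labels, dtype=np.int64),
        column_index_map=column_index_map,
        value_index_map=value_index_map,
        indexing_method=method,
    )


def split(
    dataset: PairDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[PairDataset, PairDataset]:
    """Seeded disjoint, exhaustive train/test split of the pairs.

    The training share takes floor(train_fraction * n) pairs; the
    remainder goes to test.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 pairs to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    return dataset.subset(perm[:n_train]), dataset.subset(perm[n_train:])
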