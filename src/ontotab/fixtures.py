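"""Synthetic gene-like fixtures: tables, mock ontology index, generic RDF.

The generator emulates the structure of real gene datasets at pattern
level: concepts distinctive for the gene concept (identifiers, symbols,
names) appear as near-duplicate columns shared across datasets and are
labeled positive; dataset-specific columns (dates, chromosomal
coordinates, locations) are labeled negative. Columns sharing a concept
draw from one value pool, so a trained embedding model can recover the
concept structure, and the ground-truth labels propagate to every
downstream check (classification, similarity, coverage, quality
tallies). Everything is byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ontotab.tabular_io import ColumnRecord, write_table

GENERIC_BASE = "http://example.org/generic"
DATA_BASE = "http://example.org/data"
GRAPH_BASE = "http://example.org/graph"

PATTERNS = ("symbol", "numeric_id", "name", "date", "coordinate", "band", "accession")


@dataclass
class ConceptSpec:
    """One semantic attribute kind and the columns that carry it."""

    name: str
    pattern: str
    label: int
    columns: list[tuple[str, str]]  # (dataset_id, column name)
    pool_size: int | None = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown value pattern {self.pattern!r}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not self.columns:
            raise ValueError("a concept needs at least one column")


@dataclass
class FixtureSpec:
    """Full specification of one synthetic bundle."""

    n_rows: int = 1000
    seed: int = 0
    concepts: list[ConceptSpec] = field(default_factory=lambda: default_concepts())

    def __post_init__(self) -> None:
        labels = {c.label for c in self.concepts}
        if labels != {0, 1}:
            raise ValueError("need at least one label-1 and one label-0 concept")
        names = [col for c in self.concepts for _, col in c.columns]
        if len(names) != len(set(names)):
            raise ValueError("fixture column names must be globally unique")

    @property
    def dataset_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.concepts:
            for ds, _ in c.columns:
                if ds not in seen:
                    seen.append(ds)
        return seen

    def class_labels(self) -> dict[str, int]:
        """Ground-truth column label map (column name -> {0,1})."""
        return {col: c.label for c in self.concepts for _, col in c.columns}

    def categories(self) -> dict[str, str]:
        """Ground-truth column -> concept map for pair indexing."""
        return {col: c.name for c in self.concepts for _, col in c.columns}


def default_concepts() -> list[ConceptSpec]:
    """Three gene datasets with shared positive and specific negative columns."""
    return [
        ConceptSpec("hgnc_id", "numeric_id", 1, [("genes_a", "hgnc id"), ("annotations_c", "HGNC Id")]),
        ConceptSpec(
            "gene_symbol",
            "symbol",
            1,
            [("genes_a", "symbol"), ("interactions_b", "Gene Symbol"), ("annotations_c", "Symbol")],
        ),
        ConceptSpec("gene_name", "name", 1, [("genes_a", "Name"), ("annotations_c", "name")]),
        ConceptSpec("date_modified", "date", 0, [("genes_a", "date modified")]),
        ConceptSpec("date_approved", "date", 0, [("genes_a", "date approved reserved")]),
        ConceptSpec("location", "band", 0, [("genes_a", "location")]),
        ConceptSpec("chromosome", "band", 0, [("annotations_c", "Chromosome")]),
        ConceptSpec("chrom_start", "coordinate", 0, [("annotations_c", "Chromosomal Start")]),
        ConceptSpec("chrom_stop", "coordinate", 0, [("annotations_c", "Chromosomal Stop")]),
        ConceptSpec("accession", "accession", 0, [("annotations_c", "Accession Id")]),
        ConceptSpec("pubmed_ids", "numeric_id", 0, [("interactions_b", "PubMed IDs")]),
        ConceptSpec("organism", "name", 0, [("interactions_b", "Organism")]),
    ]


_LETTERS = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
_ALNUM = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"))
_LOWER = np.array(list("abcdefghijklmnopqrstuvwxyz"))


def _value_pool(pattern: str, size: int, rng: np.random.Generator) -> list[str]:
    """Draw a pool of distinct values following one pattern."""
    pool: list[str] = []
    seen: set[str] = set()
    base = int(rng.integers(1000, 50000))
    i = 0
    while len(pool) < size:
        if pattern == "numeric_id":
            v = str(base + i)
        elif pattern == "accession":
            v = f"PA{base + i}"
        elif pattern == "symbol":
            n = int(rng.integers(2, 7))
            chars = [str(rng.choice(_LETTERS))] + [str(rng.choice(_ALNUM)) for _ in range(n - 1)]
            v = "".join(chars)
        elif pattern == "name":
            words = []
            for _ in range(2):
                ln = int(rng.integers(3, 9))
                words.append("".join(str(rng.choice(_LOWER)) for _ in range(ln)))
            v = " ".join(words)
        elif pattern == "date":
            y = int(rng.integers(1990, 2021))
            m = int(rng.integers(1, 13))
            d = int(rng.integers(1, 29))
            v = f"{y:04d}-{m:02d}-{d:02d}"
        elif pattern == "coordinate":
            v = str(int(rng.integers(1_000, 250_000_000)))
        elif pattern == "band":
            chrom = int(rng.integers(1, 23))
            arm = "p" if rng.random() < 0.5 else "q"
            v = f"{chrom}{arm}{int(rng.integers(11, 40))}.{int(rng.integers(1, 4))}"
        else:  # pragma: no cover - guarded by ConceptSpec
            raise ValueError(pattern)
        i += 1
        if v not in seen:
            seen.add(v)
            pool.append(v)
    return pool


def generate_columns(spec: FixtureSpec) -> dict[str, list[ColumnRecord]]:
    """Generate all columns, grouped by dataset id.

    Columns of one concept sample (with replacement) from the concept's
    shared value pool, so concept-mates overlap heavily in values; pools
    of distinct concepts are disjoint by construction with overwhelming
    probability.
    """
    rng = np.random.default_rng(spec.seed)
    datasets: dict[str, list[ColumnRecord]] = {ds: [] for ds in spec.dataset_ids}
    for concept in spec.concepts:
        pool_size = concept.pool_size or max(10, spec.n_rows // 10)
        pool = _value_pool(concept.pattern, pool_size, rng)
        for ds_id, col_name in concept.columns:
            idx = rng.integers(0, len(pool), size=spec.n_rows)
            values = [pool[i] for i in idx]
            datasets[ds_id].append(ColumnRecord(name=col_name, values=values, dataset_id=ds_id))
    return datasets


def generate_tables(spec: FixtureSpec, out_dir: str | Path) -> list[Path]:
    """Write one delimited file per dataset; returns the paths.

    The first dataset is written as TSV and the rest as CSV, mirroring
    the mixed formats of real gene data collections.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    datasets = generate_columns(spec)
    paths = []
    for i, (ds_id, columns) in enumerate(datasets.items()):
        ext = ".tsv" if i == 0 else ".csv"
        path = out_dir / f"{ds_id}{ext}"
        write_table(path, columns)
        paths.append(path)
    return paths


def _underscored(name: str) -> str:
    return name.replace(" ", "_")


def generate_mock_ontology(spec: FixtureSpec, path: str | Path | None = None) -> dict:
    """Build the mock ontology index (optionally written as JSON).

    For every positive concept each of its columns gets a FULL-matchable
    property (label equal to the column name up to case/underscores) in
    the gene ontology GENEMOCK, plus SEMI-matchable and distractor terms
    spread over the non-gene ontologies CHEMMOCK and MISCMOCK. GENEMOCK
    therefore holds the plurality of matches, so frequency analysis
    selects it. A Gene class term supports class search and typing.
    """
    ontologies = [
        {"acronym": "GENEMOCK", "description": "Mock ontology of gene concepts: gene symbols, gene identifiers and gene names."},
        {"acronym": "CHEMMOCK", "description": "Mock ontology of chemical interactions and reactions."},
        {"acronym": "MISCMOCK", "description": "Mock ontology of dates, coordinates and administrative records."},
    ]
    terms: list[dict] = []

    def add(label: str, onto: str, kind: str, definition: str | None = None) -> None:
        iri = f"http://example.org/onto/{onto}/{_underscored(label)}"
        terms.append(
            {"label": label, "iri": iri, "ontology": onto, "kind": kind, "definition": definition}
        )

    add("Gene", "GENEMOCK", "class", "A heritable unit of genomic information.")
    for concept in spec.concepts:
        if concept.label != 1:
            continue
        for _, col in concept.columns:
            add(
                _underscored(col),
                "GENEMOCK",
                "property",
                f"The {concept.name.replace('_', ' ')} attribute of a gene.",
            )
    # SEMI-matchable generic terms share single tokens with gene columns
    add("id", "CHEMMOCK", "property", "A generic identifier.")
    add("symbol prefix", "MISCMOCK", "property", "Leading characters of a record symbol.")
    # distractors that match nothing gene-like
    add("reaction rate", "CHEMMOCK", "property", "Speed of a chemical reaction.")
    add("assay temperature", "CHEMMOCK", "property", None)
    add("archive bin", "MISCMOCK", "property", "Storage bin for retired records.")

    index = {"ontologies": ontologies, "terms": terms}
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(index, fh, indent=1)
    return index


def _slug(name: str) -> str:
    # case-preserving: distinct headers must mint distinct predicates
    return re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_")


def generic_predicate(dataset_id: str, column_name: str) -> str:
    """The deterministic predicate IRI the generic converter mints."""
    return f"{GENERIC_BASE}/{dataset_id}/{_slug(column_name)}"


def generic_row_class(dataset_id: str) -> str:
    return f"{GENERIC_BASE}/{dataset_id}/Row"


def generate_generic_rdf(
    datasets: dict[str, list[ColumnRecord]],
    path: str | Path,
) -> Path:
    """Emit generic converter-style N-Quads for the given tables.

    One entity per row, one auto-minted predicate per column, one type
    quad per row entity, one named graph per dataset. An n-row,
    c-column table yields n*c data quads plus n type quads.
    """
    path = Path(path)
    lines: list[str] = []
    for ds_id, columns in datasets.items():
        graph = f"{GRAPH_BASE}/{ds_id}"
        row_class = generic_row_class(ds_id)
        n_rows = len(columns[0].values) if columns else 0
        for i in range(n_rows):
            subject = f"{DATA_BASE}/{ds_id}/row{i}"
            lines.append(
                f"<{subject}> <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> "
                f"<{row_class}> <{graph}> ."
            )
            for col in columns:
                pred = generic_predicate(ds_id, col.name)
                obj = json.dumps(col.values[i])  # N-Quads literal escaping
                lines.append(f"<{subject}> <{pred}> {obj} <{graph}> .")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
    return path
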