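"""Rewriting generic converter-produced RDF with selected ontology terms.

The upstream converter mints one predicate per column and one entity per
row, all meaningless IRIs. Enhancement replaces each mapped generic
predicate with the selected ontology property (same subject, object and
named graph) and asserts the recognized class on the row entities, via
generated SPARQL Update statements. Predicate rewriting conserves the
quad count; only type assertions add quads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdflib import Dataset, Graph, URIRef
from rdflib.namespace import RDF


@dataclass
class EnhancementMapping:
    """Column-to-ontology-property rewrite plan for one dataset."""

    dataset_id: str
    property_map: dict[str, str] = field(default_factory=dict)
    class_iri: str | None = None

    def __post_init__(self) -> None:
        for old, new in self.property_map.items():
            if not (_is_absolute_iri(old) and _is_absolute_iri(new)):
                raise ValueError(f"property map entries must be absolute IRIs: {old} -> {new}")
            if old == new:
                raise ValueError(f"predicate maps to itself: {old}")
        if self.class_iri is not None and not _is_absolute_iri(self.class_iri):
            raise ValueError(f"class_iri must be an absolute IRI: {self.class_iri}")


def _is_absolute_iri(iri: str) -> bool:
    return ":" in iri and not iri.startswith(":")


@dataclass
class GraphOverview:
    """Counts mirroring a triple-store data overview."""

    n_classes: int
    n_properties: int
    n_instances: int

    def __post_init__(self) -> None:
        if min(self.n_classes, self.n_properties, self.n_instances) < 0:
            raise ValueError("counts must be >= 0")


def overview(ds: Dataset) -> GraphOverview:
    """Distinct rdf:type objects, predicates, and typed subjects."""
    classes: set = set()
    predicates: set = set()
    instances: set = set()
    for s, p, o, _g in ds.quads((None, None, None, None)):
        predicates.add(p)
        if p == RDF.type:
            classes.add(o)
            instances.add(s)
    return GraphOverview(
        n_classes=len(classes),
        n_properties=len(predicates),
        n_instances=len(instances),
    )


def load_nquads(path: str | Path) -> tuple[Dataset, GraphOverview]:
    """Parse an N-Quads file; malformed lines are fatal with position info."""
    ds = Dataset()
    try:
        ds.parse(str(path), format="nquads")
    except Exception as exc:  # rdflib raises with line context in the message
        raise ValueError(f"N-Quads parse error in {path}: {exc}") from exc
    return ds, overview(ds)


def save_nquads(ds: Dataset, path: str | Path) -> None:
    """Serialize with one sorted quad per line (stable, diff-friendly)."""
    lines = sorted(
        _format_quad(s, p, o, g) for s, p, o, g in ds.quads((None, None, None, None))
    )
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")


def _format_quad(s, p, o, g) -> str:
    graph_part = f" {g.n3()}" if g is not None and not _is_default_graph(g) else ""
    return f"{s.n3()} {p.n3()} {o.n3()}{graph_part} ."


def _is_default_graph(g) -> bool:
    from rdflib.graph import DATASET_DEFAULT_GRAPH_ID

    gid = g.identifier if isinstance(g, Graph) else g
    return gid == DATASET_DEFAULT_GRAPH_ID


@dataclass
class UpdateStatement:
    """One SPARQL Update statement plus its structured intent."""

    sparql: str
    kind: str  # "rewrite" | "type_assertion"
    old_predicate: str | None = None
    new_predicate: str | None = None
    class_iri: str | None = None


def build_updates(mapping: EnhancementMapping) -> list[UpdateStatement]:
    """Generate update statements from a mapping.

    One predicate-rewrite statement per property-map entry (delete the
    triple with the old predicate, insert it with the new one, same
    subject/object/graph) and, when a class IRI is set, one
    type-assertion statement typing the row entities.
    """
    if not mapping.property_map and mapping.class_iri is None:
        raise ValueError("mapping is empty")
    statements: list[UpdateStatement] = []
    for old, new in mapping.property_map.items():
        sparql = (
            f"DELETE {{ GRAPH ?g {{ ?s <{old}> ?o }} }}\n"
            f"INSERT {{ GRAPH ?g {{ ?s <{new}> ?o }} }}\n"
            f"WHERE  {{ GRAPH ?g {{ ?s <{old}> ?o }} }}"
        )
        statements.append(
            UpdateStatement(sparql=sparql, kind="rewrite", old_predicate=old, new_predicate=new)
        )
    if mapping.class_iri is not None:
        if mapping.property_map:
            # type only the subjects of mapped (now rewritten) predicates
            values = " ".join(f"<{p}>" for p in mapping.property_map.values())
            where = f"?s ?p ?o . VALUES ?p {{ {values} }}"
        else:
            where = "?s ?p ?o ."
        sparql = (
            f"INSERT {{ GRAPH ?g {{ ?s a <{mapping.class_iri}> }} }}\n"
            f"WHERE  {{ GRAPH ?g {{ {where} }} }}"
        )
        statements.append(
            UpdateStatement(sparql=sparql, kind="type_assertion", class_iri=mapping.class_iri)
        )
    return statements


def updates_document(statements: Sequence[UpdateStatement]) -> str:
    """A single SPARQL Update document, statements separated by ';'."""
    return " ;\n".join(s.sparql for s in statements) + "\n"


def apply_updates(ds: Dataset, statements: Sequence[UpdateStatement]) -> tuple[Dataset, GraphOverview]:
    """Apply update statements in place; returns the dataset and its overview.

    A rewrite whose old predicate is absent from the graph is a warning
    no-op. Rewrites preserve graph membership and never alter subjects
    or objects; type assertions only add quads.
    """
    pred_in_use = {p for _s, p, _o, _g in ds.quads((None, None, None, None))}
    for st in statements:
        if st.kind == "rewrite" and URIRef(st.old_predicate) not in pred_in_use:
            warnings.warn(
                f"predicate {st.old_predicate} absent from graph; rewrite is a no-op",
                stacklevel=2,
            )
            continue
        ds.update(st.sparql)
        pred_in_use = {p for _s, p, _o, _g in ds.quads((None, None, None, None))}
    return ds, overview(ds)
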