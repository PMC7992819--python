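"""Ontology term search, restriction, and match curation.

A term repository (live biomedical ontology portal, or a deterministic
in-memory index for offline work) is queried with column names. Results
can be restricted by a longest-match rule (the full search key must be
contained in the term label) and by an ontology list, which is derived
either from a frequency distribution of matches per ontology or from the
recognized dataset concept. Matches are curated into Full / Semi / No
match categories; the first Full match per column becomes its property.
"""

from __future__ import annotations

import json
import re
import time
import urllib.parse
import urllib.request
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence

FULL = "FULL"
SEMI = "SEMI"
NONE = "NONE"
UNCURATED = "UNCURATED"

CLASS = "class"
PROPERTY = "property"


class TransportError(RuntimeError):
    """Retryable failure talking to a live repository."""


@dataclass
class TermMatch:
    """One candidate ontology term for a search key."""

    search_key: str
    term_label: str
    term_iri: str
    ontology_acronym: str
    term_kind: str  # class | property
    definition: str | None = None
    category: str = UNCURATED

    def __post_init__(self) -> None:
        if self.term_kind not in (CLASS, PROPERTY):
            raise ValueError(f"term_kind must be class or property, got {self.term_kind!r}")
        if self.category not in (FULL, SEMI, NONE, UNCURATED):
            raise ValueError(f"invalid category {self.category!r}")


@dataclass
class SearchConfig:
    """Search restriction parameters."""

    longest_match: bool = False
    ontology_filter: list[str] | None = None
    term_kind: str = PROPERTY
    page_limit: int = 50

    def __post_init__(self) -> None:
        if self.page_limit < 1:
            raise ValueError("page_limit must be >= 1")


def _normalize(label: str) -> str:
    """Casefold, underscores to spaces, collapse whitespace."""
    return re.sub(r"\s+", " ", label.casefold().replace("_", " ")).strip()


def _tokens(label: str) -> set[str]:
    return set(_normalize(label).split())


class TermRepository(Protocol):
    """Anything searchable for ontology terms."""

    def query(self, key: str, config: SearchConfig) -> list[TermMatch]: ...

    def ontology_acronyms(self) -> set[str]: ...


class MockTermIndex:
    """Deterministic in-memory term index (insertion-ordered results).

    Loads from a JSON file holding a list of term records with keys
    label, iri, ontology, kind, definition. A term matches a key when
    its normalized label shares at least one token with the key or
    contains the full normalized key.
    """

    def __init__(self, terms: Sequence[dict]):
        self._terms = list(terms)

    @classmethod
    def from_json(cls, path: str | Path) -> "MockTermIndex":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(data["terms"] if isinstance(data, dict) else data)

    def ontology_acronyms(self) -> set[str]:
        return {t["ontology"] for t in self._terms}

    def query(self, key: str, config: SearchConfig) -> list[TermMatch]:
        norm_key = _normalize(key)
        key_tokens = _tokens(key)
        out: list[TermMatch] = []
        for t in self._terms:
            if t["kind"] != config.term_kind:
                continue
            norm_label = _normalize(t["label"])
            hit = norm_key in norm_label or bool(key_tokens & _tokens(t["label"]))
            if not hit:
                continue
            out.append(
                TermMatch(
                    search_key=key,
                    term_label=t["label"],
                    term_iri=t["iri"],
                    ontology_acronym=t["ontology"],
                    term_kind=t["kind"],
                    definition=t.get("definition"),
                )
            )
        return out


class RestTermIndex:
    """Thin client for a live ontology-portal search endpoint.

    Speaks JSON over HTTPS with parameters for an ontology list and
    exact/longest matching; paged and politely rate limited. Requires an
    API key and network access — never exercised offline.
    """

    def __init__(self, base_url: str, api_key: str, min_interval: float = 0.5):
        self.base_url = base_url.rstrip("/")
        self.api_key = api_key
        self.min_interval = min_interval
        self._last_call = 0.0

    def ontology_acronyms(self) -> set[str]:  # pragma: no cover - network
        return set()

    def query(self, key: str, config: SearchConfig) -> list[TermMatch]:  # pragma: no cover - network
        params = {
            "q": key,
            "apikey": self.api_key,
            "pagesize": str(config.page_limit),
        }
        if config.term_kind == PROPERTY:
            params["also_search_properties"] = "true"
        if config.ontology_filter:
            params["ontologies"] = ",".join(config.ontology_filter)
        if config.longest_match:
            params["require_exact_match"] = "false"
        url = f"{self.base_url}/search?{urllib.parse.urlencode(params)}"
        wait = self.min_interval - (time.monotonic() - self._last_call)
        if wait > 0:
            time.sleep(wait)
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                payload = json.load(resp)
        except OSError as exc:
            raise TransportError(f"repository request failed: {exc}") from exc
        self._last_call = time.monotonic()
        out = []
        for item in payload.get("collection", []):
            ontology = item.get("links", {}).get("ontology", "").rsplit("/", 1)[-1]
            out.append(
                TermMatch(
                    search_key=key,
                    term_label=item.get("prefLabel", ""),
                    term_iri=item.get("@id", ""),
                    ontology_acronym=ontology,
                    term_kind=config.term_kind,
                    definition=(item.get("definition") or [None])[0],
                )
            )
        return out


def search(repository: TermRepository, key: str, config: SearchConfig) -> list[TermMatch]:
    """Query the repository, applying restrictions.

    With ``longest_match`` only terms whose normalized label contains
    the full normalized key survive; with ``ontology_filter`` only terms
    from the listed ontologies survive (unknown acronyms in the filter
    are warned about and ignored). Results are capped at
    ``config.page_limit``.
    """
    results = repository.query(key, config)
    if config.longest_match:
        norm_key = _normalize(key)
        results = [m for m in results if norm_key in _normalize(m.term_label)]
    if config.ontology_filter is not None:
        known = repository.ontology_acronyms()
        keep = []
        for acro in config.ontology_filter:
            if known and acro not in known:
                warnings.warn(f"unknown ontology acronym {acro!r} ignored", stacklevel=2)
            else:
                keep.append(acro)
        results = [m for m in results if m.ontology_acronym in keep]
    return results[: config.page_limit]


@dataclass
class OntologyFrequency:
    """Match counts per ontology with a selection threshold."""

    counts: dict[str, int]
    threshold: int
    selected: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        expected = {o for o, c in self.counts.items() if c >= self.threshold}
        if not self.selected:
            self.selected = expected
        elif self.selected != expected:
            raise ValueError("selected must be exactly the ontologies meeting threshold")


def build_frequency(
    matches: Sequence[TermMatch],
    threshold_rule: int | str = "mode",
) -> OntologyFrequency:
    """Frequency distribution of matches per ontology.

    The "mode" rule sets the threshold to the most frequent per-ontology
    match count (ties resolved toward the smaller count, so selection is
    never artificially narrowed); an explicit integer is always accepted
    and is the recommended path since the mode varies by dataset.
    """
    if not matches:
        raise ValueError("match list is empty")
    counts: dict[str, int] = {}
    for m in matches:
        counts[m.ontology_acronym] = counts.get(m.ontology_acronym, 0) + 1
    if threshold_rule == "mode":
        values = sorted(counts.values())
        best_count, best_freq = values[0], 0
        for v in set(values):
            f = values.count(v)
            if f > best_freq or (f == best_freq and v < best_count):
                best_count, best_freq = v, f
        threshold = best_count
    else:
        threshold = int(threshold_rule)
    return OntologyFrequency(counts=counts, threshold=threshold)


class OntologyListProvider(Protocol):
    """Maps a recognized concept to a list of relevant ontology acronyms."""

    def ontologies_for(self, concept: str) -> list[str]: ...


class MockOntologyListProvider:
    """Offline provider: ontologies whose description mentions the concept."""

    def __init__(self, ontologies: Sequence[dict]):
        # records with keys: acronym, description
        self._ontologies = list(ontologies)

    @classmethod
    def from_json(cls, path: str | Path) -> "MockOntologyListProvider":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(data["ontologies"])

    def ontologies_for(self, concept: str) -> list[str]:
        needle = _normalize(concept)
        return [
            o["acronym"]
            for o in self._ontologies
            if needle and needle in _normalize(o.get("description", ""))
        ]


def concept_ontology_list(provider: OntologyListProvider, concept: str) -> list[str]:
    """Ontology acronyms relevant to a recognized concept, usable as a filter."""
    return provider.ontologies_for(concept)


def categorize(
    match: TermMatch,
    column: str,
    curator: str | None = None,
) -> TermMatch:
    """Assign a curation category; a curator verdict always wins.

    Auto-suggestion: FULL when the normalized labels are equal
    (case/underscore/whitespace-insensitive), SEMI when the label token
    sets intersect, NONE otherwise. Description-based FULL judgments are
    inherently the curator's call.
    """
    if curator is not None:
        if curator not in (FULL, SEMI, NONE):
            raise ValueError(f"invalid curator verdict {curator!r}")
        return replace(match, category=curator)
    if _normalize(match.term_label) == _normalize(column):
        cat = FULL
    elif _tokens(match.term_label) & _tokens(column):
        cat = SEMI
    else:
        cat = NONE
    return replace(match, category=cat)


def select_property(matches: Sequence[TermMatch]) -> Optional[TermMatch]:
    """First FULL match in repository result order; None when absent.

    Columns with no Full match keep their generic converter property.
    """
    for m in matches:
        if m.category == FULL:
            return m
    return None


def save_curated(matches: Sequence[TermMatch], path: str | Path) -> None:
    """Persist curated matches as TSV (search_key, iri, ontology, kind, category)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("search_key\tterm_label\tterm_iri\tontology\tkind\tcategory\n")
        for m in matches:
            fh.write(
                f"{m.search_key}\t{m.term_label}\t{m.term_iri}\t"
                f"{m.ontology_acronym}\t{m.term_kind}\t{m.category}\n"
            )


def load_curated(path: str | Path) -> list[TermMatch]:
    out = []
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            key, label, iri, onto, kind, cat = line.rstrip("\n").split("\t")
            out.append(
                TermMatch(
                    search_key=key,
                    term_label=label,
                    term_iri=iri,
                    ontology_acronym=onto,
                    term_kind=kind,
                    category=cat,
                )
            )
    return out
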