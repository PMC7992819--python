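"""Evaluation metrics: coverage, completeness, and data-quality tallies.

Coverage is the fraction of a dataset's columns covered (replaced) by
the enhancement method; for property search only columns with a Full
match count as covered. Completeness is the fraction of all retrieved
matches that are Full matches. The quality tally counts curator-flagged
issues (broad terminology, ontology hijacking, missing definition) and
derives undefined terminology as the columns still carrying their
auto-minted converter predicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import TYPE_CHECKING, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from ontotab.rdf_enhance import EnhancementMapping


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(value: float) -> str:
    """Render a percentage, dropping a trailing '.0' ("37%", "72.7%")."""
    v = _round_half_up(value, 1)
    if v == int(v):
        return f"{int(v)}%"
    return f"{v}%"


@dataclass
class CoverageReport:
    """Per-dataset column coverage."""

    dataset_id: str
    matched_columns: int
    total_columns: int
    coverage_pct: float

    def __post_init__(self) -> None:
        if not 0 <= self.matched_columns <= self.total_columns:
            raise ValueError("need 0 <= matched_columns <= total_columns")

    def __str__(self) -> str:
        return f"{self.dataset_id}\t{self.matched_columns}\t{format_pct(self.coverage_pct)}"


def coverage(
    matched: int,
    total: int,
    dataset_id: str = "",
    decimals: int = 0,
) -> CoverageReport:
    """Ratio of covered columns to total columns, as a rounded percentage.

    Default rounding is to the integer percent (half-up); pass
    ``decimals=1`` where one decimal is wanted (e.g. 8 of 11 columns ->
    72.7). ``total`` must be positive.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= matched <= total:
        raise ValueError("need 0 <= matched <= total")
    pct = _round_half_up(100.0 * matched / total, decimals)
    return CoverageReport(
        dataset_id=dataset_id,
        matched_columns=matched,
        total_columns=total,
        coverage_pct=pct,
    )


def average_coverage(reports: Sequence[CoverageReport | float]) -> float:
    """Arithmetic mean of coverage percentages, rounded to one decimal."""
    if not reports:
        raise ValueError("need at least one report")
    vals = [r.coverage_pct if isinstance(r, CoverageReport) else float(r) for r in reports]
    return _round_half_up(sum(vals) / len(vals), 1)


def completeness(full_matches: int, total_matches: int) -> float:
    """Share of all matches that are Full matches, as a 2-decimal percent.

    Undefined (raises) when there are no matches at all — a column with
    no matches contributes nothing to either count.
    """
    if total_matches < 1:
        raise ValueError("completeness undefined: no matches")
    if not 0 <= full_matches <= total_matches:
        raise ValueError("need 0 <= full_matches <= total_matches")
    return _round_half_up(100.0 * full_matches / total_matches, 2)


@dataclass
class QualityReport:
    """Data-quality tallies over a dataset's enhanced properties.

    broad_terminology, ontology_hijacking and missing_definition are
    curator judgments on mapped columns; undefined_terminology counts
    columns that kept their auto-minted converter predicate, so it
    always equals total_properties - total_added_properties.
    """

    broad_terminology: int
    ontology_hijacking: int
    undefined_terminology: int
    missing_definition: int
    total_added_properties: int
    total_properties: int

    def __post_init__(self) -> None:
        counts = (
            self.broad_terminology,
            self.ontology_hijacking,
            self.undefined_terminology,
            self.missing_definition,
            self.total_added_properties,
            self.total_properties,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.undefined_terminology != self.total_properties - self.total_added_properties:
            raise ValueError("undefined_terminology must equal TP - TAP")

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


VALID_FLAGS = {"BT", "OH", "MD"}


def quality_tally(
    columns: Sequence[str],
    mapped_columns: Sequence[str],
    flags: Mapping[str, Sequence[str]] | None = None,
) -> QualityReport:
    """Tally quality issues for one enhanced dataset.

    ``columns`` is every column of the dataset; ``mapped_columns`` the
    subset that received a selected ontology property; ``flags`` maps a
    mapped column to curator flags among {BT, OH, MD}. Flagging an
    unmapped column is an error (there is no added property to judge).
    """
    flags = flags or {}
    mapped = set(mapped_columns)
    unknown = mapped - set(columns)
    if unknown:
        raise ValueError(f"mapped columns not in dataset: {sorted(unknown)}")
    tallies = {"BT": 0, "OH": 0, "MD": 0}
    for col, col_flags in flags.items():
        if col not in mapped:
            raise ValueError(f"flag on unmapped column {col!r}")
        for f in col_flags:
            if f not in VALID_FLAGS:
                raise ValueError(f"unknown flag {f!r}")
            tallies[f] += 1
    tp = len(columns)
    tap = len(mapped)
    return QualityReport(
        broad_terminology=tallies["BT"],
        ontology_hijacking=tallies["OH"],
        undefined_terminology=tp - tap,
        missing_definition=tallies["MD"],
        total_added_properties=tap,
        total_properties=tp,
    )


def render_coverage_table(reports: Sequence[CoverageReport], title: str = "Coverage") -> str:
    """Aligned-text table: one row per dataset plus the average row."""
    lines = [title, "Dataset\tMatches\tCoverage"]
    for r in reports:
        lines.append(str(r))
    lines.append(f"Average coverage\t\t{format_pct(average_coverage(reports))}")
    return "\n".join(lines)


def render_quality_table(rows: Mapping[str, QualityReport]) -> str:
    """Aligned-text table of quality tallies (BT OH UT MD TAP TP per row)."""
    lines = ["Dataset\tBT\tOH\tUT\tMD\tTAP\tTP"]
    for name, q in rows.items():
        lines.append(
            f"{name}\t{q.broad_terminology}\t{q.ontology_hijacking}\t"
            f"{q.undefined_terminology}\t{q.missing_definition}\t"
            f"{q.total_added_properties}\t{q.total_properties}"
        )
    return "\n".join(lines)
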