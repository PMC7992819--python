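"""Reading and writing delimited tabular files with a header row.

Datasets arrive as CSV or TSV (the gene nomenclature and chemical–gene
interaction sets use both). Cells are kept as strings; typing is the
encoding layer's job. Comment lines starting with ``#`` before the header
are skipped (the chemical–gene interaction dialect).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class RaggedRowError(ValueError):
    """A data row whose cell count differs from the header's."""

    def __init__(self, row_number: int, expected: int, got: int):
        self.row_number = row_number
        super().__init__(
            f"row {row_number} has {got} cells, expected {expected} (header width)"
        )


@dataclass
class ColumnRecord:
    """One dataset column: header name plus its ordered cell values."""

    name: str
    values: list[str]
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("column name must be non-empty after trimming")


@dataclass
class DatasetProfile:
    """Shape summary of a parsed dataset."""

    dataset_id: str
    n_columns: int
    n_rows: int
    delimiter: str
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_columns <= 0:
            raise ValueError("a dataset must have at least one column")
        if self.n_columns != len(self.column_names):
            raise ValueError("n_columns must equal len(column_names)")


_EXT_DELIMS = {".csv": ",", ".tsv": "\t", ".tab": "\t", ".txt": "\t"}


def _infer_delimiter(path: Path) -> str:
    return _EXT_DELIMS.get(path.suffix.lower(), ",")


def read_table(
    path: str | Path,
    delimiter: str | None = None,
    dataset_id: str | None = None,
    max_rows: int | None = None,
) -> tuple[DatasetProfile, list[ColumnRecord]]:
    """Parse a delimited file into per-column records.

    Parameters
    ----------
    path : file path
        Delimited text file whose first non-comment row is the header.
    delimiter : str, optional
        Auto-detected from the extension (.csv -> comma, .tsv -> tab)
        when not given.
    dataset_id : str, optional
        Defaults to the file stem.
    max_rows : int, optional
        Read at most this many data rows. Exposed because very large
        source files are commonly subsampled for training; no default
        cap is imposed.

    Raises
    ------
    FileNotFoundError
        When the file does not exist.
    RaggedRowError
        When a data row's width differs from the header's, naming the
        1-based physical row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    delim = delimiter if delimiter is not None else _infer_delimiter(path)
    ds_id = dataset_id if dataset_id is not None else path.stem

    # utf-8 with replacement: gene names are occasionally non-ASCII and a
    # stray byte must not abort ingestion.
    with open(path, encoding="utf-8", errors="replace", newline="") as fh:
        lines = fh.read().splitlines(keepends=True)

    # skip comment preamble before the header
    start = 0
    while start < len(lines) and lines[start].startswith("#"):
        start += 1
    if start >= len(lines):
        raise ValueError(f"{path}: no header row found")

    reader = csv.reader(io.StringIO("".join(lines[start:])), delimiter=delim)
    header = next(reader)
    header = [h.strip() for h in header]
    n_cols = len(header)
    columns: list[list[str]] = [[] for _ in header]
    n_rows = 0
    for i, row in enumerate(reader):
        if max_rows is not None and n_rows >= max_rows:
            break
        if not row:  # ignore blank trailing lines
            continue
        if len(row) != n_cols:
            raise RaggedRowError(start + i + 2, n_cols, len(row))
        for col, cell in zip(columns, row):
            col.append(cell)
        n_rows += 1

    records = [ColumnRecord(name=h, values=v, dataset_id=ds_id) for h, v in zip(header, columns)]
    profile = DatasetProfile(
        dataset_id=ds_id,
        n_columns=n_cols,
        n_rows=n_rows,
        delimiter=delim,
        column_names=list(header),
    )
    return profile, records


def write_table(
    path: str | Path,
    columns: Sequence[ColumnRecord],
    delimiter: str | None = None,
) -> None:
    """Write ColumnRecords back to a delimited file (inverse of read_table)."""
    path = Path(path)
    delim = delimiter if delimiter is not None else _infer_delimiter(path)
    if not columns:
        raise ValueError("need at least one column")
    n_rows = len(columns[0].values)
    if any(len(c.values) != n_rows for c in columns):
        raise ValueError("all columns must have the same number of values")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, quoting=csv.QUOTE_MINIMAL)
        writer.writerow([c.name for c in columns])
        for i in range(n_rows):
            writer.writerow([c.values[i] for c in columns])
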