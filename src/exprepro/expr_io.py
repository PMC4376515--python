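"""Reading and writing expression matrices, sample layouts and gene-length tables.

The central container is :class:`ExpressionDataset`: a nonnegative gene × sample
matrix together with a *layout* that maps every sample column to a
``(treatment, replicate)`` pair.  All downstream statistics key on the layout,
never on column order, so permuting columns of the input file changes nothing.

Missing cells are never imputed: a gene whose value is missing in a sample used
by some operation is excluded from that operation and counted in the reported
``n_excluded``.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneLengthTable",
    "read_expression_matrix",
    "read_layout",
    "read_length_table",
    "write_expression_matrix",
    "write_layout",
    "write_length_table",
    "write_report",
]

_DELIMITERS = ("\t", ",", ";")


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    with open(path, newline="") as fh:
        head = fh.readline()
    counts = {d: head.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else "\t"


@dataclass
class ExpressionDataset:
    """Gene × sample expression matrix with a sample layout.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample.  All finite
        values must be nonnegative; NaN marks an explicitly missing cell.
    layout
        Mapping ``sample -> (treatment, replicate)``.  Replicate labels are
        unique within a treatment.
    metadata
        Free-form provenance notes (normalization records, seeds, ...).
    """

    values: pd.DataFrame
    layout: dict[str, tuple[str, str]]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.layout]
        if missing:
            raise ValueError(f"samples absent from layout: {missing}")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("expression values must be nonnegative")
        seen: dict[tuple[str, str], str] = {}
        for sample in self.values.columns:
            key = self.layout[sample]
            if key in seen:
                raise ValueError(
                    f"replicate label {key[1]!r} duplicated within treatment "
                    f"{key[0]!r} (samples {seen[key]!r}, {sample!r})"
                )
            seen[key] = sample

    # -- layout helpers -----------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def treatments(self) -> list[str]:
        out: list[str] = []
        for sample in self.values.columns:
            t = self.layout[sample][0]
            if t not in out:
                out.append(t)
        return out

    def replicates(self, treatment: str) -> list[str]:
        """Replicate labels of one treatment, in sorted order."""
        reps = sorted(
            r for s, (t, r) in self.layout.items()
            if t == treatment and s in self.values.columns
        )
        if not reps:
            raise KeyError(f"unknown treatment: {treatment!r}")
        return reps

    def sample_for(self, treatment: str, replicate: str) -> str:
        for s in self.values.columns:
            if self.layout[s] == (treatment, replicate):
                return s
        raise KeyError(f"no sample for ({treatment!r}, {replicate!r})")

    def column(self, treatment: str, replicate: str) -> pd.Series:
        return self.values[self.sample_for(treatment, replicate)]

    def with_values(self, values: pd.DataFrame, **extra_metadata: Any) -> "ExpressionDataset":
        meta = dict(self.metadata)
        meta.update(extra_metadata)
        return ExpressionDataset(values=values, layout=dict(self.layout), metadata=meta)


@dataclass
class GeneLengthTable:
    """Gene id → length (bp) of the ORF or exon model."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for gene, length in self.lengths.items():
            if int(length) != length or length < 1:
                raise ValueError(f"length for {gene!r} must be a positive integer, got {length!r}")
        self.lengths = {g: int(v) for g, v in self.lengths.items()}

    def __len__(self) -> int:
        return len(self.lengths)

    def __getitem__(self, gene: str) -> int:
        return self.lengths[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.lengths

    def subset(self, genes: Iterable[str]) -> "GeneLengthTable":
        genes = list(genes)
        missing = [g for g in genes if g not in self.lengths]
        if missing:
            raise KeyError(f"genes without a length entry: {missing}")
        return GeneLengthTable({g: self.lengths[g] for g in genes})


def read_layout(path: str | Path, delimiter: str | None = None) -> dict[str, tuple[str, str]]:
    """Read a sidecar layout TSV: columns sample, treatment, replicate."""
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    layout: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if rows and rows[0][0].strip().lower() in {"sample", "sample_id"}:
        rows = rows[1:]
    for row in rows:
        if len(row) < 3:
            raise ValueError(f"layout rows need (sample, treatment, replicate); got {row}")
        sample, treatment, replicate = (c.strip() for c in row[:3])
        if sample in layout:
            raise ValueError(f"duplicate sample in layout: {sample!r}")
        layout[sample] = (treatment, replicate)
    return layout


def read_expression_matrix(
    path: str | Path,
    layout: Mapping[str, tuple[str, str]] | str | Path,
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Read a delimited gene × sample matrix.

    First column holds gene ids, the header row sample names.  Every sample in
    the header must appear in *layout* (a mapping or a sidecar file path).
    Negative values, duplicate gene ids and non-numeric cells are hard errors.
    Empty cells become NaN (explicitly missing).
    """
    path = Path(path)
    if not isinstance(layout, Mapping):
        layout = read_layout(layout, delimiter=delimiter)
    delim = _sniff_delimiter(path, delimiter)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"empty expression matrix: {path}")
    header = [c.strip() for c in rows[0][1:]]
    for sample in header:
        if sample not in layout:
            raise ValueError(f"sample {sample!r} in header missing from layout")
    gene_ids: list[str] = []
    data: list[list[float]] = []
    seen: set[str] = set()
    for i, row in enumerate(rows[1:], start=2):
        gene = row[0].strip()
        if gene in seen:
            raise ValueError(f"duplicate gene id: {gene!r}")
        seen.add(gene)
        vals: list[float] = []
        for j, cell in enumerate(row[1:], start=2):
            cell = cell.strip()
            if cell in {"", "NA", "NaN", "nan"}:
                vals.append(math.nan)
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell at row {i}, column {j} ({gene!r}/{header[j - 2]!r}): {cell!r}"
                ) from None
            if v < 0:
                raise ValueError(f"negative value at row {i}, column {j}: {v}")
            vals.append(v)
        if len(vals) != len(header):
            raise ValueError(f"row {i} has {len(vals)} values, expected {len(header)}")
        gene_ids.append(gene)
        data.append(vals)
    values = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene"), columns=header, dtype=float)
    used_layout = {s: tuple(layout[s]) for s in header}
    return ExpressionDataset(values=values, layout=used_layout, metadata={"source": str(path)})


def read_length_table(path: str | Path, delimiter: str | None = None) -> GeneLengthTable:
    """Read a two-column (gene id, length in bp) table; header row optional."""
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    lengths: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise ValueError(f"length-table rows need (gene, length); got {row}")
        gene, raw = row[0].strip(), row[1].strip()
        if i == 0:
            try:
                float(raw)
            except ValueError:
                continue  # header row
        try:
            length = int(float(raw))
        except ValueError:
            raise ValueError(f"non-integer length for {gene!r}: {raw!r}") from None
        if float(raw) != length:
            raise ValueError(f"non-integer length for {gene!r}: {raw!r}")
        if length <= 0:
            raise ValueError(f"length for {gene!r} must be positive, got {length}")
        if gene in lengths:
            raise ValueError(f"duplicate gene id in length table: {gene!r}")
        lengths[gene] = length
    return GeneLengthTable(lengths)


# -- writing ----------------------------------------------------------------

def _fmt(v: Any) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))  # shortest representation that round-trips exactly
    return str(v)


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["gene", *dataset.values.columns])
        for gene, row in dataset.values.iterrows():
            writer.writerow([gene, *("" if math.isnan(v) else _fmt(float(v)) for v in row)])


def write_layout(layout: Mapping[str, tuple[str, str]], path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["sample", "treatment", "replicate"])
        for sample, (treatment, replicate) in layout.items():
            writer.writerow([sample, treatment, replicate])


def write_length_table(table: GeneLengthTable, path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["gene", "length_bp"])
        for gene, length in table.lengths.items():
            writer.writerow([gene, length])


def _result_rows(result: Any) -> tuple[list[str], list[list[Any]], dict[str, Any]]:
    """Split a result object into (header, detail rows, summary scalars)."""
    detail_attrs = {
        "comparisons": None, "populations": None, "fold_changes": None,
        "per_gene": None,
    }
    summary: dict[str, Any] = {}
    header: list[str] = []
    rows: list[list[Any]] = []
    for f in dataclasses.fields(result):
        value = getattr(result, f.name)
        if f.name in detail_attrs and value is not None:
            if isinstance(value, pd.DataFrame):
                header = [str(c) for c in value.columns]
                rows = value.values.tolist()
            elif isinstance(value, (list, tuple, np.ndarray)):
                header = [f.name]
                rows = [[v] for v in value]
        elif isinstance(value, (int, float, str, bool)) or value is None:
            summary[f.name] = value
        elif isinstance(value, (list, tuple)) and len(value) <= 24:
            summary[f.name] = ",".join(_fmt(v) for v in value)
    return header, rows, summary


def write_report(result: Any, path: str | Path, format: str = "tabular") -> None:
    """Serialize a result dataclass as TSV (``tabular``) or key-value text.

    Numeric precision is full double precision, well above six significant
    digits, so reports round-trip.
    """
    if not dataclasses.is_dataclass(result) or isinstance(result, type):
        raise TypeError(f"cannot serialize object of type {type(result).__name__}")
    if format not in {"tabular", "structured-text"}:
        raise ValueError(f"unknown report format: {format!r}")
    path = Path(path)
    header, rows, summary = _result_rows(result)
    with open(path, "w", newline="") as fh:
        if format == "structured-text":
            for k, v in summary.items():
                fh.write(f"{k}\t{_fmt(v)}\n")
            return
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for k, v in summary.items():
            writer.writerow([f"# {k}", _fmt(v)])
        if header:
            writer.writerow(header)
            for row in rows:
                writer.writerow([_fmt(v) for v in row])
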