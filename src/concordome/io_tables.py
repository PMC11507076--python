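"""Readers and writers for the tabular formats the pipeline touches.

Quantification tables are tab-separated with a header row, in the style of
RSEM ``*.genes.results`` / ``*.isoforms.results`` output: one identifier
column and one abundance column (RPKM for sequencing layers, LFQ intensity
for proteomics).  Gene universes are plain text, one symbol per line.

Gene symbols are whitespace-stripped and upper-cased on ingest so that
tables from different quantifiers join on a single canonical case.  Zero
abundances are retained — detection is decided later by thresholding,
never at parse time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "QuantTable",
    "IsoformTable",
    "GeneUniverse",
    "TableFormatError",
    "read_quant_table",
    "read_gene_universe",
    "read_annotation_table",
    "write_quant_table",
    "write_gene_universe",
    "write_report",
]


class TableFormatError(ValueError):
    """Raised when an input table violates the format contract."""


def _canon(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class QuantTable:
    """One abundance value per gene for a single omic layer.

    Parameters
    ----------
    layer_label:
        Free-text name of the layer/method (e.g. ``"RNC-seq"``).
    values:
        Mapping gene symbol -> abundance.  Every abundance is finite and
        non-negative; symbols are unique and upper-cased.
    unit_kind:
        ``"RPKM"`` for sequencing layers, ``"LFQ"`` for proteome tables.
    """

    layer_label: str
    values: Mapping[str, float]
    unit_kind: str = "RPKM"

    def __post_init__(self) -> None:
        if self.unit_kind not in ("RPKM", "LFQ"):
            raise ValueError(f"unit_kind must be RPKM or LFQ, got {self.unit_kind!r}")
        for sym, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"abundance for {sym} must be finite and >= 0, got {v!r}"
                )

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, symbol: str) -> float:
        return self.values[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.values

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self.values)


@dataclass(frozen=True)
class IsoformTable:
    """Isoform-level rows ``(isoform_id, gene_symbol, rpkm)``.

    A gene symbol may appear in several rows; :func:`~concordome.gene_centric.pool_isoforms`
    collapses them to one value per gene.
    """

    layer_label: str
    rows: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        for iso, sym, v in self.rows:
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"RPKM for isoform {iso} ({sym}) must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        return iter(self.rows)


@dataclass(frozen=True)
class GeneUniverse:
    """The fixed ordered set of protein-coding gene symbols.

    Defines the denominator for every coverage percentage downstream.
    """

    symbols: tuple[str, ...]
    _index: frozenset[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ValueError("gene universe is empty")
        idx = frozenset(self.symbols)
        if len(idx) != len(self.symbols):
            raise ValueError("gene universe contains duplicate symbols")
        object.__setattr__(self, "_index", idx)

    @classmethod
    def from_iterable(cls, symbols: Iterable[str]) -> "GeneUniverse":
        seen: dict[str, None] = {}
        for s in symbols:
            c = _canon(s)
            if c and c not in seen:
                seen[c] = None
        return cls(tuple(seen))

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)


def _read_tsv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise TableFormatError(
                f"{path}: column {col!r} not found (header: {list(df.columns)})"
            )
    return df


def _parse_values(df: pd.DataFrame, value_column: str, path: Path) -> list[float]:
    out: list[float] = []
    for i, raw in enumerate(df[value_column], start=2):  # row 1 is the header
        try:
            v = float(raw)
        except ValueError:
            raise TableFormatError(
                f"{path}: non-numeric value {raw!r} in column {value_column!r} at row {i}"
            ) from None
        if not math.isfinite(v) or v < 0:
            raise TableFormatError(
                f"{path}: value {raw!r} in column {value_column!r} at row {i} "
                "must be finite and >= 0"
            )
        out.append(v)
    return out


def read_quant_table(
    path: str | Path,
    id_column: str = "gene",
    value_column: str = "rpkm",
    gene_column: str | None = None,
    layer_label: str | None = None,
    unit_kind: str = "RPKM",
) -> QuantTable | IsoformTable:
    """Read a tab-separated quantification table.

    When ``gene_column`` is given the file is treated as isoform-level
    (``id_column`` holds transcript ids, ``gene_column`` the parent gene)
    and an :class:`IsoformTable` is returned; otherwise ``id_column`` holds
    gene symbols and a :class:`QuantTable` is returned.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    TableFormatError
        On a missing column, or a non-numeric or negative abundance
        (the message names the offending row).
    """
    path = Path(path)
    label = layer_label if layer_label is not None else path.stem
    required = [id_column, value_column] + ([gene_column] if gene_column else [])
    df = _read_tsv(path, required)
    vals = _parse_values(df, value_column, path)

    if gene_column is not None:
        rows = tuple(
            (iso.strip(), _canon(sym), v)
            for iso, sym, v in zip(df[id_column], df[gene_column], vals)
        )
        return IsoformTable(layer_label=label, rows=rows)

    values: dict[str, float] = {}
    for i, (sym, v) in enumerate(zip(df[id_column], vals), start=2):
        c = _canon(sym)
        if c in values:
            raise TableFormatError(
                f"{path}: duplicate gene symbol {c!r} at row {i}; "
                "isoform-level tables need gene_column so they can be pooled"
            )
        values[c] = v
    return QuantTable(layer_label=label, values=values, unit_kind=unit_kind)


def read_gene_universe(path: str | Path) -> GeneUniverse:
    """Read a gene universe: one symbol per line, blank lines ignored.

    Symbols are upper-cased and deduplicated, first-seen order preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise TableFormatError(f"{path}: gene universe file is empty")
    return GeneUniverse.from_iterable(lines)


def read_annotation_table(
    path: str | Path,
    gene_column: str = "gene",
    length_column: str = "canonical_length",
    gc_column: str = "gc_percent",
) -> pd.DataFrame:
    """Read a transcript annotation table (gene, canonical length, GC%).

    Returns a DataFrame indexed by upper-cased gene symbol with columns
    ``canonical_length`` and ``gc_percent``.
    """
    df = _read_tsv(path, [gene_column, length_column, gc_column])
    out = pd.DataFrame(
        {
            "canonical_length": pd.to_numeric(df[length_column]),
            "gc_percent": pd.to_numeric(df[gc_column]),
        },
        index=[_canon(s) for s in df[gene_column]],
    )
    return out[~out.index.duplicated(keep="first")]


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    """Write a :class:`QuantTable` as a two-column TSV readable by
    :func:`read_quant_table`."""
    value_col = "rpkm" if table.unit_kind == "RPKM" else "lfq"
    lines = [f"gene\t{value_col}"]
    lines += [f"{g}\t{v!r}" for g, v in table.values.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_gene_universe(universe: GeneUniverse, path: str | Path) -> None:
    Path(path).write_text("\n".join(universe.symbols) + "\n")


def write_report(results, path: str | Path, format: str = "tsv") -> None:
    """Serialize a result object deterministically.

    Any result type exposing ``to_tsv()`` / ``to_jsonable()`` is accepted
    (Tanimoto profiles, Venn partitions, correlation results, copy-class
    histograms, portraits, cross-omic matrices).  Similarities are printed
    with 4 decimals and percentages with 1, so re-running the pipeline on
    the same inputs yields byte-identical files.
    """
    path = Path(path)
    if format == "tsv":
        if not hasattr(results, "to_tsv"):
            raise TypeError(f"{type(results).__name__} has no TSV serialization")
        path.write_text(results.to_tsv())
    elif format == "json":
        if not hasattr(results, "to_jsonable"):
            raise TypeError(f"{type(results).__name__} has no JSON serialization")
        path.write_text(json.dumps(results.to_jsonable(), indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'tsv' or 'json')")


def fmt_threshold(t: float) -> str:
    """Render a threshold compactly (0 not 0.0, 0.1 not 0.10)."""
    return f"{t:g}"


def fmt_similarity(s: float) -> str:
    return f"{s:.4f}"


def fmt_percent(p: float) -> str:
    return f"{p:.1f}"
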