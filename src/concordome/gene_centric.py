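"""Gene-centric reduction: isoform pooling, universe restriction,
threshold detection sets and coverage percentages.

All coverage figures downstream are fractions of a fixed protein-coding
gene universe, so every table is restricted to that universe before any
set arithmetic.  Detection at a threshold ``t`` means abundance strictly
greater than ``t`` ("RPKM > t"); at ``t = 0`` this excludes exact zeros,
which is why detected counts are below the universe size.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

from .io_tables import GeneUniverse, IsoformTable, QuantTable

__all__ = [
    "GeneSet",
    "Restricted",
    "THRESHOLD_LADDER",
    "pool_isoforms",
    "restrict_to_universe",
    "detected_set",
    "coverage_percent",
]

#: Default RPKM cutoff ladder for threshold sweeps.
THRESHOLD_LADDER: tuple[float, ...] = (0.0, 0.1, 1.0, 5.0, 10.0)


@dataclass(frozen=True)
class GeneSet:
    """A detection set: genes whose abundance exceeds a threshold."""

    label: str
    threshold: float
    symbols: frozenset[str]

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


class Restricted(NamedTuple):
    """A universe-restricted table plus the number of genes dropped."""

    table: QuantTable
    dropped: int


def pool_isoforms(iso: IsoformTable, method: str = "sum") -> QuantTable:
    """Collapse isoform-level RPKM to one value per gene.

    The default pools splice variants by summing their RPKM, which
    conserves read mass (a gene's RPKM is the total over its transcripts,
    as in RSEM gene-level output).  ``method="max"`` keeps the dominant
    isoform instead.
    """
    if len(iso) == 0:
        raise ValueError("isoform table is empty")
    if method not in ("sum", "max"):
        raise ValueError(f"pooling method must be 'sum' or 'max', got {method!r}")
    pooled: dict[str, float] = {}
    for _iso_id, gene, rpkm in iso:
        if gene in pooled:
            pooled[gene] = pooled[gene] + rpkm if method == "sum" else max(pooled[gene], rpkm)
        else:
            pooled[gene] = rpkm
    return QuantTable(layer_label=iso.layer_label, values=pooled, unit_kind="RPKM")


def restrict_to_universe(table: QuantTable, universe: GeneUniverse) -> Restricted:
    """Drop genes outside the universe; report how many were dropped."""
    kept = {g: v for g, v in table.values.items() if g in universe}
    restricted = QuantTable(
        layer_label=table.layer_label, values=kept, unit_kind=table.unit_kind
    )
    return Restricted(restricted, len(table) - len(kept))


def detected_set(table: QuantTable, threshold: float, label: str | None = None) -> GeneSet:
    """Genes with abundance strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    symbols = frozenset(g for g, v in table.values.items() if v > threshold)
    return GeneSet(
        label=label if label is not None else table.layer_label,
        threshold=float(threshold),
        symbols=symbols,
    )


def coverage_percent(detected_count: int, universe_size: int) -> float:
    """Percentage of the universe detected, to one decimal place.

    Rounding is half-away-from-zero on exact decimal arithmetic, so
    e.g. 16,655 of 20,423 genes is 81.55...% and prints as 81.6 — binary
    floating point would sometimes round such halves the other way.
    """
    if universe_size <= 0:
        raise ValueError("universe_size must be > 0")
    if not 0 <= detected_count <= universe_size:
        raise ValueError(
            f"detected_count {detected_count} outside [0, {universe_size}]"
        )
    pct = (Decimal(detected_count) * 100 / Decimal(universe_size)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(pct)
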