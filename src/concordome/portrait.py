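"""Copy-class histograms and the gene-centric multiomic portrait.

The portrait is a per-gene boolean matrix over three omic layers —
transcriptome (RNA-seq), translatome (RNC-seq or Ribo-seq) and proteome
(LC-MS/MS) — evaluated over the whole protein-coding universe, so its
eight flag categories partition the universe exactly.  Copy classes bin
positive RPKM values into half-open decade-style intervals separating
low-, medium- and high-copy genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .concordance import classify_similarity, tanimoto
from .gene_centric import GeneSet, coverage_percent, detected_set
from .io_tables import GeneUniverse, QuantTable, fmt_percent, fmt_similarity, fmt_threshold

__all__ = [
    "DEFAULT_COPY_CLASSES",
    "CopyClassBins",
    "PortraitMatrix",
    "CrossOmicMatrix",
    "PORTRAIT_CATEGORIES",
    "copy_class_histogram",
    "build_portrait",
    "cross_omic_tanimoto_matrix",
]

#: (low, high] RPKM intervals: low-copy (0.1, 1], medium (1, 10], (10, 100],
#: high-copy (100, 1000], (1000, 10000].
DEFAULT_COPY_CLASSES: tuple[tuple[float, float], ...] = (
    (0.1, 1.0),
    (1.0, 10.0),
    (10.0, 100.0),
    (100.0, 1000.0),
    (1000.0, 10000.0),
)


@dataclass(frozen=True)
class CopyClassBins:
    """Histogram of positive abundances over (low, high] intervals.

    Genes with 0 < value <= lowest bound fall in ``below_range_count``;
    values above the top bound are counted in the top bin and reported
    in ``above_range_count``.  Bin counts plus the below-range count
    equal the number of genes with positive abundance.
    """

    layer_label: str
    intervals: tuple[tuple[float, float], ...]
    counts: tuple[int, ...]
    below_range_count: int
    above_range_count: int
    n_positive: int

    def to_tsv(self) -> str:
        lines = ["interval\tcount"]
        lines.append(f"(0,{fmt_threshold(self.intervals[0][0])}]\t{self.below_range_count}")
        for (lo, hi), c in zip(self.intervals, self.counts):
            lines.append(f"({fmt_threshold(lo)},{fmt_threshold(hi)}]\t{c}")
        return "\n".join(lines) + "\n"

    def to_jsonable(self) -> dict:
        return {
            "layer": self.layer_label,
            "intervals": [list(iv) for iv in self.intervals],
            "counts": list(self.counts),
            "below_range_count": self.below_range_count,
            "above_range_count": self.above_range_count,
            "n_positive": self.n_positive,
        }


def copy_class_histogram(
    table: QuantTable,
    intervals: tuple[tuple[float, float], ...] = DEFAULT_COPY_CLASSES,
) -> CopyClassBins:
    """Assign each positively-expressed gene to exactly one copy class."""
    intervals = tuple((float(lo), float(hi)) for lo, hi in intervals)
    if not intervals:
        raise ValueError("no intervals given")
    for lo, hi in intervals:
        if not lo < hi:
            raise ValueError(f"interval ({lo}, {hi}] is empty or inverted")
    for (_, hi1), (lo2, _) in zip(intervals, intervals[1:]):
        if lo2 != hi1:
            raise ValueError("intervals must be sorted, non-overlapping and contiguous")

    counts = [0] * len(intervals)
    below = above = positive = 0
    lowest = intervals[0][0]
    top = intervals[-1][1]
    for v in table.values.values():
        if v <= 0:
            continue
        positive += 1
        if v <= lowest:
            below += 1
            continue
        if v > top:
            above += 1
            counts[-1] += 1  # flagged via above_range_count
            continue
        for i, (lo, hi) in enumerate(intervals):
            if lo < v <= hi:
                counts[i] += 1
                break
    return CopyClassBins(
        layer_label=table.layer_label,
        intervals=intervals,
        counts=tuple(counts),
        below_range_count=below,
        above_range_count=above,
        n_positive=positive,
    )


#: Flag order is (transcriptome, translatome, proteome).
PORTRAIT_CATEGORIES: dict[tuple[bool, bool, bool], str] = {
    (True, True, True): "all_levels",
    (True, True, False): "transcribed_and_translated_no_protein",
    (True, False, True): "transcribed_with_protein_no_translation",
    (False, True, True): "translated_with_protein_no_transcript",
    (True, False, False): "transcript_only",
    (False, True, False): "translated_only",
    (False, False, True): "protein_only",
    (False, False, False): "genome_only",
}


@dataclass(frozen=True)
class PortraitMatrix:
    """Per-gene detection flags across omic layers, over the universe.

    ``flags`` is a boolean DataFrame indexed by gene with columns
    transcriptome/translatome/proteome.  Category counts partition the
    universe; fractions are percentages of the universe and sum to 100
    up to 1-decimal rounding.
    """

    universe: GeneUniverse
    flags: pd.DataFrame
    layer_labels: dict[str, str]
    category_counts: dict[str, int]
    category_fractions: dict[str, float]

    def to_jsonable(self) -> dict:
        return {
            "universe_size": self.universe.size,
            "layer_labels": dict(self.layer_labels),
            "layer_coverage_percent": {
                layer: coverage_percent(int(self.flags[layer].sum()), self.universe.size)
                for layer in self.flags.columns
            },
            "category_counts": dict(self.category_counts),
            "category_fractions": dict(self.category_fractions),
        }

    def to_tsv(self) -> str:
        lines = ["category\tcount\tpercent"]
        for cat, n in self.category_counts.items():
            lines.append(f"{cat}\t{n}\t{fmt_percent(self.category_fractions[cat])}")
        return "\n".join(lines) + "\n"


def build_portrait(
    rna: QuantTable,
    translatome: QuantTable,
    proteome: QuantTable | None,
    universe: GeneUniverse,
    rpkm_threshold: float = 0.0,
    lfq_threshold: float = 0.0,
) -> PortraitMatrix:
    """Classify every gene of the universe by which layers detect it.

    ``proteome`` may be ``None`` (no proteomics run for the sample); the
    proteome flags are then all false and genes land in the remaining
    categories.
    """
    t_set = detected_set(rna, rpkm_threshold).symbols
    l_set = detected_set(translatome, rpkm_threshold).symbols
    p_set = (
        detected_set(proteome, lfq_threshold).symbols
        if proteome is not None
        else frozenset()
    )
    genes = list(universe)
    flags = pd.DataFrame(
        {
            "transcriptome": [g in t_set for g in genes],
            "translatome": [g in l_set for g in genes],
            "proteome": [g in p_set for g in genes],
        },
        index=genes,
    )
    counts = {cat: 0 for cat in PORTRAIT_CATEGORIES.values()}
    for t, l, p in flags.itertuples(index=False):
        counts[PORTRAIT_CATEGORIES[(t, l, p)]] += 1
    fractions = {
        cat: coverage_percent(n, universe.size) for cat, n in counts.items()
    }
    return PortraitMatrix(
        universe=universe,
        flags=flags,
        layer_labels={
            "transcriptome": rna.layer_label,
            "translatome": translatome.layer_label,
            "proteome": proteome.layer_label if proteome is not None else "none",
        },
        category_counts=counts,
        category_fractions=fractions,
    )


@dataclass(frozen=True)
class CrossOmicMatrix:
    """Pairwise Tanimoto similarities across layers at each RPKM cutoff.

    Proteome (LFQ) tables are always thresholded at intensity > 0
    regardless of the RPKM cutoff, since LFQ intensities are not on the
    RPKM scale.  Each per-cutoff matrix is symmetric with unit diagonal.
    """

    labels: tuple[str, ...]
    thresholds: tuple[float, ...]
    similarities: dict[float, dict[tuple[str, str], float]]

    def value(self, threshold: float, a: str, b: str) -> float:
        return self.similarities[threshold][(a, b)]

    def band(self, threshold: float, a: str, b: str) -> str:
        return classify_similarity(self.value(threshold, a, b))

    def to_jsonable(self) -> dict:
        return {
            "labels": list(self.labels),
            "thresholds": list(self.thresholds),
            "matrices": {
                fmt_threshold(t): [
                    [round(self.similarities[t][(a, b)], 4) for b in self.labels]
                    for a in self.labels
                ]
                for t in self.thresholds
            },
        }

    def to_tsv(self) -> str:
        lines = ["threshold\tlayer_a\tlayer_b\tsimilarity\tband"]
        for t in self.thresholds:
            for i, a in enumerate(self.labels):
                for b in self.labels[i + 1 :]:
                    s = self.similarities[t][(a, b)]
                    lines.append(
                        f"{fmt_threshold(t)}\t{a}\t{b}\t{fmt_similarity(s)}\t"
                        f"{classify_similarity(s)}"
                    )
        return "\n".join(lines) + "\n"


def cross_omic_tanimoto_matrix(
    tables, thresholds=(0.0, 1.0, 10.0)
) -> CrossOmicMatrix:
    """Tanimoto similarity between every pair of layers at each cutoff.

    ``tables`` is a sequence of :class:`~concordome.io_tables.QuantTable`
    (their ``layer_label`` names the rows/columns).
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least 2 tables")
    labels = tuple(t.layer_label for t in tables)
    if len(set(labels)) != len(labels):
        raise ValueError("layer labels must be unique")
    thresholds = tuple(float(t) for t in thresholds)
    sims: dict[float, dict[tuple[str, str], float]] = {}
    for t in thresholds:
        sets = {
            tab.layer_label: detected_set(tab, 0.0 if tab.unit_kind == "LFQ" else t)
            for tab in tables
        }
        m: dict[tuple[str, str], float] = {}
        for a in labels:
            for b in labels:
                m[(a, b)] = tanimoto(sets[a], sets[b])
        sims[t] = m
    return CrossOmicMatrix(labels=labels, thresholds=thresholds, similarities=sims)
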