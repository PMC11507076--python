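"""Concordance statistics between two detection methods.

The central statistic is the Tanimoto (Jaccard) coefficient between two
gene detection sets,

    T(a, b) = |a ∩ b| / (|a| + |b| - |a ∩ b|),

swept over an RPKM cutoff ladder, with the conventional interpretation
bands: T >= 0.7 "identical", 0.55 <= T < 0.7 "weakly similar",
T < 0.55 "significantly different".  Quantitative agreement between two
methods is measured on genes detected by both, as Spearman rank
correlation and Pearson correlation of log10 abundances, with a
permutation p-value (exact enumeration at very small n).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gene_centric import GeneSet, detected_set
from .io_tables import (
    QuantTable,
    fmt_percent,
    fmt_similarity,
    fmt_threshold,
)

__all__ = [
    "BAND_IDENTICAL",
    "BAND_WEAK",
    "BAND_DIFFERENT",
    "TanimotoProfile",
    "ProfileRow",
    "VennPartition",
    "CorrelationResult",
    "UniqueSetSummary",
    "tanimoto",
    "classify_similarity",
    "tanimoto_profile",
    "venn_counts",
    "log_rpkm_correlation",
    "annotate_unique_transcripts",
]

BAND_IDENTICAL = "identical"
BAND_WEAK = "weakly_similar"
BAND_DIFFERENT = "significantly_different"


def _symbols(s: GeneSet | frozenset[str] | set[str]) -> frozenset[str]:
    return s.symbols if isinstance(s, GeneSet) else frozenset(s)


def tanimoto(a, b) -> float:
    """Tanimoto/Jaccard similarity of two gene sets, in [0, 1].

    Two empty sets are identical by convention, so T(∅, ∅) = 1.0.
    """
    sa, sb = _symbols(a), _symbols(b)
    inter = len(sa & sb)
    union = len(sa) + len(sb) - inter
    if union == 0:
        return 1.0
    return inter / union


def classify_similarity(t: float) -> str:
    """Map a Tanimoto value to its interpretation band.

    Each stated range is closed on its upper edge: 0.7 belongs to
    "identical" and 0.55 to "weakly similar".
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"similarity {t} outside [0, 1]")
    if t >= 0.7:
        return BAND_IDENTICAL
    if t >= 0.55:
        return BAND_WEAK
    return BAND_DIFFERENT


@dataclass(frozen=True)
class ProfileRow:
    threshold: float
    similarity: float
    band: str
    both_empty: bool = False


@dataclass(frozen=True)
class TanimotoProfile:
    """Tanimoto similarity at each cutoff of a threshold ladder."""

    label_a: str
    label_b: str
    rows: tuple[ProfileRow, ...]

    def to_tsv(self) -> str:
        lines = ["threshold\tsimilarity\tband"]
        lines += [
            f"{fmt_threshold(r.threshold)}\t{fmt_similarity(r.similarity)}\t{r.band}"
            for r in self.rows
        ]
        return "\n".join(lines) + "\n"

    def to_jsonable(self) -> dict:
        return {
            "labels": [self.label_a, self.label_b],
            "rows": [
                {
                    "threshold": r.threshold,
                    "similarity": round(r.similarity, 4),
                    "band": r.band,
                    "both_empty": r.both_empty,
                }
                for r in self.rows
            ],
        }


def tanimoto_profile(
    table_a: QuantTable,
    table_b: QuantTable,
    thresholds=(0.0, 0.1, 1.0, 5.0, 10.0),
) -> TanimotoProfile:
    """Sweep the cutoff ladder and band each similarity."""
    thresholds = tuple(thresholds)
    if len(thresholds) == 0:
        raise ValueError("threshold ladder is empty")
    if any(t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    rows = []
    for t in thresholds:
        a = detected_set(table_a, t)
        b = detected_set(table_b, t)
        sim = tanimoto(a, b)
        rows.append(
            ProfileRow(
                threshold=float(t),
                similarity=sim,
                band=classify_similarity(sim),
                both_empty=(len(a) == 0 and len(b) == 0),
            )
        )
    return TanimotoProfile(table_a.layer_label, table_b.layer_label, tuple(rows))


@dataclass(frozen=True)
class VennPartition:
    """Exclusive region counts for 2 or 3 detection sets.

    ``region_counts`` is keyed by membership pattern in set order:
    ``"10"`` = only the first set, ``"11"`` = both, and for three sets
    ``"101"`` = first and third but not second, etc.  The exclusive
    counts always sum to ``union_total``.
    """

    labels: tuple[str, ...]
    region_counts: dict[str, int]
    union_total: int

    def count(self, pattern: str) -> int:
        return self.region_counts[pattern]

    def set_size(self, index: int) -> int:
        """Reconstruct an input set's size from the exclusive regions."""
        return sum(c for p, c in self.region_counts.items() if p[index] == "1")

    def to_jsonable(self) -> dict:
        return {
            "labels": list(self.labels),
            "region_counts": dict(self.region_counts),
            "union_total": self.union_total,
        }

    def to_tsv(self) -> str:
        lines = ["region\tcount"]
        lines += [f"{p}\t{c}" for p, c in self.region_counts.items()]
        lines.append(f"union\t{self.union_total}")
        return "\n".join(lines) + "\n"


def venn_counts(sets) -> VennPartition:
    """Partition 2 or 3 gene sets into exclusive Venn regions."""
    sets = list(sets)
    if len(sets) not in (2, 3):
        raise ValueError(f"venn_counts takes 2 or 3 sets, got {len(sets)}")
    labels = tuple(
        s.label if isinstance(s, GeneSet) else f"set{i}" for i, s in enumerate(sets)
    )
    members = [_symbols(s) for s in sets]
    union = frozenset().union(*members)
    counts: dict[str, int] = {}
    for bits in itertools.product((1, 0), repeat=len(sets)):
        if not any(bits):
            continue
        pattern = "".join(map(str, bits))
        region = union
        for m, bit in zip(members, bits):
            region = region & m if bit else region - m
        counts[pattern] = len(region)
    return VennPartition(labels=labels, region_counts=counts, union_total=len(union))


@dataclass(frozen=True)
class CorrelationResult:
    """Rank and log-scale correlation between two methods' abundances.

    Computed only over genes detected (value > threshold) in *both*
    tables.  ``p_value`` is a permutation p-value for the Spearman
    statistic; when ``exact`` is true all n! orderings were enumerated,
    otherwise ``n_permutations`` random permutations were drawn from
    ``seed`` with an add-one correction.
    """

    n_shared: int
    spearman_rho: float
    pearson_r_log10: float
    r_squared: float
    p_value: float
    n_permutations: int
    exact: bool
    seed: int

    def to_jsonable(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "spearman_rho": round(self.spearman_rho, 4),
            "pearson_r_log10": round(self.pearson_r_log10, 4),
            "r_squared": round(self.r_squared, 4),
            "p_value": round(self.p_value, 6),
            "n_permutations": self.n_permutations,
            "exact": self.exact,
            "seed": self.seed,
        }

    def to_tsv(self) -> str:
        j = self.to_jsonable()
        lines = ["statistic\tvalue"]
        lines += [f"{k}\t{v}" for k, v in j.items()]
        return "\n".join(lines) + "\n"


def _norm_ranks(values: np.ndarray) -> np.ndarray:
    r = stats.rankdata(values)  # mid-ranks for ties
    r = r - r.mean()
    norm = math.sqrt(float(r @ r))
    if norm == 0:
        raise ValueError("constant values: rank correlation undefined")
    return r / norm


def log_rpkm_correlation(
    table_a: QuantTable,
    table_b: QuantTable,
    threshold: float = 0.0,
    n_permutations: int = 9999,
    seed: int = 0,
) -> CorrelationResult:
    """Correlate log10 abundances of genes detected by both methods.

    Spearman rho uses mid-ranks; Pearson r is computed on log10 values
    (applied after thresholding, so zeros never reach the log) and
    ``r_squared`` is its square.  The permutation test shuffles one
    table's values: all n! orderings are enumerated when n <= 8,
    otherwise ``n_permutations`` seeded draws with the add-one
    correction p = (1 + #{|rho*| >= |rho|}) / (1 + N).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    shared = sorted(
        g
        for g, v in table_a.values.items()
        if v > threshold and table_b.values.get(g, 0.0) > threshold
    )
    n = len(shared)
    if n < 3:
        raise ValueError(f"only {n} genes detected in both tables; need >= 3")

    x = np.log10([table_a.values[g] for g in shared])
    y = np.log10([table_b.values[g] for g in shared])

    zx, zy = _norm_ranks(x), _norm_ranks(y)
    rho = float(zx @ zy)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant log10 values: Pearson correlation undefined")
    pearson = float(np.corrcoef(x, y)[0, 1])

    obs = abs(rho) - 1e-12  # guard against permutations tied with the observed rho
    if n <= 8:
        total = math.factorial(n)
        hits = sum(1 for perm in itertools.permutations(zy) if abs(zx @ np.array(perm)) >= obs)
        p_value = hits / total
        n_used, exact = total, True
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            hits += abs(zx @ rng.permutation(zy)) >= obs
        p_value = (1 + hits) / (1 + n_permutations)
        n_used, exact = n_permutations, False

    return CorrelationResult(
        n_shared=n,
        spearman_rho=rho,
        pearson_r_log10=pearson,
        r_squared=pearson * pearson,
        p_value=float(p_value),
        n_permutations=n_used,
        exact=exact,
        seed=seed,
    )


@dataclass(frozen=True)
class UniqueSetSummary:
    """Descriptive annotation of a method-unique gene set."""

    label: str
    n_annotated: int
    missing: tuple[str, ...]
    median_gc_percent: float
    mean_length: float
    max_length_gene: str
    max_length: float

    def to_jsonable(self) -> dict:
        return {
            "label": self.label,
            "n_annotated": self.n_annotated,
            "n_missing": len(self.missing),
            "median_gc_percent": round(self.median_gc_percent, 1),
            "mean_length": round(self.mean_length, 1),
            "max_length_gene": self.max_length_gene,
            "max_length": self.max_length,
        }

    def to_tsv(self) -> str:
        j = self.to_jsonable()
        lines = ["statistic\tvalue"]
        lines += [f"{k}\t{v}" for k, v in j.items()]
        return "\n".join(lines) + "\n"


def annotate_unique_transcripts(unique: GeneSet, annotations) -> UniqueSetSummary:
    """Summarise GC content and canonical transcript length of a
    method-unique set.

    ``annotations`` is a DataFrame indexed by gene symbol with columns
    ``canonical_length`` and ``gc_percent`` (see
    :func:`~concordome.io_tables.read_annotation_table`).  Genes absent
    from the annotation are reported in ``missing`` and skipped.
    """
    present = sorted(g for g in unique.symbols if g in annotations.index)
    missing = tuple(sorted(unique.symbols - set(present)))
    if not present:
        raise ValueError("no gene of the unique set is annotated")
    sub = annotations.loc[present]
    lengths = sub["canonical_length"].to_numpy(dtype=float)
    imax = int(np.argmax(lengths))
    return UniqueSetSummary(
        label=unique.label,
        n_annotated=len(present),
        missing=missing,
        median_gc_percent=float(np.median(sub["gc_percent"].to_numpy(dtype=float))),
        mean_length=float(lengths.mean()),
        max_length_gene=present[imax],
        max_length=float(lengths[imax]),
    )
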