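from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from concordome.concordance import (
    annotate_unique_transcripts,
    classify_similarity,
    log_rpkm_correlation,
    tanimoto,
    tanimoto_profile,
    venn_counts,
)
from concordome.gene_centric import GeneSet
from concordome.io_tables import QuantTable

elements = st.sets(st.integers(min_value=0, max_value=30), max_size=15)


def brute_force_tanimoto(a: set, b: set) -> float:
    """Independent oracle: count membership element by element."""
    union = a | b
    inter = sum(1 for x in union if x in a and x in b)
    return inter / len(union) if union else 1.0


class TestTanimoto:
    def test_identical_sets(self):
        s = GeneSet("a", 0, frozenset("ABC"))
        assert tanimoto(s, s) == 1.0

    def test_disjoint_sets(self):
        assert tanimoto(frozenset("AB"), frozenset("CD")) == 0.0

    def test_hand_evaluated_formula(self):
        a = frozenset(range(5))
        b = frozenset(range(2, 6))  # |a|=5, |b|=4, |a∩b|=3
        assert tanimoto(a, b) == 3 / (5 + 4 - 3) == 0.5

    def test_both_empty_convention(self):
        assert tanimoto(frozenset(), frozenset()) == 1.0

    @given(elements, elements)
    def test_matches_brute_force_and_is_symmetric(self, a, b):
        t = tanimoto(a, b)
        assert t == pytest.approx(brute_force_tanimoto(a, b))
        assert t == tanimoto(b, a)
        assert 0.0 <= t <= 1.0


class TestClassifySimilarity:
    @pytest.mark.parametrize(
        "t, band",
        [
            (0.89, "identical"),
            (0.7, "identical"),
            (0.69, "weakly_similar"),
            (0.55, "weakly_similar"),
            (0.54, "significantly_different"),
            (0.0, "significantly_different"),
        ],
    )
    def test_bands(self, t, band):
        assert classify_similarity(t) == band

    @pytest.mark.parametrize("t", [-0.1, 1.1])
    def test_out_of_range_rejected(self, t):
        with pytest.raises(ValueError):
            classify_similarity(t)


class TestTanimotoProfile:
    def test_identical_tables_give_unit_profile(self, small_table):
        profile = tanimoto_profile(small_table, small_table)
        assert len(profile.rows) == 5  # default ladder 0, 0.1, 1, 5, 10
        assert all(r.similarity == 1.0 for r in profile.rows)

    def test_mcf7_like_counts_give_092(self):
        # intersection 15,676 with uniques 688/675 -> 15,676 / 17,039
        shared = {f"S{i}": 1.0 for i in range(15676)}
        a = QuantTable("rnc", {**shared, **{f"A{i}": 1.0 for i in range(675)}})
        b = QuantTable("ribo", {**shared, **{f"B{i}": 1.0 for i in range(688)}})
        profile = tanimoto_profile(a, b, thresholds=(0.0,))
        assert profile.rows[0].similarity == pytest.approx(15676 / 17039)
        assert round(profile.rows[0].similarity, 4) == 0.9200
        assert profile.rows[0].band == "identical"

    def test_empty_or_unsorted_ladder_rejected(self, small_table):
        with pytest.raises(ValueError):
            tanimoto_profile(small_table, small_table, thresholds=())
        with pytest.raises(ValueError):
            tanimoto_profile(small_table, small_table, thresholds=(1.0, 0.5))

    def test_insertion_order_of_genes_is_irrelevant(self):
        values = {"A": 1.0, "B": 0.2, "C": 0.0, "D": 7.0}
        t1 = QuantTable("x", values)
        t2 = QuantTable("x", dict(reversed(values.items())))
        other = QuantTable("y", {"A": 0.5, "C": 2.0, "D": 7.0, "B": 0.0})
        p1 = tanimoto_profile(t1, other)
        p2 = tanimoto_profile(t2, other)
        assert p1.rows == p2.rows


class TestVennCounts:
    def test_two_set_hand_enumeration(self):
        a = GeneSet("a", 0, frozenset("xy"))
        b = GeneSet("b", 0, frozenset("yz"))
        venn = venn_counts([a, b])
        assert venn.region_counts == {"10": 1, "01": 1, "11": 1}
        assert venn.union_total == 3

    def test_identical_sets_populate_only_the_full_region(self):
        a = GeneSet("a", 0, frozenset("pqr"))
        venn = venn_counts([a, a])
        assert venn.region_counts == {"10": 0, "01": 0, "11": 3}

    def test_wrong_set_count_rejected(self):
        a = GeneSet("a", 0, frozenset("x"))
        with pytest.raises(ValueError):
            venn_counts([a])
        with pytest.raises(ValueError):
            venn_counts([a, a, a, a])

    @given(st.lists(elements, min_size=2, max_size=3))
    def test_regions_partition_union_and_reconstruct_set_sizes(self, sets):
        gene_sets = [GeneSet(f"s{i}", 0, frozenset(map(str, s))) for i, s in enumerate(sets)]
        venn = venn_counts(gene_sets)
        assert sum(venn.region_counts.values()) == venn.union_total
        assert venn.union_total == len(frozenset().union(*(s.symbols for s in gene_sets)))
        for i, s in enumerate(gene_sets):
            assert venn.set_size(i) == len(s)


class TestLogRpkmCorrelation:
    def test_identical_tables_give_unit_correlation(self):
        table = QuantTable("a", {f"G{i}": float(i + 1) for i in range(20)})
        res = log_rpkm_correlation(table, table, seed=3)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.n_shared == 20

    def test_scaling_is_a_log_shift(self):
        a = QuantTable("a", {f"G{i}": float(2 + i**1.3) for i in range(15)})
        b = QuantTable("b", {g: 3.7 * v for g, v in a.values.items()})
        res = log_rpkm_correlation(a, b, seed=3)
        assert res.pearson_r_log10 == pytest.approx(1.0)

    def test_restricted_to_genes_detected_in_both(self):
        a = QuantTable("a", {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "E": 0.0})
        b = QuantTable("b", {"A": 2.0, "B": 3.0, "C": 5.0, "D": 0.0, "E": 9.0})
        res = log_rpkm_correlation(a, b, seed=3)
        assert res.n_shared == 3

    def test_too_few_shared_genes_rejected(self):
        a = QuantTable("a", {"A": 1.0, "B": 2.0})
        b = QuantTable("b", {"A": 1.0, "B": 2.0})
        with pytest.raises(ValueError, match="need >= 3"):
            log_rpkm_correlation(a, b, seed=3)

    def test_exact_enumeration_matches_direct_permutation_count(self):
        vals_a = [1.0, 3.0, 9.0, 27.0, 5.0, 40.0]
        vals_b = [2.0, 5.0, 7.0, 30.0, 90.0, 6.0]
        a = QuantTable("a", {f"G{i}": v for i, v in enumerate(vals_a)})
        b = QuantTable("b", {f"G{i}": v for i, v in enumerate(vals_b)})
        res = log_rpkm_correlation(a, b, seed=3)
        assert res.exact and res.n_permutations == math.factorial(6)

        # independent oracle: enumerate Spearman rho over raw-value permutations
        ra = stats.rankdata(vals_a)
        rb = stats.rankdata(vals_b)
        obs = abs(stats.pearsonr(ra, rb).statistic)
        hits = sum(
            1
            for perm in itertools.permutations(rb)
            if abs(stats.pearsonr(ra, perm).statistic) >= obs - 1e-12
        )
        assert res.p_value == pytest.approx(hits / math.factorial(6))

    def test_sampled_p_value_is_small_for_strong_association(self):
        rng = np.random.default_rng(7)
        x = 10 ** rng.normal(0.5, 0.8, size=60)
        a = QuantTable("a", {f"G{i}": float(v) for i, v in enumerate(x)})
        b = QuantTable("b", {f"G{i}": float(v * 10 ** rng.normal(0, 0.1)) for i, v in enumerate(x)})
        res = log_rpkm_correlation(a, b, n_permutations=999, seed=11)
        assert not res.exact
        assert res.p_value == pytest.approx(1 / 1000)


class TestAnnotateUniqueTranscripts:
    def _ann(self, rows):
        return pd.DataFrame(
            rows, columns=["canonical_length", "gc_percent"],
            index=[f"G{i}" for i in range(len(rows))],
        )

    def test_median_gc(self):
        ann = self._ann([(1000, 45.0), (1200, 46.0), (1400, 47.0)])
        s = annotate_unique_transcripts(GeneSet("u", 0, frozenset(ann.index)), ann)
        assert s.median_gc_percent == 46.0

    def test_single_long_gene_reported_as_maximum(self):
        ann = pd.DataFrame(
            {"canonical_length": [30609], "gc_percent": [44.0]}, index=["GRIN2B"]
        )
        s = annotate_unique_transcripts(GeneSet("u", 0, frozenset(["GRIN2B"])), ann)
        assert s.mean_length == 30609
        assert s.max_length_gene == "GRIN2B"

    def test_mean_length_and_missing_genes_skipped(self):
        ann = self._ann([(2000, 40.0), (3000, 50.0)])
        unique = GeneSet("u", 0, frozenset(list(ann.index) + ["ABSENT"]))
        s = annotate_unique_transcripts(unique, ann)
        assert s.mean_length == 2500
        assert s.missing == ("ABSENT",)
        assert s.n_annotated == 2

    def test_fully_unannotated_set_rejected(self):
        ann = self._ann([(2000, 40.0)])
        with pytest.raises(ValueError, match="annotated"):
            annotate_unique_transcripts(GeneSet("u", 0, frozenset(["NOPE"])), ann)
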