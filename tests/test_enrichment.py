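import math
from fractions import Fraction

import numpy as np
import pytest

from enrichkit import (
    ContigCountRecord,
    Direction,
    EnrichmentConfig,
    LibrarySizes,
    Partition,
    RobustRule,
    Sidedness,
    ac_point_probability,
    ac_pvalue,
    call_enrichment,
    classify_partition,
    fold_enrichment,
    robust_candidates,
)
from enrichkit.enrichment import (
    EnrichmentCall,
    pvalues_vectorized,
    summary_from_class_counts,
)

from _oracles import (
    binom_mass_exact,
    two_library_pvalue_exact,
)


class TestPointProbability:
    def test_empty_sum_identity(self):
        sizes = LibrarySizes(1000, 1000)
        assert ac_point_probability(0, 0, sizes) == 1.0

    def test_ten_zero_equal_sizes(self, equal_sizes):
        # Binomial(10, 0.5) mass at 0 = 0.5**10
        assert ac_point_probability(10, 0, equal_sizes) == pytest.approx(
            0.5**10, rel=1e-12
        )

    def test_unequal_sizes_matches_binomial_third(self):
        sizes = LibrarySizes(500_000, 250_000)
        expected = float(binom_mass_exact(7, 10, Fraction(1, 3)))
        assert ac_point_probability(3, 7, sizes) == pytest.approx(expected, rel=1e-12)

    def test_negative_count_rejected(self, equal_sizes):
        with pytest.raises(ValueError):
            ac_point_probability(-1, 2, equal_sizes)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            LibrarySizes(0, 10)

    def test_large_counts_no_overflow(self, study_sizes):
        p = ac_point_probability(500_000, 480_000, study_sizes)
        assert 0.0 <= p <= 1.0
        assert np.isfinite(p)


class TestPvalue:
    def test_balanced_counts_p_one(self, equal_sizes):
        # smaller tail P(Y<=5 | 10, 0.5) = 0.6230..., doubled and capped
        assert ac_pvalue(5, 5, equal_sizes) == 1.0

    def test_ten_zero_two_sided(self, equal_sizes):
        assert ac_pvalue(10, 0, equal_sizes) == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_label_swap_symmetry(self):
        a = ac_pvalue(17, 4, LibrarySizes(640_000, 710_000))
        b = ac_pvalue(4, 17, LibrarySizes(710_000, 640_000))
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_zero_returns_one(self, equal_sizes):
        assert ac_pvalue(0, 0, equal_sizes) == 1.0

    def test_one_sided_half_of_two_sided_away_from_cap(self, equal_sizes):
        two = ac_pvalue(12, 1, equal_sizes, sidedness=Sidedness.TWO_SIDED)
        one = ac_pvalue(12, 1, equal_sizes, sidedness=Sidedness.ONE_SIDED)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_extreme_counts_tiny_p_no_underflow_to_garbage(self, equal_sizes):
        p = ac_pvalue(150, 1, equal_sizes)
        expected = float(two_library_pvalue_exact(150, 1, 700_000, 700_000))
        assert p == pytest.approx(expected, rel=1e-9)

    def test_string_sidedness_accepted(self, equal_sizes):
        assert ac_pvalue(5, 5, equal_sizes, sidedness="two_sided") == 1.0


@pytest.mark.parametrize(
    "n_a,n_b",
    [(700_000, 700_000), (500_000, 250_000), (742_771, 721_543)],
    ids=["equal", "two_to_one", "study"],
)
def test_oracle_equivalence_grid(n_a, n_b):
    """Implementation vs exact Fraction arithmetic over all x, y <= 30."""
    sizes = LibrarySizes(n_a, n_b)
    q = Fraction(n_b, n_a + n_b)
    for x in range(31):
        for y in range(31):
            mass = ac_point_probability(x, y, sizes)
            expect_mass = float(binom_mass_exact(y, x + y, q)) if x + y else 1.0
            assert mass == pytest.approx(expect_mass, rel=1e-10), (x, y)
            p = ac_pvalue(x, y, sizes)
            expect_p = float(two_library_pvalue_exact(x, y, n_a, n_b))
            assert p == pytest.approx(expect_p, rel=1e-10), (x, y)


def test_vectorized_matches_scalar(study_sizes):
    rng = np.random.default_rng(7)
    x = rng.integers(0, 200, size=50)
    y = rng.integers(0, 200, size=50)
    vec = pvalues_vectorized(x, y, study_sizes)
    for i in range(50):
        assert vec[i] == pytest.approx(
            ac_pvalue(int(x[i]), int(y[i]), study_sizes), rel=1e-12
        )


class TestFoldEnrichment:
    def test_equal_rates(self, equal_sizes):
        assert fold_enrichment(10, 10, equal_sizes) == 1.0

    def test_hundredfold(self, equal_sizes):
        assert fold_enrichment(200, 2, equal_sizes) == pytest.approx(100.0)

    def test_normalized_by_library_size(self):
        sizes = LibrarySizes(700_000, 350_000)
        assert fold_enrichment(100, 5, sizes) == pytest.approx(10.0)

    def test_single_zero_is_inf(self, equal_sizes):
        assert math.isinf(fold_enrichment(5, 0, equal_sizes))
        assert math.isinf(fold_enrichment(0, 5, equal_sizes))

    def test_double_zero_rejected(self, equal_sizes):
        with pytest.raises(ValueError):
            fold_enrichment(0, 0, equal_sizes)


class TestClassifyPartition:
    def test_mixed_and_exclusive_counts(self, small_table):
        labels, summary = classify_partition(small_table)
        assert summary.n_mixed == 2
        assert summary.n_a_only == 1
        assert summary.n_b_only == 2
        assert labels == [
            Partition.MIXED,
            Partition.B_ONLY,
            Partition.A_ONLY,
            Partition.MIXED,
            Partition.B_ONLY,
        ]

    def test_single_contig(self):
        _, summary = classify_partition([ContigCountRecord("c1", 1, 0)])
        assert (summary.n_a_only, summary.n_mixed, summary.n_b_only) == (1, 0, 0)

    def test_counts_conserved(self, small_table):
        _, summary = classify_partition(small_table)
        assert summary.n_contigs == len(small_table)
        assert summary.reads_a == sum(r.x for r in small_table)
        assert summary.reads_b == sum(r.y for r in small_table)

    def test_zero_zero_contig_named_in_error(self):
        with pytest.raises(ValueError, match="bad_contig"):
            classify_partition(
                [ContigCountRecord("ok", 1, 1), ContigCountRecord("bad_contig", 0, 0)]
            )

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="dup"):
            classify_partition(
                [ContigCountRecord("dup", 1, 1), ContigCountRecord("dup", 2, 2)]
            )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            classify_partition([])


def test_summary_from_class_counts_accounting():
    summary = summary_from_class_counts(26_001, 9_484, 10_053)
    assert summary.n_contigs == 26_001 + 9_484 + 10_053
    summary = summary_from_class_counts(1, 2, 3, reads_a=10, reads_b=20)
    assert summary.total_reads == 30


class TestCallEnrichment:
    def test_strong_enrichment_called(self, equal_sizes):
        calls = call_enrichment(
            [ContigCountRecord("c1", 150, 1)], equal_sizes, EnrichmentConfig()
        )
        assert calls[0].enriched
        assert calls[0].direction is Direction.A
        expected = float(two_library_pvalue_exact(150, 1, 700_000, 700_000))
        assert calls[0].p_value == pytest.approx(expected, rel=1e-9)

    def test_weak_difference_not_called(self, equal_sizes):
        calls = call_enrichment([ContigCountRecord("c1", 3, 1)], equal_sizes)
        # two-sided p = 2 * P(Y<=1 | 4, 0.5) = 0.625
        assert calls[0].p_value == pytest.approx(0.625, rel=1e-12)
        assert not calls[0].enriched

    def test_exclusive_untested_by_default(self, equal_sizes, small_table):
        calls = call_enrichment(small_table, equal_sizes)
        by_id = {c.contig_id: c for c in calls}
        assert by_id["c3"].p_value is None
        assert not by_id["c3"].enriched
        assert by_id["c1"].p_value is not None

    def test_exclusive_tested_when_enabled(self, equal_sizes, small_table):
        config = EnrichmentConfig(include_exclusive=True)
        calls = call_enrichment(small_table, equal_sizes, config)
        by_id = {c.contig_id: c for c in calls}
        assert by_id["c3"].p_value == pytest.approx(
            float(two_library_pvalue_exact(7, 0, 700_000, 700_000)), rel=1e-10
        )

    def test_output_order_matches_input(self, equal_sizes, small_table):
        calls = call_enrichment(small_table, equal_sizes)
        assert [c.contig_id for c in calls] == [r.contig_id for r in small_table]

    def test_empty_table_empty_output(self, equal_sizes):
        assert call_enrichment([], equal_sizes) == []

    def test_tied_rates_direction_none(self, equal_sizes):
        calls = call_enrichment([ContigCountRecord("c1", 4, 4)], equal_sizes)
        assert calls[0].direction is Direction.NONE
        assert not calls[0].enriched

    def test_library_swap_symmetry(self, small_table):
        sizes = LibrarySizes(640_000, 710_000)
        fwd = call_enrichment(small_table, sizes)
        swapped_table = [
            ContigCountRecord(r.contig_id, r.y, r.x) for r in small_table
        ]
        rev = call_enrichment(swapped_table, LibrarySizes(710_000, 640_000))
        for f, r in zip(fwd, rev):
            assert f.fold == pytest.approx(r.fold)
            if f.p_value is not None:
                assert f.p_value == pytest.approx(r.p_value, rel=1e-12)
            assert {Partition.A_ONLY: Partition.B_ONLY,
                    Partition.B_ONLY: Partition.A_ONLY,
                    Partition.MIXED: Partition.MIXED}[f.partition] == r.partition
            assert {Direction.A: Direction.B,
                    Direction.B: Direction.A,
                    Direction.NONE: Direction.NONE}[f.direction] == r.direction

    def test_bh_adjustment_more_conservative(self, equal_sizes):
        table = [ContigCountRecord(f"c{i}", 20 + i, 2) for i in range(10)]
        raw = call_enrichment(table, equal_sizes)
        adj = call_enrichment(table, equal_sizes, EnrichmentConfig(fdr=True))
        for r, a in zip(raw, adj):
            assert a.q_value >= r.p_value


class TestRobustCandidates:
    @staticmethod
    def _call(p, fold, x, y):
        return EnrichmentCall(
            contig_id="c",
            partition=Partition.MIXED,
            x=x,
            y=y,
            rate_a=0.1,
            rate_b=0.001,
            fold=fold,
            p_value=p,
            direction=Direction.A,
            enriched=p < 0.001,
        )

    def test_fold_rule_keeps_large_fold(self):
        config = EnrichmentConfig(robust_rule=RobustRule.FOLD)
        kept = robust_candidates([self._call(1e-5, 150.0, 30, 0)], config)
        assert len(kept) == 1
        assert kept[0].robust
        assert "fold" in kept[0].robust_by

    def test_fold_rule_drops_small_fold(self):
        config = EnrichmentConfig(robust_rule=RobustRule.FOLD)
        assert robust_candidates([self._call(1e-5, 40.0, 30, 1)], config) == []

    def test_alpha_failure_dropped_despite_fold(self):
        config = EnrichmentConfig(robust_rule=RobustRule.FOLD)
        assert robust_candidates([self._call(0.01, 500.0, 30, 0)], config) == []

    def test_reads_rule(self):
        config = EnrichmentConfig(robust_rule=RobustRule.READS)
        assert robust_candidates([self._call(1e-5, 40.0, 150, 2)], config)
        assert robust_candidates([self._call(1e-5, 40.0, 90, 2)], config) == []

    def test_either_rule_union(self):
        config = EnrichmentConfig(robust_rule=RobustRule.EITHER)
        assert robust_candidates([self._call(1e-5, 150.0, 50, 0)], config)
        assert robust_candidates([self._call(1e-5, 40.0, 150, 3)], config)
        assert robust_candidates([self._call(1e-5, 40.0, 50, 1)], config) == []

    def test_result_subset_of_enriched(self, equal_sizes):
        table = [
            ContigCountRecord("a", 150, 1),
            ContigCountRecord("b", 3, 1),
            ContigCountRecord("c", 400, 2),
        ]
        calls = call_enrichment(table, equal_sizes)
        kept = robust_candidates(calls)
        enriched_ids = {c.contig_id for c in calls if c.enriched}
        assert {c.contig_id for c in kept} <= enriched_ids


class TestConfigValidation:
    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            EnrichmentConfig(alpha=0.0)
        with pytest.raises(ValueError):
            EnrichmentConfig(alpha=1.0)

    def test_min_fold_at_least_one(self):
        with pytest.raises(ValueError):
            EnrichmentConfig(robust_min_fold=0.5)
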