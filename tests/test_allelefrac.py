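"""Allele-fraction estimation, replicate weighting and coverage filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allelecho.allelefrac import (
    allele_fraction,
    allele_fraction_table,
    combine_replicates,
    expressed_fraction,
    germline_binomial_filter,
    min_read_filter,
    pooled_counts,
)
from allelecho.core import AlleleCounts
from allelecho.sim import SimConfig, simulate_counts, simulate_genome


class TestAlleleFraction:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(0, 100, 0.0), (176, 495, 176 / 495), (50, 50, 1.0)],
    )
    def test_point_estimate_is_k_over_n(self, k, n, expected):
        est = allele_fraction(AlleleCounts(k, n))
        assert est.p == pytest.approx(expected)
        assert est.n_effective == n

    def test_se_positive_even_at_boundaries(self):
        for k, n in [(0, 100), (50, 50)]:
            assert allele_fraction(AlleleCounts(k, n)).se > 0

    def test_se_matches_stabilized_binomial_formula(self):
        est = allele_fraction(AlleleCounts(87, 248))
        p_t = 89 / 252
        assert est.se == pytest.approx(math.sqrt(p_t * (1 - p_t) / 252))

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            allele_fraction(AlleleCounts(0, 0))


class TestCombineReplicates:
    def test_identical_replicates_idempotent(self):
        e = allele_fraction(AlleleCounts(87, 248))
        assert combine_replicates([e, e]).p == pytest.approx(e.p)

    def test_inverse_variance_oracle(self):
        """Replicate fractions 35% and 36% combine to ~35.5%; the expected
        value is frozen from explicit inverse-variance arithmetic."""
        e1 = allele_fraction(AlleleCounts(87, 248))
        e2 = allele_fraction(AlleleCounts(89, 247))
        w1, w2 = 1 / e1.se**2, 1 / e2.se**2
        expected_p = (w1 * e1.p + w2 * e2.p) / (w1 + w2)
        expected_se = math.sqrt(1 / (w1 + w2))
        combined = combine_replicates([e1, e2])
        assert combined.p == pytest.approx(expected_p)
        assert combined.p == pytest.approx(0.3555, abs=5e-4)
        assert combined.se == pytest.approx(expected_se)
        assert combined.n_effective == 495

    def test_single_replicate_unchanged(self):
        e = allele_fraction(AlleleCounts(10, 40))
        assert combine_replicates([e]) is e

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_replicates([])

    def test_more_reads_more_weight(self):
        """Doubling one replicate's depth pulls the mean toward it."""
        lo = allele_fraction(AlleleCounts(20, 100))
        hi_small = allele_fraction(AlleleCounts(60, 100))
        hi_big = allele_fraction(AlleleCounts(120, 200))
        p_small = combine_replicates([lo, hi_small]).p
        p_big = combine_replicates([lo, hi_big]).p
        assert p_big > p_small

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(50, 300)), min_size=2, max_size=6
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_order_invariant(self, pairs):
        ests = [allele_fraction(AlleleCounts(k, n)) for k, n in pairs]
        fwd = combine_replicates(ests)
        rev = combine_replicates(ests[::-1])
        assert fwd.p == pytest.approx(rev.p)
        assert fwd.se == pytest.approx(rev.se)

    def test_weighted_close_to_pooled_on_simulated_duplicates(self):
        """Cross-validation of the weighting: on duplicate libraries with
        depth >= 50 the weighted mean tracks the pooled-count estimate,
        agreeing within a percentage point for the overwhelming majority of
        loci (replicate pairs that happen to disagree by several binomial SEs
        can differ slightly more, since the replicate with the less extreme
        fraction gets a touch less weight)."""
        truth = simulate_genome(SimConfig(n_snvs=150, dna_depth_mean=120, seed=17))
        counts = simulate_counts(truth)
        dna = counts[(counts["sample"] == "tumor") & (counts["analyte"] == "DNA")]
        diffs = []
        for _, grp in dna.groupby("snv_id"):
            cs = [AlleleCounts(int(r.mutant_reads), int(r.total_reads)) for r in grp.itertuples()]
            if any(c.total_reads < 50 for c in cs):
                continue
            k, n = pooled_counts(cs)
            weighted = combine_replicates([allele_fraction(c) for c in cs]).p
            diffs.append(abs(weighted - k / n))
        diffs = np.asarray(diffs)
        assert len(diffs) > 100
        assert np.mean(diffs < 0.01) >= 0.95
        assert diffs.max() < 0.03


class TestFilters:
    @pytest.mark.parametrize(
        "n_dna,n_rna,keep",
        [(248, 9, False), (10, 10, True), (495, 300, True), (9, 500, False)],
    )
    def test_min_read_filter_pooled_boundary(self, n_dna, n_rna, keep):
        dna = [AlleleCounts(0, n_dna)]
        rna = [AlleleCounts(0, n_rna)]
        assert min_read_filter(dna, rna) is keep

    def test_min_read_filter_pools_replicates(self):
        dna = [AlleleCounts(0, 5), AlleleCounts(0, 5)]
        rna = [AlleleCounts(1, 6), AlleleCounts(1, 4)]
        assert min_read_filter(dna, rna) is True

    def test_germline_filter_drops_shallow_coverage(self):
        # with 4 germline reads a het variant escapes detection 6.25% of the
        # time, above alpha=0.05 -> cannot call the locus somatic
        tumor = [AlleleCounts(10, 30)]
        assert germline_binomial_filter(tumor, [AlleleCounts(0, 4)]) is False
        assert germline_binomial_filter(tumor, [AlleleCounts(0, 5)]) is True

    def test_germline_filter_keeps_deep_clean_germline(self):
        tumor = [AlleleCounts(87, 248), AlleleCounts(89, 247)]
        germ = [AlleleCounts(0, 141), AlleleCounts(0, 133)]
        assert germline_binomial_filter(tumor, germ) is True

    def test_germline_filter_drops_het_germline_variant(self):
        assert (
            germline_binomial_filter([AlleleCounts(50, 100)], [AlleleCounts(40, 100)])
            is False
        )

    def test_filters_are_pure(self):
        dna, rna = [AlleleCounts(3, 20)], [AlleleCounts(2, 12)]
        assert all(min_read_filter(dna, rna) == min_read_filter(dna, rna) for _ in range(3))


class TestExpressedFraction:
    def test_all_expressed(self):
        assert expressed_fraction([1, 5, 2, 9]) == 1.0

    def test_mixed(self):
        assert expressed_fraction([0] * 13 + [1] * 967) == pytest.approx(967 / 980)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            expressed_fraction([])

    def test_nmd_free_simulation_nearly_all_expressed(self):
        """Without NMD and with >= 10 RNA reads per locus, virtually every
        mutation shows at least one mutant RNA read."""
        truth = simulate_genome(
            SimConfig(n_snvs=300, nmd_efficiency=0.0, rna_depth_mean=100,
                      rna_depth_sigma=0.3, seed=19)
        )
        counts = simulate_counts(truth)
        table = allele_fraction_table(counts)
        kept = table[table.pass_min_reads]
        assert len(kept) > 250
        assert expressed_fraction(kept.rna_mutant_reads.tolist()) >= 0.99


class TestAlleleFractionTable:
    def test_columns_and_filter_flags(self):
        truth = simulate_genome(SimConfig(n_snvs=25, seed=23))
        counts = simulate_counts(truth)
        table = allele_fraction_table(counts)
        assert len(table) == 25
        for col in ("p_dna", "se_dna", "p_rna", "se_rna", "pass_filters"):
            assert col in table.columns
        assert ((table.p_dna >= 0) & (table.p_dna <= 1)).all()
        # pooled coverage must match the raw counts
        dna = counts[(counts["sample"] == "tumor") & (counts.analyte == "DNA")]
        pooled = dna.groupby("snv_id").total_reads.sum()
        got = table.set_index("snv_id").dna_total_reads
        assert (pooled.sort_index() == got.sort_index()).all()
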