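import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteopgs import (GenotypeQC, QcConfig, SimConfig, call_rate_filter,
                      cochran_q, hwe_exact_test, ld_prune, ld_r2,
                      minor_allele_frequency, run_qc, simulate_cohort)

from conftest import make_matrix


def hwe_enumeration_oracle(n_hom_ref: int, n_het: int,
                           n_hom_alt: int) -> float:
    """Exact HWE p by enumerating genotype configurations of n individuals.

    Counts, for each feasible heterozygote count, the number of labeled
    genotype assignments consistent with the allele counts (choose the
    hom-ref individuals, then the hets, with 2 allele orders per het), and
    sums the counts no larger than the observed table's.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_ref, 2 * n - n_ref)
    ways = {}
    for h in range(rare % 2, rare + 1, 2):
        a = (n_ref - h) // 2
        ways[h] = math.comb(n, a) * math.comb(n - a, h) * 2 ** h
    total = sum(ways.values())
    obs = ways[n_het]
    return sum(w for w in ways.values() if w <= obs) / total


class TestMinorAlleleFrequency:
    @pytest.mark.parametrize("dosages, maf", [
        ([0, 0, 0], 0.0),
        ([2, 2], 0.0),
        ([0, 1, 1, 2], 0.5),     # 4 of 8 alleles
        ([0, 0, 0, 1], 0.125),   # 1 of 8 alleles
    ])
    def test_hand_counts(self, dosages, maf):
        assert minor_allele_frequency(np.array(dosages)) == maf

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            minor_allele_frequency(np.array([]))


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 7) == 1.0
        assert hwe_exact_test(7, 0, 0) == 1.0

    def test_small_table_matches_enumeration(self):
        # 4 ref and 4 alt alleles: het counts {0, 2, 4}
        assert hwe_exact_test(1, 2, 1) == pytest.approx(
            hwe_enumeration_oracle(1, 2, 1), abs=1e-15)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(1, 26))
            n0 = int(rng.integers(0, n + 1))
            n1 = int(rng.integers(0, n - n0 + 1))
            n2 = n - n0 - n1
            assert hwe_exact_test(n0, n1, n2) == pytest.approx(
                hwe_enumeration_oracle(n0, n1, n2), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_homozygote_swap_symmetry(self, n0, n1, n2):
        if n0 + n1 + n2 == 0:
            return
        assert hwe_exact_test(n0, n1, n2) == hwe_exact_test(n2, n1, n0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestLdR2:
    def test_self_and_mirror_correlation(self):
        d = np.array([0, 1, 2, 0, 1])
        assert ld_r2(d, d) == pytest.approx(1.0)
        assert ld_r2(d, 2 - d) == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        d1 = np.array([0, 1, 2, 0])
        d2 = np.array([0, 1, 1, 1])
        r = np.corrcoef(d1, d2)[0, 1]
        assert ld_r2(d1, d2) == pytest.approx(r * r, abs=1e-12)

    def test_monomorphic_returns_nan(self):
        assert math.isnan(ld_r2(np.array([1, 1, 1]), np.array([0, 1, 2])))

    def test_pairwise_complete_subset_used(self):
        d1 = np.array([0, 1, 2, 2])
        d2 = np.array([0, 1, 2, 0])
        m2 = np.array([False, False, False, True])
        assert ld_r2(d1, d2, None, m2) == pytest.approx(1.0)


class TestLdPrune:
    def test_independent_variants_untouched(self):
        rng = np.random.default_rng(3)
        G = make_matrix(rng.integers(0, 3, size=(60, 5)))
        out, removed = ld_prune(G, QcConfig())
        assert removed == []
        assert out.n_variants == 5

    def test_duplicate_column_loses_once(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 3, size=(40, 1))
        G = make_matrix(np.hstack([base, base]))
        out, removed = ld_prune(G, QcConfig())
        assert len(removed) == 1 and out.n_variants == 1

    def test_greedy_trace_on_copied_variants(self):
        rng = np.random.default_rng(5)
        cols = [rng.integers(0, 3, size=40) for _ in range(3)]
        # variants 2 and 4 (0-based 1 and 3) are copies of variant 1 (0)
        dosage = np.column_stack(
            [cols[0], cols[0], cols[1], cols[0], cols[2]])
        G = make_matrix(dosage)
        out, removed = ld_prune(G, QcConfig())
        assert removed == ["v1", "v3"]
        assert out.variant_ids == ["v0", "v2", "v4"]

    def test_lower_call_rate_member_removed(self):
        rng = np.random.default_rng(6)
        base = rng.integers(0, 3, size=(50, 1))
        missing = np.zeros((50, 2), dtype=bool)
        missing[:5, 0] = True  # first (map-earlier) copy has worse calls
        G = make_matrix(np.hstack([base, base]), missing=missing)
        out, removed = ld_prune(G, QcConfig())
        assert removed == ["v0"]


class TestCochranQ:
    def test_identical_effects_no_heterogeneity(self):
        q, df, p, i2 = cochran_q(np.array([0.3, 0.3, 0.3]),
                                 np.array([0.1, 0.2, 0.3]))
        assert q == pytest.approx(0.0) and i2 == 0.0
        assert p == pytest.approx(1.0)

    def test_two_effects_hand_computed(self):
        # weights 1, weighted mean 0.5, Q = 0.25 + 0.25
        q, df, p, i2 = cochran_q(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        assert q == pytest.approx(0.5) and df == 1

    def test_i2_formula(self):
        rng = np.random.default_rng(8)
        eff = rng.normal(0, 1, 5)
        se = rng.uniform(0.1, 1.0, 5)
        q, df, _, i2 = cochran_q(eff, se)
        assert i2 == pytest.approx(max(0.0, (q - 4) / q) * 100)

    def test_single_effect_rejected(self):
        with pytest.raises(ValueError):
            cochran_q(np.array([1.0]), np.array([1.0]))


class TestCallRateFilter:
    def test_complete_matrix_unchanged(self):
        G = make_matrix(np.ones((5, 4), dtype=int))
        out, rs, rv = call_rate_filter(G, QcConfig())
        assert rs == [] and rv == []

    def test_sample_below_threshold_removed(self):
        missing = np.zeros((3, 100), dtype=bool)
        missing[0, :4] = True  # call rate 0.96 < 0.97
        G = make_matrix(np.ones((3, 100), dtype=int), missing=missing)
        out, rs, _ = call_rate_filter(G, QcConfig())
        assert rs == ["s0"]

    def test_engineered_variant_removed(self):
        # variant 3 missing in 10% of samples; affected samples still have
        # 39/40 = 0.975 call rate, so only the variant goes
        missing = np.zeros((20, 40), dtype=bool)
        missing[:2, 3] = True
        G = make_matrix(np.ones((20, 40), dtype=int), missing=missing)
        out, rs, rv = call_rate_filter(G, QcConfig())
        assert rs == [] and rv == ["v3"]


class TestRunQc:
    def test_clean_panel_fully_retained(self):
        sim = simulate_cohort(SimConfig(
            seed=21, n_samples=400, n_snps=25, n_causal=10,
            maf_range=(0.2, 0.45)))
        out, report = run_qc(sim.genotypes, QcConfig(hwe_alpha=1e-4))
        assert report.n_variants_out == 25
        assert report.removed == [] and report.removed_samples == []

    def test_removal_accounting_sums(self, small_cohort):
        _, report = run_qc(small_cohort.genotypes)
        assert (report.n_variants_out + len(report.removed)
                == report.n_variants_in)

    def test_qc_is_idempotent(self):
        sim = simulate_cohort(SimConfig(
            seed=22, n_samples=300, n_snps=40, n_causal=20,
            missing_rate=0.02, n_hwe_violators=3, n_ld_duplicates=3))
        once, _ = run_qc(sim.genotypes)
        twice, report = run_qc(once)
        assert report.removed == [] and report.removed_samples == []
        assert twice.variant_ids == once.variant_ids

    def test_transform_requires_fit(self, small_cohort):
        with pytest.raises(RuntimeError):
            GenotypeQC().transform(small_cohort.genotypes)

    def test_reasons_follow_filter_order(self):
        sim = simulate_cohort(SimConfig(
            seed=23, n_samples=500, n_snps=40, n_causal=10,
            maf_range=(0.1, 0.45), n_hwe_violators=4, n_ld_duplicates=4))
        _, report = run_qc(sim.genotypes)
        reasons = dict(report.removed)
        for vid in sim.hwe_violators:
            assert reasons[vid] == "hwe"
        for vid, src in zip(sim.ld_duplicates, sim.ld_duplicate_sources):
            # the duplicate is pruned as LD unless its source already fell
            # to an earlier filter, dissolving the redundant pair
            assert reasons.get(vid) == "ld" or src in reasons
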