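"""Neutral-marker estimators against hand computations and brute-force oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from landqg import (
    SimGenotypeConfig,
    allelic_richness,
    cohort_ttest,
    expected_heterozygosity,
    hedrick_gst_prime,
    hierarchical_amova,
    inbreeding_coefficient,
    jost_d,
    ne_molecular_coancestry,
    pairwise_fst,
    simulate_genotypes,
    slatkin_rst,
    weir_cockerham_fstats,
)
from landqg.popgen import _rarefied_alleles, _wc_components_locus, molecular_coancestry_pair
from landqg.tables import GenotypeTable

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# expected heterozygosity
# ---------------------------------------------------------------------------

class TestExpectedHeterozygosity:
    def test_all_heterozygous_unbiased_formula(self):
        g = make_genotypes({"A": [[(1, 2)] for _ in range(10)]})
        assert expected_heterozygosity(g, "A") == pytest.approx((20 / 19) * 0.5)

    def test_monomorphic_is_zero(self):
        g = make_genotypes({"A": [[(5, 5)] for _ in range(8)]})
        assert expected_heterozygosity(g, "A") == 0.0

    def test_three_alleles_matches_brute_force(self):
        # 10 diploids, allele copies 10/6/4
        genos = [[(1, 1)]] * 5 + [[(2, 2)]] * 3 + [[(3, 3)]] * 2
        g = make_genotypes({"A": genos})
        p = np.array([10, 6, 4]) / 20
        expected = (20 / 19) * (1 - (p**2).sum())
        assert expected_heterozygosity(g, "A") == pytest.approx(expected, abs=1e-12)

    def test_unknown_population_raises(self, two_pop_fixed):
        with pytest.raises(KeyError):
            expected_heterozygosity(two_pop_fixed, "nope")


# ---------------------------------------------------------------------------
# rarefied allelic richness
# ---------------------------------------------------------------------------

def enumerate_rarefied(counts, g):
    """Oracle: average distinct-allele count over all C(N, g) subsamples (exact)."""
    copies = [a for a, c in enumerate(counts) for _ in range(c)]
    total = Fraction(0)
    n_sub = 0
    for combo in itertools.combinations(range(len(copies)), g):
        total += len({copies[i] for i in combo})
        n_sub += 1
    return total / n_sub


class TestAllelicRichness:
    def test_two_plus_two_copies_exhaustive(self):
        assert _rarefied_alleles(np.array([2, 2]), 2) == pytest.approx(5 / 3)
        assert float(enumerate_rarefied([2, 2], 2)) == pytest.approx(5 / 3)

    def test_monomorphic_is_one(self):
        g = make_genotypes({"A": [[(7, 7)] for _ in range(6)]})
        assert allelic_richness(g, "A", rarefaction_g=4) == 1.0

    def test_full_sample_gives_observed_count(self):
        counts = np.array([5, 3, 2])
        assert _rarefied_alleles(counts, 10) == pytest.approx(3.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=4).filter(
            lambda c: 2 <= sum(c) <= 12
        ),
        st.data(),
    )
    def test_matches_enumeration_up_to_12_copies(self, counts, data):
        g = data.draw(st.integers(min_value=1, max_value=sum(counts)))
        oracle = enumerate_rarefied(counts, g)
        assert _rarefied_alleles(np.array(counts), g) == pytest.approx(float(oracle), abs=1e-12)

    def test_default_g_uses_smallest_population(self):
        # pop B has 2 diploids -> g = 4 gene copies
        g = make_genotypes(
            {
                "A": [[(1, 2)], [(1, 3)], [(2, 3)], [(1, 1)]],
                "B": [[(1, 2)], [(2, 2)]],
            }
        )
        countsA = np.array([4, 2, 2])  # alleles 1,2,3 in pop A
        assert allelic_richness(g, "A") == pytest.approx(_rarefied_alleles(countsA, 4))

    def test_g_too_large_raises(self):
        with pytest.raises(ValueError):
            _rarefied_alleles(np.array([2, 2]), 5)


# ---------------------------------------------------------------------------
# inbreeding coefficient
# ---------------------------------------------------------------------------

class TestInbreedingCoefficient:
    def test_all_homozygous_two_alleles_is_one(self):
        g = make_genotypes({"A": [[(1, 1)]] * 5 + [[(2, 2)]] * 5})
        assert inbreeding_coefficient(g, "A") == pytest.approx(1.0)

    def test_full_heterozygosity_negative(self):
        g = make_genotypes({"A": [[(1, 2)] for _ in range(10)]})
        assert inbreeding_coefficient(g, "A") < 0

    def test_monomorphic_undefined(self):
        g = make_genotypes({"A": [[(1, 1)] for _ in range(5)]})
        assert math.isnan(inbreeding_coefficient(g, "A"))

    def test_hardy_weinberg_near_zero(self):
        g = simulate_genotypes(
            SimGenotypeConfig(
                n_pops=1, n_per_pop=500, n_loci=20, n_landscapes=1,
                target_F=0.0, selfing_rate=0.0, seed=11, cohorts=("adult",),
            )
        )
        assert abs(inbreeding_coefficient(g, "P01")) < 0.03


# ---------------------------------------------------------------------------
# F_ST (Weir & Cockerham theta)
# ---------------------------------------------------------------------------

class TestPairwiseFst:
    def test_fixed_different_alleles_is_one(self, two_pop_fixed):
        assert pairwise_fst(two_pop_fixed, "A", "B") == pytest.approx(1.0)

    def test_identical_counts_nonpositive(self):
        block = [[(1, 1)]] * 3 + [[(1, 2)]] * 4 + [[(2, 2)]] * 3
        g = make_genotypes({"A": block, "B": block})
        assert pairwise_fst(g, "A", "B") <= 0

    def test_symmetry(self, two_pop_p2_p8):
        assert pairwise_fst(two_pop_p2_p8, "A", "B") == pytest.approx(
            pairwise_fst(two_pop_p2_p8, "B", "A")
        )

    def test_small_population_rejected(self):
        g = make_genotypes({"A": [[(1, 2)]], "B": [[(1, 2)], [(2, 2)]]})
        with pytest.raises(ValueError):
            pairwise_fst(g, "A", "B")

    def test_multilocus_is_ratio_of_sums_not_mean_of_ratios(self):
        # two loci with very different information content separate the two rules
        pop_a = [[(1, 1), (1, 2)]] * 6 + [[(1, 2), (2, 2)]] * 4
        pop_b = [[(2, 2), (1, 2)]] * 6 + [[(1, 2), (1, 1)]] * 4
        g = make_genotypes({"A": pop_a, "B": pop_b})
        comps = [
            _wc_components_locus(
                [g.locus_genotypes(loc, g.mask(population=p)) for p in ("A", "B")]
            )
            for loc in range(2)
        ]
        ratio_of_sums = sum(c[0] for c in comps) / sum(sum(c) for c in comps)
        mean_of_ratios = np.mean([c[0] / sum(c) for c in comps])
        assert weir_cockerham_fstats(g, ["A", "B"])["F_ST"] == pytest.approx(ratio_of_sums)
        assert abs(ratio_of_sums - mean_of_ratios) > 1e-3  # the rules genuinely differ here


# ---------------------------------------------------------------------------
# G'_ST and Jost's D
# ---------------------------------------------------------------------------

class TestDiversityDifferentiation:
    def test_fixed_differences_give_one(self, two_pop_fixed):
        assert hedrick_gst_prime(two_pop_fixed) == pytest.approx(1.0)
        assert jost_d(two_pop_fixed) == pytest.approx(1.0)

    def test_identical_populations_give_zero(self):
        block = [[(1, 1)]] * 2 + [[(1, 2)]] * 4 + [[(2, 2)]] * 4
        g = make_genotypes({"A": block, "B": block})
        assert hedrick_gst_prime(g) == pytest.approx(0.0, abs=1e-12)
        assert jost_d(g) == pytest.approx(0.0, abs=1e-12)

    def test_two_allele_case_matches_hand_computation(self, two_pop_p2_p8):
        # H_S = 0.32, H_T = 0.5, G_ST = 0.36 (frequencies 0.2/0.8 vs 0.8/0.2)
        hs, ht, k = 0.32, 0.5, 2
        gst = (ht - hs) / ht
        gst_prime = gst * (k - 1 + hs) / ((k - 1) * (1 - hs))
        d = (k / (k - 1)) * (ht - hs) / (1 - hs)
        assert hedrick_gst_prime(two_pop_p2_p8) == pytest.approx(gst_prime, abs=1e-12)
        assert jost_d(two_pop_p2_p8) == pytest.approx(d, abs=1e-12)
        assert gst_prime == pytest.approx(0.6988235294117647)
        assert d == pytest.approx(0.5294117647058824)

    def test_gst_prime_at_least_gst(self):
        g = simulate_genotypes(
            SimGenotypeConfig(
                n_pops=4, n_per_pop=25, n_loci=6, n_landscapes=2,
                target_F=0.1, seed=5, cohorts=("adult",),
            )
        )
        from landqg.popgen import _hs_ht_per_locus
        hs_l, ht_l = _hs_ht_per_locus(g, g.populations())
        gst = (ht_l.mean() - hs_l.mean()) / ht_l.mean()
        assert hedrick_gst_prime(g) >= gst


# ---------------------------------------------------------------------------
# R_ST
# ---------------------------------------------------------------------------

class TestSlatkinRst:
    def test_fixed_sizes_give_one(self, two_pop_fixed):
        res = slatkin_rst(two_pop_fixed, n_perm=99, seed=0)
        assert res.rst == pytest.approx(1.0)

    def test_no_size_variance_undefined(self):
        g = make_genotypes({"A": [[(10, 10)]] * 5, "B": [[(10, 10)]] * 5})
        res = slatkin_rst(g, n_perm=99, seed=0)
        assert math.isnan(res.rst)

    def test_requires_enough_permutations(self, two_pop_fixed):
        with pytest.raises(ValueError):
            slatkin_rst(two_pop_fixed, n_perm=10)


# ---------------------------------------------------------------------------
# hierarchical AMOVA
# ---------------------------------------------------------------------------

class TestAmova:
    def _structured(self, seed=0):
        return simulate_genotypes(
            SimGenotypeConfig(
                n_pops=4, n_per_pop=20, n_loci=5, n_landscapes=2,
                target_F=0.08, seed=seed, cohorts=("adult",),
            )
        )

    def test_identical_populations_near_zero(self):
        block = [[(1, 1), (3, 4)]] * 3 + [[(1, 2), (3, 3)]] * 4 + [[(2, 2), (4, 4)]] * 3
        g = make_genotypes(
            {p: block for p in ("A", "B", "C", "D")},
            landscape_of={"A": "L1", "B": "L1", "C": "L2", "D": "L2"},
        )
        res = hierarchical_amova(g, n_perm=49, seed=1)
        # identical populations: components carry only the small finite-sample
        # bias of the estimator, and nothing is significant
        assert abs(res.F_CT) < 0.1
        assert abs(res.F_SC) < 0.1
        assert res.p_CT > 0.05 and res.p_SC > 0.05

    def test_sums_of_squares_conserve(self):
        res = hierarchical_amova(self._structured(), n_perm=49, seed=1)
        assert res.ss_total == pytest.approx(
            res.ss_among_landscape + res.ss_among_pop + res.ss_within, abs=1e-9
        )

    def test_landscapes_fixed_pops_identical_extreme(self):
        g = make_genotypes(
            {
                "A": [[(1, 1)]] * 5,
                "B": [[(1, 1)]] * 5,
                "C": [[(2, 2)]] * 5,
                "D": [[(2, 2)]] * 5,
            },
            landscape_of={"A": "L1", "B": "L1", "C": "L2", "D": "L2"},
        )
        res = hierarchical_amova(g, n_perm=49, seed=1)
        assert res.F_CT == pytest.approx(1.0)
        assert res.F_SC == pytest.approx(0.0)

    def test_size_distance_variant_extreme(self):
        g = make_genotypes(
            {
                "A": [[(10, 10)]] * 5,
                "B": [[(10, 10)]] * 5,
                "C": [[(20, 20)]] * 5,
                "D": [[(20, 20)]] * 5,
            },
            landscape_of={"A": "L1", "B": "L1", "C": "L2", "D": "L2"},
        )
        res = hierarchical_amova(g, n_perm=49, seed=1, distance="size")
        assert res.F_CT == pytest.approx(1.0)
        assert res.F_SC == pytest.approx(0.0)

    def test_single_landscape_rejected(self):
        g = make_genotypes({"A": [[(1, 2)]] * 3, "B": [[(1, 1)]] * 3})
        with pytest.raises(ValueError):
            hierarchical_amova(g, n_perm=49)


# ---------------------------------------------------------------------------
# Ne from molecular coancestry
# ---------------------------------------------------------------------------

def mendelian_offspring(n_parents, n_off, n_loci, rng):
    """Offspring of a finite random-mating parent pool (true positive coancestry)."""
    parent_alleles = rng.integers(100, 112, size=(n_parents, n_loci, 2))
    out = np.empty((n_off, n_loci, 2), dtype=np.int64)
    for i in range(n_off):
        mom, dad = rng.integers(0, n_parents, size=2)
        for loc in range(n_loci):
            out[i, loc, 0] = parent_alleles[mom, loc, rng.integers(0, 2)]
            out[i, loc, 1] = parent_alleles[dad, loc, rng.integers(0, 2)]
    return out


class TestNeMolecularCoancestry:
    def test_clone_limit(self):
        g = make_genotypes({"A": [[(7, 7), (9, 9)]] * 5})
        ne, fbar = ne_molecular_coancestry(g, "A")
        assert fbar == pytest.approx(1.0)
        assert ne == pytest.approx(0.5)

    def test_pair_coancestry_matches_exhaustive_counting(self):
        geno_i = np.array([[1, 2], [3, 3]])
        geno_j = np.array([[1, 1], [3, 4]])
        s = molecular_coancestry_pair(geno_i, geno_j)
        # brute force over the 4 x 4 single-allele draws at each locus
        expected = []
        for li in range(2):
            matches = [
                int(a == b) for a in geno_i[li] for b in geno_j[li]
            ]
            expected.append(np.mean(matches))
        assert s == pytest.approx(np.mean(expected))
        assert s == pytest.approx(0.5)

    def test_never_negative_and_raw_always_positive(self):
        """Corrected Ne is positive or undefined (never negative); the raw
        similarity version is positive and finite on every seed."""
        import pandas as pd

        n_seeds = 25
        ok_raw = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            alleles = mendelian_offspring(n_parents=30, n_off=30, n_loci=10, rng=rng)
            meta = pd.DataFrame(
                {
                    "individual_id": [f"i{k}" for k in range(30)],
                    "population_id": "A",
                    "landscape_id": "L1",
                    "cohort": "adult",
                }
            )
            g = GenotypeTable(meta, alleles)
            ne, _ = ne_molecular_coancestry(g, "A")
            assert math.isnan(ne) or ne > 0
            ne_raw, fbar_raw = ne_molecular_coancestry(g, "A", corrected=False)
            if np.isfinite(ne_raw) and ne_raw > 0:
                ok_raw += 1
        assert ok_raw >= 0.9 * n_seeds

    def test_corrected_mean_is_pinned_to_self_coancestry(self):
        """The sample-referenced pairwise mean equals -f_self/(n-1): the
        documented identity that makes unstructured samples undefined."""
        import pandas as pd

        rng = np.random.default_rng(5)
        alleles = mendelian_offspring(n_parents=20, n_off=20, n_loci=8, rng=rng)
        meta = pd.DataFrame(
            {
                "individual_id": [f"i{k}" for k in range(20)],
                "population_id": "A",
                "landscape_id": "L1",
                "cohort": "adult",
            }
        )
        g = GenotypeTable(meta, alleles)
        _, fbar = ne_molecular_coancestry(g, "A")
        assert fbar < 0.01  # no recoverable mean signal relative to the sample

    def test_too_few_individuals_rejected(self):
        g = make_genotypes({"A": [[(1, 2)], [(2, 2)]]})
        with pytest.raises(ValueError):
            ne_molecular_coancestry(g, "A")


# ---------------------------------------------------------------------------
# cohort t test
# ---------------------------------------------------------------------------

class TestCohortTtest:
    def test_identical_vectors_zero(self):
        t, p = cohort_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0

    def test_sign_convention(self):
        t, _ = cohort_ttest([1, 2, 3], [11, 12, 13])
        assert t < 0  # adults below juveniles

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        a, j = rng.normal(0, 1, 12), rng.normal(0.4, 1.3, 9)
        t, p = cohort_ttest(a, j)
        na, nj = len(a), len(j)
        sp2 = ((na - 1) * a.var(ddof=1) + (nj - 1) * j.var(ddof=1)) / (na + nj - 2)
        t_hand = (a.mean() - j.mean()) / math.sqrt(sp2 * (1 / na + 1 / nj))
        p_hand = 2 * stats.t.sf(abs(t_hand), na + nj - 2)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_zero_variance_both_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            cohort_ttest([1, 1, 1], [2, 2, 2])
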