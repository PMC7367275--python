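import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_alignment, random_genotype_matrix
from geckoabc import sumstats
from geckoabc.iodata import MISSING, GenotypeMatrix, SequenceAlignment


class TestLocusDiversity:
    def test_hand_enumerated_he_ho_fis(self, toy_fixtures):
        """Two individuals (100/104), (100/100): He = (4/3)(1 - 10/16) = 0.5."""
        div = sumstats.locus_diversity(toy_fixtures["he_toy"]["data"])
        row = div[div.population == "PopX"].iloc[0]
        assert row.He == pytest.approx(0.5)
        assert row.Ho == pytest.approx(0.5)
        assert row.FIS == pytest.approx(0.0)
        assert row.NA_alleles == 2

    def test_monomorphic_reports_nan_fis(self):
        calls = np.full((3, 1, 2), 100)
        G = GenotypeMatrix(["a", "b", "c"], ["L1"], calls, ["P"] * 3)
        row = sumstats.locus_diversity(G).iloc[0]
        assert row.NA_alleles == 1
        assert row.He == 0.0 and row.Ho == 0.0
        assert np.isnan(row.FIS)

    def test_fis_permutation_p_is_uniformish_under_null(self, rng):
        G = random_genotype_matrix(rng, n=20, loci=1, missing=0.0)
        div = sumstats.locus_diversity(G, fis_permutations=300, seed=4)
        p = div[div.population != "_all_"].FIS_p.dropna()
        assert ((p > 0) & (p <= 1)).all()

    def test_matches_bruteforce_oracle_on_random_inputs(self, rng):
        for _ in range(25):
            G = random_genotype_matrix(rng, n=10, loci=2, missing=0.15)
            div = sumstats.locus_diversity(G)
            for _, row in div[div.population == "_all_"].iterrows():
                j = G.loci.index(row.locus)
                col = G.calls[:, j, :]
                genod = col[col[:, 0] != MISSING]
                if len(genod) < 2:
                    continue
                copies = genod.ravel().tolist()
                assert row.He == pytest.approx(oracles.he_unbiased(copies))
                assert row.Ho == pytest.approx(
                    oracles.ho_observed([tuple(g) for g in genod]))


class TestWeirCockerham:
    def test_fixed_populations_give_theta_one(self):
        calls = np.zeros((20, 3, 2), int)
        calls[:10] = 100
        calls[10:] = 104
        G = GenotypeMatrix([f"i{j}" for j in range(20)], ["a", "b", "c"], calls,
                           ["P1"] * 10 + ["P2"] * 10)
        theta = sumstats.wc_theta(G.calls, np.array([0] * 10 + [1] * 10), 2)
        assert theta == pytest.approx(1.0)

    def test_identical_frequencies_give_near_zero(self, rng):
        calls = rng.choice([100, 104, 108, 112], size=(100, 10, 2))
        idx = np.array([0] * 50 + [1] * 50)
        theta = sumstats.wc_theta(calls, idx, 2)
        assert abs(theta) < 0.02

    def test_theta_centered_on_zero_under_label_permutation(self, rng):
        calls = rng.choice([100, 104, 108], size=(30, 4, 2))
        idx = np.array([0] * 15 + [1] * 15)
        thetas = [sumstats.wc_theta(calls, rng.permutation(idx), 2) for _ in range(300)]
        assert abs(np.mean(thetas)) < 3 * np.std(thetas) / np.sqrt(len(thetas)) + 1e-3

    def test_pairwise_matrix_shape_and_permutation_p(self, rng):
        G = random_genotype_matrix(rng, n=24, loci=3, missing=0.05)
        dm = sumstats.pairwise_fst(G, permutations=99, seed=3)
        assert dm.values.shape == (2, 2)
        assert dm.values[0, 0] == 0
        assert 0 < dm.pvalues[0, 1] <= 1
        assert np.isfinite(dm.global_value)

    def test_small_population_excluded_with_warning(self, rng):
        G = random_genotype_matrix(rng, n=9, loci=2, missing=0.0)
        pops = ["P1"] * 4 + ["P2"] * 4 + ["tiny"]
        G = GenotypeMatrix(G.individuals, G.loci, G.calls, pops)
        with pytest.warns(UserWarning, match="tiny"):
            dm = sumstats.pairwise_fst(G)
        assert "tiny" not in dm.labels


class TestNeiGst:
    def test_complete_sorting_gives_one(self):
        assert sumstats.nei_gst(np.array([[10, 0], [0, 10]])) == pytest.approx(1.0)

    def test_equal_frequencies_give_nonpositive(self):
        # correction term -(1 - sum p^2) / (2 (ntilde - 1)) pushes below zero
        assert sumstats.nei_gst(np.array([[5, 5], [5, 5]])) <= 0

    def test_diagonal_zero_and_symmetry(self):
        aln = SequenceAlignment(
            ["a", "b", "c", "d"], ["X", "X", "Y", "Y"], ["AAAA", "AAAT", "TTTT", "TTTA"])
        dm = sumstats.gst_sequences(aln)
        assert np.allclose(np.diag(dm.values), 0)
        assert np.allclose(dm.values, dm.values.T)


class TestHWE:
    def test_monomorphic_p_is_one(self):
        calls = np.full((4, 1, 2), 100)
        G = GenotypeMatrix([f"i{j}" for j in range(4)], ["L1"], calls, ["P"] * 4)
        res = sumstats.hwe_exact(G, mc_reps=1000, seed=0)
        assert res.exact_p.iloc[0] == 1.0
        assert res.chi2_p.iloc[0] == 1.0

    def test_two_allele_all_homozygote_exact_third(self):
        """Genotypes (AA, aa): enumeration over the 3 attainable tables gives 1/3."""
        calls = np.array([[[100, 100]], [[104, 104]]])
        G = GenotypeMatrix(["i1", "i2"], ["L1"], calls, ["P", "P"])
        res = sumstats.hwe_exact(G, mc_reps=30000, seed=1)
        expected = oracles.hwe_exact_enumeration([(100, 100), (104, 104)])
        assert expected == pytest.approx(1 / 3)
        se = np.sqrt(expected * (1 - expected) / 30000)
        assert abs(res.exact_p.iloc[0] - expected) < 3 * se + 2 / 30000

    def test_mc_agrees_with_enumeration_on_small_tables(self, rng):
        for _ in range(4):
            genos = [tuple(sorted(rng.choice([100, 104], 2))) for _ in range(4)]
            calls = np.array(genos).reshape(4, 1, 2)
            G = GenotypeMatrix([f"i{j}" for j in range(4)], ["L1"], calls, ["P"] * 4)
            if len(np.unique(calls)) < 2:
                continue
            res = sumstats.hwe_exact(G, mc_reps=20000, seed=9)
            exact = oracles.hwe_exact_enumeration(genos)
            se = np.sqrt(exact * (1 - exact) / 20000)
            assert abs(res.exact_p.iloc[0] - exact) < 4 * se + 2 / 20000

    def test_low_reps_warns(self):
        calls = np.array([[[100, 104]], [[100, 100]]])
        G = GenotypeMatrix(["i1", "i2"], ["L1"], calls, ["P", "P"])
        with pytest.warns(UserWarning, match="unstable"):
            sumstats.hwe_exact(G, mc_reps=100, seed=0)

    def test_chi2_df_is_k_choose_2(self, rng):
        G = random_genotype_matrix(rng, n=30, loci=1, n_alleles=4, missing=0.0)
        res = sumstats.hwe_exact(G, mc_reps=1000, seed=2)
        k = len(np.unique(G.calls))
        assert res.df.iloc[0] == k * (k - 1) // 2


class TestBenjaminiYekutieli:
    def test_hand_computed_example(self):
        reject, crit = sumstats.benjamini_yekutieli([0.001, 0.01, 0.02, 0.5], 0.05)
        assert reject.tolist() == [True, True, False, False]
        assert crit == pytest.approx(2 * 0.05 / (4 * 25 / 12))

    def test_all_ones_rejects_nothing(self):
        reject, crit = sumstats.benjamini_yekutieli([1.0] * 6, 0.05)
        assert not reject.any()
        assert crit == 0.0

    def test_single_test_reduces_to_alpha(self):
        assert sumstats.benjamini_yekutieli([0.04], 0.05)[0].all()
        assert not sumstats.benjamini_yekutieli([0.06], 0.05)[0].any()

    def test_empty_input(self):
        reject, crit = sumstats.benjamini_yekutieli([], 0.05)
        assert reject.size == 0 and crit == 0.0

    def test_agrees_with_exhaustive_search_small_m(self, rng):
        for _ in range(40):
            m = rng.integers(1, 11)
            p = np.round(rng.random(m), 3)
            mine, crit = sumstats.benjamini_yekutieli(p, 0.05)
            oracle, ocrit = oracles.by_exhaustive(p, 0.05)
            assert mine.tolist() == oracle.tolist()

    def test_rejection_set_monotone_in_alpha(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=60, derandomize=True)
        @given(st.lists(st.floats(0, 1), min_size=1, max_size=12),
               st.floats(0.01, 0.2), st.floats(0.01, 0.2))
        def check(pvals, a1, a2):
            lo, hi = sorted((a1, a2))
            r_lo, _ = sumstats.benjamini_yekutieli(pvals, lo)
            r_hi, _ = sumstats.benjamini_yekutieli(pvals, hi)
            # a stricter alpha can never reject more hypotheses
            assert not (r_lo & ~r_hi).any()

        check()

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(rng.integers(2, 15))
            mine, _ = sumstats.benjamini_yekutieli(p, 0.05)
            theirs = multipletests(p, alpha=0.05, method="fdr_by")[0]
            assert mine.tolist() == theirs.tolist()


class TestAlleleSharing:
    def test_identical_and_disjoint(self):
        calls = np.array([
            [[100, 104], [200, 200]],
            [[100, 104], [200, 200]],
            [[108, 112], [204, 208]],
        ])
        G = GenotypeMatrix(["a", "b", "c"], ["L1", "L2"], calls, ["P"] * 3)
        psa = sumstats.allele_sharing(G)
        assert psa.loc["a", "b"] == pytest.approx(1.0)
        assert psa.loc["a", "c"] == pytest.approx(0.0)
        assert psa.loc["a", "a"] == 1.0

    def test_hand_enumerated_half_sharing(self):
        calls = np.array([
            [[100, 104], [200, 200]],
            [[100, 100], [200, 204]],
        ])
        G = GenotypeMatrix(["i1", "i2"], ["L1", "L2"], calls, ["P", "P"])
        assert sumstats.allele_sharing(G).loc["i1", "i2"] == pytest.approx(0.5)

    def test_no_shared_loci_is_nan(self):
        calls = np.array([
            [[100, 100], [-1, -1]],
            [[-1, -1], [200, 200]],
        ])
        G = GenotypeMatrix(["i1", "i2"], ["L1", "L2"], calls, ["P", "P"])
        assert np.isnan(sumstats.allele_sharing(G).loc["i1", "i2"])

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            G = random_genotype_matrix(rng, n=6, loci=3, missing=0.2)
            psa = sumstats.allele_sharing(G)
            for i in range(6):
                for j in range(i + 1, 6):
                    expected = oracles.psa_pair(
                        [tuple(g) for g in G.calls[i]], [tuple(g) for g in G.calls[j]])
                    got = psa.iloc[i, j]
                    if np.isnan(expected):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(expected)


class TestSequenceDiversity:
    def test_identical_sequences(self):
        aln = SequenceAlignment(["a", "b", "c"], ["P"] * 3, ["ACGT"] * 3)
        d = sumstats.sequence_diversity(aln)
        assert (d.n_hap, d.S, d.pi, d.Hd) == (1, 0, 0.0, 0.0)

    def test_two_sequences_one_difference(self):
        aln = SequenceAlignment(["a", "b"], ["P", "P"], ["ACGT", "ACGA"])
        d = sumstats.sequence_diversity(aln)
        assert d.pi == pytest.approx(0.25)
        assert d.k == pytest.approx(1.0)
        assert d.Hd == pytest.approx(1.0)

    def test_single_sequence_reports_nan(self):
        aln = SequenceAlignment(["a"], ["P"], ["ACGT"])
        d = sumstats.sequence_diversity(aln)
        assert np.isnan(d.pi) and np.isnan(d.k) and np.isnan(d.Hd)

    def test_invariants_and_oracle_on_random_alignments(self, rng):
        for _ in range(20):
            aln = random_alignment(rng, n=6, length=15, with_missing=True)
            d = sumstats.sequence_diversity(aln)
            assert d.eta >= d.S
            assert 0 <= d.Hd <= 1
            if d.pi > 0:
                assert d.k == pytest.approx(d.pi * d.effective_length)
                assert d.max_p >= d.pi - 1e-12
            k_oracle, pi_oracle = oracles.mean_pairwise(aln.sequences)
            assert d.k == pytest.approx(k_oracle)
            assert d.pi == pytest.approx(pi_oracle)


class TestPDistance:
    def test_trivial_quarter(self):
        aln = SequenceAlignment(["a", "b"], ["P", "P"], ["ACGT", "ACGA"])
        assert sumstats.p_distance_matrix(aln).iloc[0, 1] == pytest.approx(0.25)

    def test_self_distance_zero(self, rng):
        aln = random_alignment(rng, n=4, length=10)
        assert np.allclose(np.diag(sumstats.p_distance_matrix(aln)), 0)

    def test_no_comparable_sites_is_nan(self):
        aln = SequenceAlignment(["a", "b"], ["P", "P"], ["NN", "AC"])
        assert np.isnan(sumstats.p_distance_matrix(aln).iloc[0, 1])

    def test_matches_oracle(self, rng):
        aln = random_alignment(rng, n=5, length=20, with_missing=True)
        pd_m = sumstats.p_distance_matrix(aln)
        for i in range(5):
            for j in range(5):
                expected = oracles.p_distance(aln.sequences[i], aln.sequences[j]) if i != j else 0.0
                got = pd_m.iloc[i, j]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)
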