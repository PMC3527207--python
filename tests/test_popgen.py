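import itertools

import numpy as np
import pytest

from conftest import make_alignment
from cytosym.popgen import (binomial_proportion_ci, concordance,
                            conditional_coalescent_null, diversity_summary,
                            exhaustive_kst_pvalue, infection_fraction_test,
                            kst_permutation_test, kst_statistic,
                            nucleotide_diversity_pi, tajimas_d,
                            watterson_theta)

@pytest.fixture
def singleton_aln():
    """4 sequences, 3 singleton sites over L=16 (hand-enumerated oracle)."""
    # s1 differs at col 1, s2 at col 2, s3 at col 16: three singleton sites
    return make_alignment({
        "s1": "CACGTACGTACGTACG",
        "s2": "AGCGTACGTACGTACG",
        "s3": "AACGTACGTACGTACT",
        "s4": "AACGTACGTACGTACG",
    })


class TestDiversity:
    def test_pi_two_sequences(self):
        aln = make_alignment({"a": "ACGTACGTAC", "b": "TCGTACGTAC"})
        assert nucleotide_diversity_pi(aln) == pytest.approx(0.1)

    def test_pi_identical(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT"})
        assert nucleotide_diversity_pi(aln) == 0.0

    def test_pi_hand_enumeration(self, singleton_aln):
        # each singleton separates 3 of the 6 pairs: (3*3/6)/16
        assert nucleotide_diversity_pi(singleton_aln) == pytest.approx(
            (9 / 6) / 16)

    def test_theta_examples(self, singleton_aln):
        two = make_alignment({"a": "A" * 100,
                              "b": "CCCCC" + "A" * 95})
        assert watterson_theta(two) == pytest.approx(0.05)   # a1 = 1
        a1 = 1 + 1 / 2 + 1 / 3
        assert watterson_theta(singleton_aln) == pytest.approx(3 / (a1 * 16))
        mono = make_alignment({"a": "ACGT", "b": "ACGT"})
        assert watterson_theta(mono) == 0.0

    def test_theta_eta_counts_triallelic_twice(self):
        aln = make_alignment({"a": "AAAA", "b": "CAAA", "c": "GAAA"})
        assert watterson_theta(aln, count="eta") > watterson_theta(aln, "S")

    def test_tajimas_d_frozen_oracle(self, singleton_aln):
        # independent evaluation of the 1989 constants gives -0.754451
        assert tajimas_d(singleton_aln) == pytest.approx(-0.754451, abs=1e-5)

    def test_all_singletons_negative(self, singleton_aln):
        assert tajimas_d(singleton_aln) < 0

    def test_d_undefined_without_variation(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT"})
        with pytest.raises(ValueError):
            tajimas_d(aln)

    def test_summary_consistency(self, singleton_aln):
        est = diversity_summary(singleton_aln)
        assert (est.n, est.L, est.S, est.eta) == (4, 16, 3, 3)
        assert est.theta_w >= 0 and est.pi >= 0


class TestConditionalNull:
    def test_extreme_observation_bounded_p(self):
        _, p = conditional_coalescent_null(10, 20, 400, seed=1,
                                           observed_d=-10.0)
        assert p == pytest.approx(1 / 400)

    def test_mean_d_is_stable_across_reruns(self):
        d1, _ = conditional_coalescent_null(20, 30, 3000, seed=2)
        d2, _ = conditional_coalescent_null(20, 30, 3000, seed=3)
        assert abs(d1.mean() - d2.mean()) < 0.05

    def test_seed_reproducibility(self):
        d1, _ = conditional_coalescent_null(12, 7, 200, seed=9)
        d2, _ = conditional_coalescent_null(12, 7, 200, seed=9)
        assert np.array_equal(d1, d2)

    def test_sfs_against_msprime_oracle(self):
        """Cross-check: mean pairwise diversity of the conditional placement
        matches msprime's infinite-sites expectation ratio pi/S."""
        msprime = pytest.importorskip("msprime")
        n, S, reps = 8, 12, 1500
        d_ours, _ = conditional_coalescent_null(n, S, reps, seed=4)
        rng = np.random.default_rng(5)
        ds = []
        from cytosym.popgen import tajimas_d_from_parts
        for _ in range(400):
            ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1,
                                      random_seed=int(rng.integers(1, 2**31)))
            tree = ts.first()
            # place S mutations proportionally to branch length
            nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
            lens = np.array([tree.branch_length(u) for u in nodes])
            sizes = np.array([tree.num_samples(u) for u in nodes])
            muts = rng.multinomial(S, lens / lens.sum())
            sfs = np.zeros(n - 1)
            for m, k in zip(muts, sizes):
                if 0 < k < n:
                    sfs[k - 1] += m
            k = np.arange(1, n)
            pi_total = (sfs * k * (n - k)).sum() / (n * (n - 1) / 2)
            ds.append(tajimas_d_from_parts(n, int(sfs.sum()), pi_total))
        assert abs(np.mean(d_ours) - np.mean(ds)) < 0.12


class TestKst:
    def test_perfect_separation(self):
        D = np.array([[0, 0, 3, 3], [0, 0, 3, 3],
                      [3, 3, 0, 0], [3, 3, 0, 0]], float)
        labels = np.array(["i", "i", "u", "u"])
        assert kst_statistic(D, labels) == pytest.approx(1.0)

    def test_equal_distances_give_zero(self):
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        labels = np.array(["i", "i", "u", "u"])
        assert kst_statistic(D, labels) == pytest.approx(0.0)

    def test_hand_enumerated_example(self):
        D = np.full((4, 4), 3.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 1.0
        D[2, 3] = D[3, 2] = 1.0
        labels = np.array(["a", "a", "b", "b"])
        assert kst_statistic(D, labels) == pytest.approx(1 - 6 / 14)

    def test_label_permutation_invariance(self, rng):
        n = 8
        base = rng.random((n, n))
        D = base + base.T
        np.fill_diagonal(D, 0.0)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        k0 = kst_statistic(D, labels)
        perm = rng.permutation(n)
        assert kst_statistic(D[np.ix_(perm, perm)],
                             labels[perm]) == pytest.approx(k0)

    def test_undefined_cases(self):
        D = np.full((2, 2), 1.0)
        np.fill_diagonal(D, 0.0)
        with pytest.raises(ValueError):
            kst_statistic(D, np.array(["a", "b"]))   # both groups singletons

    def test_permutation_matches_exhaustive_enumeration(self, rng):
        """Single population of 5: Monte-Carlo p vs all 120 permutations."""
        n = 5
        base = rng.random((n, n))
        D = base + base.T
        np.fill_diagonal(D, 0.0)
        labels = np.array(["i", "i", "i", "u", "u"])
        pops = np.array(["p"] * n)
        exact = exhaustive_kst_pvalue(D, labels)
        res = kst_permutation_test(D, labels, pops, n_perm=4000, seed=8)
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(res.p_value - exact) < 2 * se + 1 / 4000 + 5e-3

    def test_uniform_population_contributes_nothing(self):
        D = np.full((6, 6), 1.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.1
        labels = np.array(["i", "u", "i", "u", "i", "i"])
        pops = np.array(["p1"] * 4 + ["p2"] * 2)   # p2 all infected
        res = kst_permutation_test(D, labels, pops, n_perm=50, seed=1)
        assert set(res.per_population) == {"p1"}


class TestProportionsAndConcordance:
    def test_clopper_pearson_reported_row(self):
        lo, hi = binomial_proportion_ci(88, 116)
        assert round(lo, 2) == 0.67 and round(hi, 2) == 0.83
        assert round(100 * 88 / 116, 1) == 75.9

    def test_boundaries(self):
        assert binomial_proportion_ci(0, 10)[0] == 0.0
        assert binomial_proportion_ci(10, 10)[1] == 1.0

    def test_matches_statsmodels_beta_interval(self):
        sm = pytest.importorskip("statsmodels.stats.proportion")
        for x, n in ((3, 17), (50, 60), (1, 2)):
            ours = binomial_proportion_ci(x, n)
            theirs = sm.proportion_confint(x, n, method="beta")
            assert ours == pytest.approx(theirs)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            binomial_proportion_ci(11, 10)

    def test_concordance(self):
        a = {f"s{i}": (i % 2 == 0) for i in range(10)}
        b = dict(a)
        b["s3"] = not b["s3"]
        n_agree, n_total, frac, disc = concordance(a, b)
        assert (n_agree, n_total) == (9, 10)
        assert frac == pytest.approx(0.9)
        assert disc == ["s3"]

    def test_concordance_key_mismatch(self):
        with pytest.raises(ValueError):
            concordance({"a": True}, {"b": True})

    def test_fisher_exact_panel_comparison(self):
        """Strongly different infected fractions give a tiny p; identical
        fractions give p = 1 (cross-checked against scipy directly)."""
        from scipy.stats import fisher_exact

        p = infection_fraction_test(91, 174, 88, 116)
        _, expected = fisher_exact([[91, 83], [88, 28]])
        assert p == pytest.approx(expected)
        assert p < 1e-4
        assert infection_fraction_test(10, 20, 5, 10) == pytest.approx(1.0)
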