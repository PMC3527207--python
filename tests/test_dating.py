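import numpy as np
import pytest
from scipy.linalg import expm

from cytosym.dating import (ChainSettings, coalescent_intervals_log_density,
                            coalescent_tree_log_prior, lognormal_rate_prior,
                            phylogeo_ancestral_states,
                            prepare_dating_alignment, run_dating_mcmc,
                            summarize_posterior)
from cytosym.trees import tree_from_newick


class TestRatePrior:
    def test_central_rate_matches_quoted_value(self):
        prior = lognormal_rate_prior()
        assert prior.central_rate == pytest.approx(6.2e-8, abs=0.05e-8)

    def test_point_mass_at_zero_sigma(self):
        prior = lognormal_rate_prior(-16.0, 0.0)
        assert prior.quantile(0.5) == pytest.approx(np.exp(-16.0))
        assert prior.logpdf_log_rate(-16.0) == 0.0
        assert prior.logpdf_log_rate(-15.0) == -np.inf

    def test_quantiles_closed_form(self):
        mu, sigma = -16.59613, 1 / 3
        prior = lognormal_rate_prior(mu, sigma)
        lo, hi = prior.quantile([0.025, 0.975])
        assert lo == pytest.approx(np.exp(mu - 1.959964 * sigma), rel=1e-6)
        assert hi == pytest.approx(np.exp(mu + 1.959964 * sigma), rel=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            lognormal_rate_prior(-16.0, -0.1)


class TestCoalescentPrior:
    def test_two_tip_closed_form(self):
        for t, N in ((100.0, 1000.0), (5.0, 2.0)):
            assert coalescent_intervals_log_density(
                [t], N) == pytest.approx(-np.log(N) - t / N)

    def test_scaling_invariance_up_to_jacobian(self):
        """Scaling ages and N by c changes the density by -(n-1) ln c."""
        ages = np.array([10.0, 30.0, 75.0])
        N, c = 40.0, 7.0
        lp1 = coalescent_intervals_log_density(ages, N)
        lp2 = coalescent_intervals_log_density(ages * c, N * c)
        assert lp2 - lp1 == pytest.approx(-ages.size * np.log(c))

    def test_inconsistent_tree_rejected(self):
        tree = tree_from_newick("((A:1,B:1):1,C:2);")
        for node in tree.postorder_node_iter():
            node.age = 0.0 if node.is_leaf() else None
        # parent younger than child
        inner = [n for n in tree.preorder_internal_node_iter()]
        inner[0].age = 1.0   # root
        inner[1].age = 5.0   # child older than root
        with pytest.raises(ValueError):
            coalescent_tree_log_prior(tree, 10.0)


@pytest.fixture(scope="module")
def dating_inputs():
    from cytosym.synthetic import (SyntheticParams, evolve_alignments,
                                   simulate_cytoplasmic_history)

    rates = dict(mt_codon12=1.36e-8, mt_codon3=6.2e-8, wol_codon12=6.2e-10,
                 wol_codon3=6.2e-10, wol_noncoding=6.2e-10)
    params = SyntheticParams(n_strains=8, class_rates=rates, loss_rate=0.0,
                             effective_size=500_000, mt_length=1500,
                             wol_length=4000, seed=77)
    rng = np.random.default_rng(77)
    tree, infected = simulate_cytoplasmic_history(params, rng)
    mt, wol = evolve_alignments(tree, infected, params, rng)
    return prepare_dating_alignment(mt, wol), tree


class TestDatingMCMC:
    def test_prior_only_recovers_calibration_prior(self, dating_inputs):
        aln, tree = dating_inputs
        prior = lognormal_rate_prior()
        samples = run_dating_mcmc(
            aln, tree, rate_prior=prior,
            settings=ChainSettings(n_iterations=1500, likelihood_off=True),
            seed=5)
        logr = np.log(samples["rate_mt_codon3"])
        assert logr.median() == pytest.approx(prior.mu_log, abs=0.06)
        assert logr.std() == pytest.approx(prior.sigma_log, rel=0.2)

    def test_seed_reproducibility(self, dating_inputs):
        aln, tree = dating_inputs
        s1 = run_dating_mcmc(aln, tree,
                             settings=ChainSettings(n_iterations=60), seed=3)
        s2 = run_dating_mcmc(aln, tree,
                             settings=ChainSettings(n_iterations=60), seed=3)
        assert s1.equals(s2)

    def test_unrooted_topology_rejected(self, dating_inputs):
        aln, tree = dating_inputs
        unrooted = tree.clone(depth=1)
        unrooted.is_rooted = False
        with pytest.raises(ValueError):
            run_dating_mcmc(aln, unrooted,
                            settings=ChainSettings(n_iterations=5), seed=1)


class TestSummaries:
    def _samples(self, ages):
        import pandas as pd
        df = pd.DataFrame({"age_mrca(a,b)": ages,
                           "rate_mt_codon3": np.full(len(ages), 6e-8),
                           "effective_size": np.full(len(ages), 1e5)})
        df.attrs["seed"] = 0
        return df

    def test_generations_to_years_conversion(self):
        post = summarize_posterior(self._samples([76_287.0] * 10))
        assert post.age_median["mrca(a,b)"] == pytest.approx(76_287.0)
        assert post.age_median_years["mrca(a,b)"] == pytest.approx(7_628.7)

    def test_constant_chain_zero_width_ci(self):
        post = summarize_posterior(self._samples([500.0] * 8))
        lo, hi = post.age_ci["mrca(a,b)"]
        assert lo == hi == 500.0

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(self._samples([]))


class TestPhylogeography:
    def test_uniform_tips_give_certain_root(self):
        tree = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        Q, probs = phylogeo_ancestral_states(
            tree, {s: "Africa" for s in "ABCD"})
        for key, p in probs.items():
            if key.startswith("mrca"):
                assert p[0] == pytest.approx(1.0, abs=1e-6)

    def test_three_taxon_brute_force_likelihood(self):
        """Pruning equals the 3^2-term enumeration for a fixed Q."""
        from cytosym.dating import _geo_loglik
        from cytosym.likelihood import flatten_tree

        tree = tree_from_newick("((A:0.3,B:0.8):0.5,C:1.2);")
        flat = flatten_tree(tree)
        rng = np.random.default_rng(0)
        Q = rng.random((3, 3))
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        tips = {"A": 0, "B": 1, "C": 2}
        tip_states = np.array([tips[l] for l in flat.tip_labels])
        root_freqs = np.full(3, 1 / 3)
        ll, *_ = _geo_loglik(Q, flat, tip_states, root_freqs)

        # brute force over internal states (root r, inner n)
        P = {}
        for i in range(flat.n_nodes):
            if flat.parent[i] >= 0:
                P[i] = expm(Q * flat.lengths[i])
        children = {i: [c for c in range(flat.n_nodes)
                        if flat.parent[c] == i] for i in range(flat.n_nodes)}
        root = flat.postorder[-1]
        inner = [i for i in range(flat.n_tips, flat.n_nodes) if i != root]
        total = 0.0
        for r in range(3):
            for n_state in range(3):
                assign = {root: r, inner[0]: n_state}
                for i in range(flat.n_tips):
                    assign[i] = tip_states[i]
                term = root_freqs[r]
                for i in range(flat.n_nodes):
                    if flat.parent[i] >= 0:
                        term *= P[i][assign[flat.parent[i]], assign[i]]
                total += term
        assert ll == pytest.approx(np.log(total), abs=1e-10)

    def test_unlabeled_tip_rejected(self):
        tree = tree_from_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            phylogeo_ancestral_states(tree, {"A": "Africa", "B": "Europe"})

    def test_recovers_structured_tips(self):
        """Clades with uniform locations give confident ancestral states."""
        tree = tree_from_newick(
            "((A:0.1,B:0.1):2.0,(C:0.1,D:0.1):2.0);")
        Q, probs = phylogeo_ancestral_states(
            tree, {"A": "Africa", "B": "Africa",
                   "C": "Europe", "D": "Europe"})
        assert probs["mrca(A,B)"][0] > 0.9    # Africa side
        assert probs["mrca(C,D)"][1] > 0.9    # Europe side
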