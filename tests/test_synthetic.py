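import numpy as np
import pytest
from scipy.stats import poisson

from cytosym.coverage import breadth_of_coverage, call_consensus
from cytosym.synthetic import (SyntheticParams, evolve_alignments,
                               make_fixture_bundle,
                               simulate_cytoplasmic_history, simulate_dataset,
                               simulate_depth_profiles, strain_names)


class TestHistory:
    def test_zero_loss_rate_means_all_infected(self, rng):
        params = SyntheticParams(n_strains=10, loss_rate=0.0)
        _, infected = simulate_cytoplasmic_history(params, rng)
        assert all(infected.values())

    def test_huge_loss_rate_means_all_uninfected(self, rng):
        params = SyntheticParams(n_strains=10, loss_rate=1.0)
        _, infected = simulate_cytoplasmic_history(params, rng)
        assert not any(infected.values())

    def test_mean_tmrca_matches_coalescent_expectation(self):
        """E[TMRCA] = 2N(1 - 1/n); Monte-Carlo check at n=4, N=1."""
        params = SyntheticParams(n_strains=4, effective_size=1.0)
        ages = []
        for i in range(4000):
            tree, _ = simulate_cytoplasmic_history(
                params, np.random.default_rng(i))
            ages.append(tree.seed_node.age)
        # var(TMRCA) ~ 1.12 at n=4 -> SE ~ 0.017
        assert np.mean(ages) == pytest.approx(1.5, abs=0.06)

    def test_ultrametric_ages(self, rng):
        params = SyntheticParams(n_strains=12)
        tree, _ = simulate_cytoplasmic_history(params, rng)
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                assert node.age > child.age - 1e-9
                assert child.edge.length == pytest.approx(node.age - child.age)

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_labels_follow_single_gain_multiple_loss(self, seed):
        """A tip is infected iff its root path carries zero loss events."""
        params = SyntheticParams(n_strains=30, loss_rate=2e-5, seed=seed)
        tree, infected = simulate_cytoplasmic_history(params)
        for leaf in tree.leaf_node_iter():
            losses, node = 0, leaf
            while node is not tree.seed_node:
                losses += node.n_losses
                node = node.parent_node
            assert infected[leaf.taxon.label] == (losses == 0)

    def test_too_few_strains_rejected(self):
        with pytest.raises(ValueError):
            SyntheticParams(n_strains=1)


class TestSequenceEvolution:
    def test_zero_rates_give_identical_sequences(self, rng):
        params = SyntheticParams(
            n_strains=6, mt_length=300, wol_length=300,
            class_rates={k: 0.0 for k in
                         ("mt_codon12", "mt_codon3", "wol_codon12",
                          "wol_codon3", "wol_noncoding")})
        tree, infected = simulate_cytoplasmic_history(params, rng)
        mt, wol = evolve_alignments(tree, infected, params, rng)
        assert (mt.matrix == mt.matrix[0]).all()
        if wol.n_sequences:
            assert (wol.matrix == wol.matrix[0]).all()

    def test_two_strain_small_rt_divergence(self):
        """Expected pairwise difference ~ 2 t r per site for small r t."""
        r, t_half = 1e-3, 50.0   # per-branch length 50 generations
        diffs = []
        for seed in range(40):
            params = SyntheticParams(
                n_strains=2, effective_size=1.0, mt_length=4000,
                gamma_alpha=1000.0,  # essentially rate-homogeneous
                class_rates=dict(mt_codon12=r, mt_codon3=r, wol_codon12=0,
                                 wol_codon3=0, wol_noncoding=0),
                seed=seed)
            tree, infected = simulate_cytoplasmic_history(
                params, np.random.default_rng(seed))
            # force a known divergence time
            root = tree.seed_node
            root.age = t_half
            for child in root.child_nodes():
                child.edge.length = t_half
            mt, _ = evolve_alignments(tree, infected, params,
                                      np.random.default_rng(seed + 1))
            diffs.append((mt.matrix[0] != mt.matrix[1]).mean())
        expected = 2 * t_half * r
        assert np.mean(diffs) == pytest.approx(expected, rel=0.15)

    def test_doubling_codon3_rate_does_not_reduce_variable_sites(self):
        counts = []
        for factor in (1.0, 2.0):
            vals = []
            for seed in range(12):
                params = SyntheticParams(
                    n_strains=8, mt_length=1500, wol_length=300,
                    class_rates=dict(mt_codon12=1.36e-8,
                                     mt_codon3=6.2e-8 * factor,
                                     wol_codon12=0, wol_codon3=0,
                                     wol_noncoding=0),
                    seed=seed)
                tree, infected = simulate_cytoplasmic_history(
                    params, np.random.default_rng(seed))
                mt, _ = evolve_alignments(tree, infected, params,
                                          np.random.default_rng(seed + 100))
                third = mt.subset_columns(mt.site_class == "codon3")
                vals.append(int(third.variable_columns().sum()))
            counts.append(np.mean(vals))
        assert counts[1] >= counts[0]

    def test_wolbachia_rows_only_for_infected(self, small_dataset):
        infected = small_dataset["infected"]
        wol = small_dataset["wol_alignment"]
        assert set(wol.ids) == {s for s, v in infected.items() if v}


class TestDepthProfiles:
    def _world(self, **kw):
        params = SyntheticParams(n_strains=6, mt_length=400, wol_length=1000,
                                 nuclear_length=200, seed=2, **kw)
        return params, simulate_dataset(params)

    def test_clean_uninfected_has_zero_wolbachia_profile(self):
        params, data = self._world(contamination_fraction=0.0, loss_rate=3e-5)
        for s, inf in data["infected"].items():
            if not inf:
                assert data["profiles"][(s, "wolbachia")].depths.sum() == 0

    def test_consensus_breadth_matches_poisson_closed_form(self):
        """At depth 20 the per-site callable probability is
        P(10 <= Poisson(20) <= 100) ~ 0.995, so breadth >~ 0.99."""
        params, data = self._world(loss_rate=0.0)
        p_callable = poisson.cdf(100, 20) - poisson.cdf(9, 20)
        assert p_callable > 0.99
        s = strain_names(params.n_strains)[0]
        cons = call_consensus(data["base_counts"][(s, "wolbachia")],
                              params.wol_length)
        assert breadth_of_coverage(cons) > 0.98

    def test_negative_depth_mean_rejected(self):
        with pytest.raises(ValueError):
            SyntheticParams(depth_means={"mtdna": -1.0, "wolbachia": 1,
                                         "nuclear": 1})

    def test_seeded_reproducibility(self):
        _, d1 = self._world()
        _, d2 = self._world()
        s = strain_names(6)[0]
        assert np.array_equal(d1["profiles"][(s, "mtdna")].depths,
                              d2["profiles"][(s, "mtdna")].depths)
        assert d1["base_counts"][(s, "wolbachia")].equals(
            d2["base_counts"][(s, "wolbachia")])


class TestFixtureBundle:
    def test_bundle_roundtrip_and_consistency(self, tmp_path):
        from cytosym import io as cio

        params = SyntheticParams(n_strains=5, mt_length=300, wol_length=600,
                                 nuclear_length=150, seed=9)
        truth = make_fixture_bundle(params, tmp_path)
        profiles = cio.read_depth_profiles(tmp_path / "depth_profiles.tsv")
        counts = cio.read_base_counts(tmp_path / "base_counts.tsv")
        meta = cio.read_metadata(tmp_path / "metadata.tsv")
        ann = cio.read_annotation(tmp_path / "annotation.tsv")
        loaded = cio.read_truth(tmp_path / "truth.json")
        assert len(meta) == 5
        assert set(loaded["infected"]) == set(strain_names(5))
        assert loaded["infected"] == {k: bool(v)
                                      for k, v in truth.infected.items()}
        assert ann["mtdna"].shape == (300,)
        s = strain_names(5)[0]
        assert profiles[(s, "mtdna")].depths.shape == (300,)
        assert len(counts[(s, "wolbachia")]) == 600
        # truth infected count equals strains with nonzero Wolbachia depth
        # mean in the generative model (contamination aside, uninfected
        # strains have zero or patchy-low coverage, infected have full)
        full_cov = sum(profiles[(x, "wolbachia")].depths.mean() > 5
                       for x in strain_names(5))
        assert full_cov == sum(truth.infected.values())

    def test_same_seed_identical_files(self, tmp_path):
        params = SyntheticParams(n_strains=4, mt_length=200, wol_length=300,
                                 nuclear_length=100, seed=3)
        make_fixture_bundle(params, tmp_path / "a")
        make_fixture_bundle(params, tmp_path / "b")
        for name in ("depth_profiles.tsv", "base_counts.tsv", "truth.json",
                     "metadata.tsv", "truth_tree.nwk", "annotation.tsv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes()), name
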