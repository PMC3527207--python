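"""Pruning-likelihood checks against closed forms and brute-force enumeration."""

import itertools

import numpy as np
import pytest

from conftest import make_alignment
from cytosym.alignment import PartitionedAlignment
from cytosym.likelihood import (TreeLikelihood, optimize_branch_lengths,
                                partition_loglik)
from cytosym.substitution import SubstitutionModel
from cytosym.trees import tree_from_newick


def brute_force_loglik(aln, tree, model):
    """Sum over all internal-node state assignments (oracle for <=5 taxa)."""
    from cytosym.likelihood import flatten_tree

    flat = flatten_tree(tree)
    internals = [i for i in range(flat.n_nodes) if i >= flat.n_tips]
    root = flat.postorder[-1]
    pi = np.array(model.freqs)
    cats = model.category_rates()
    row = {lab: i for i, lab in enumerate(aln.ids)}
    total = 0.0
    for col in range(aln.n_columns):
        site = 0.0
        for c in cats:
            P = {i: model.transition_probs(c * flat.lengths[i])
                 for i in range(flat.n_nodes) if flat.parent[i] >= 0}
            s = 0.0
            for states in itertools.product(range(4), repeat=len(internals)):
                assign = dict(zip(internals, states))
                for i in range(flat.n_tips):
                    assign[i] = aln.matrix[row[flat.tip_labels[i]], col]
                term = pi[assign[root]]
                for i in range(flat.n_nodes):
                    if flat.parent[i] >= 0:
                        term *= P[i][assign[flat.parent[i]], assign[i]]
                s += term
            site += s / len(cats)
        total += np.log(site)
    return total


class TestPartitionLoglik:
    def test_two_taxon_jc_closed_form(self):
        model = SubstitutionModel(kappa=1.0, freqs=(0.25,) * 4, alpha=None)
        t = 0.3
        tree = tree_from_newick(f"(A:{t / 2},B:{t / 2});")
        p_same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        for match, prob in ((True, p_same), (False, (1 - p_same) / 3)):
            aln = make_alignment({"A": "A", "B": "A" if match else "C"})
            ll = partition_loglik(aln, tree, {"noncoding": model})
            assert ll == pytest.approx(np.log(0.25 * prob))

    def test_zero_lengths_identical_sequences(self):
        model = SubstitutionModel(kappa=3.0, freqs=(0.1, 0.2, 0.3, 0.4))
        tree = tree_from_newick("((A:0,B:0):0,C:0);")
        aln = make_alignment({"A": "ACGT", "B": "ACGT", "C": "ACGT"})
        ll = partition_loglik(aln, tree, {"noncoding": model})
        expected = sum(np.log(model.freqs[b]) for b in (0, 1, 2, 3))
        assert ll == pytest.approx(expected)

    @pytest.mark.parametrize("newick,n", [
        ("((A:0.1,B:0.25):0.05,(C:0.4,D:0.02):0.11);", 4),
        ("(((A:0.12,B:0.05):0.07,C:0.3):0.02,(D:0.2,E:0.09):0.15);", 5),
    ])
    def test_matches_brute_force_enumeration(self, newick, n, rng):
        model = SubstitutionModel(kappa=3.0, freqs=(0.1, 0.2, 0.3, 0.4),
                                  alpha=0.7)
        tree = tree_from_newick(newick)
        labels = list("ABCDE")[:n]
        m = rng.integers(0, 4, (n, 12)).astype(np.int8)
        aln = PartitionedAlignment(labels, m, np.full(12, "x", object),
                                   np.arange(1, 13))
        fast = partition_loglik(aln, tree, {"x": model})
        slow = brute_force_loglik(aln, tree, model)
        assert fast == pytest.approx(slow, abs=1e-8)

    def test_per_class_rate_multiplier(self):
        """rate r on class lengths equals scaling every branch by r."""
        model = SubstitutionModel(kappa=2.0, freqs=(0.25,) * 4, alpha=0.5)
        t1 = tree_from_newick("((A:0.1,B:0.2):0.1,(C:0.3,D:0.1):0.05);")
        t2 = tree_from_newick("((A:0.05,B:0.1):0.05,(C:0.15,D:0.05):0.025);")
        aln = make_alignment({"A": "ACGTAC", "B": "ACGAAC",
                              "C": "GCGTAT", "D": "ACTTAC"})
        ll1 = partition_loglik(aln, t1, {"noncoding": model},
                               rates={"noncoding": 0.5})
        ll2 = partition_loglik(aln, t2, {"noncoding": model})
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_tip_mismatch_rejected(self):
        model = SubstitutionModel()
        tree = tree_from_newick("((A:1,B:1):1,C:1);")
        aln = make_alignment({"A": "A", "B": "C", "X": "G"})
        with pytest.raises(ValueError):
            partition_loglik(aln, tree, {"noncoding": model})


class TestOptimizeBranchLengths:
    def test_two_taxon_ml_equals_jc_distance(self):
        """Under JC the ML total length has the closed form JC correction."""
        model = SubstitutionModel(kappa=1.0, freqs=(0.25,) * 4, alpha=None)
        k, L = 10, 200
        seq_a = "A" * L
        seq_b = "C" * k + "A" * (L - k)
        aln = make_alignment({"A": seq_a, "B": seq_b})
        tree = tree_from_newick("(A:0.05,B:0.05);")
        fitted, ll = optimize_branch_lengths(tree, aln, {"noncoding": model})
        total = sum(l.edge.length for l in fitted.leaf_node_iter())
        p = k / L
        expected = -0.75 * np.log(1 - 4 / 3 * p)
        assert total == pytest.approx(expected, rel=1e-3)

    def test_identical_sequences_collapse_lengths(self):
        model = SubstitutionModel(kappa=2.0, freqs=(0.25,) * 4)
        aln = make_alignment({"A": "ACGT" * 10, "B": "ACGT" * 10,
                              "C": "ACGT" * 10})
        tree = tree_from_newick("((A:0.1,B:0.2):0.05,C:0.4);")
        fitted, _ = optimize_branch_lengths(tree, aln, {"noncoding": model})
        for node in fitted.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length <= 1e-4

    def test_never_worse_than_start(self, small_dataset):
        from cytosym.alignment import pairwise_distances
        from cytosym.trees import neighbor_joining

        aln = small_dataset["mt_alignment"]
        model = SubstitutionModel(kappa=2.0,
                                  freqs=tuple(aln.base_frequencies()),
                                  alpha=0.5)
        tree = neighbor_joining(pairwise_distances(aln), aln.ids)
        start = partition_loglik(aln, tree, dict.fromkeys(
            set(aln.site_class), model))
        _, best = optimize_branch_lengths(tree, aln, dict.fromkeys(
            set(aln.site_class), model))
        assert best >= start - 1e-9
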