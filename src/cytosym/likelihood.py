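"""Partitioned phylogenetic likelihood under HKY+Gamma on a fixed topology.

Likelihoods are computed by Felsenstein's pruning algorithm, vectorised over
compressed site patterns, with a discrete-gamma mixture over rate categories
and a per-partition rate multiplier applied to branch lengths.  A small
``TreeLikelihood`` engine caches the flattened topology and the per-class
pattern compression so MCMC and optimisation loops pay only for the numerics.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize

from .alignment import PartitionedAlignment
from .substitution import SubstitutionModel


@dataclass
class FlatTree:
    """Topology flattened to arrays: children-before-parents node order."""

    n_tips: int
    n_nodes: int
    postorder: np.ndarray        # node indices, children before parents
    parent: np.ndarray           # parent index per node (-1 at root)
    lengths: np.ndarray          # branch length above each node (0 at root)
    tip_labels: list[str]        # label per tip index (0..n_tips-1)
    nodes: list                  # dendropy nodes in index order


def flatten_tree(tree: dendropy.Tree) -> FlatTree:
    leaves = [n for n in tree.leaf_node_iter()]
    internals = [n for n in tree.preorder_internal_node_iter()]
    index = {}
    for i, n in enumerate(leaves):
        index[n] = i
    for k, n in enumerate(internals):
        index[n] = len(leaves) + k
    n_nodes = len(leaves) + len(internals)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    lengths = np.zeros(n_nodes)
    for n, i in index.items():
        if n.parent_node is not None:
            parent[i] = index[n.parent_node]
            lengths[i] = n.edge.length or 0.0
    post = [index[n] for n in tree.postorder_node_iter()]
    nodes = [None] * n_nodes
    for n, i in index.items():
        nodes[i] = n
    return FlatTree(
        n_tips=len(leaves),
        n_nodes=n_nodes,
        postorder=np.asarray(post),
        parent=parent,
        lengths=lengths,
        tip_labels=[n.taxon.label for n in leaves],
        nodes=nodes,
    )


class TreeLikelihood:
    """Pruning engine for one alignment partitioned into site classes.

    Parameters
    ----------
    aln : gap-free alignment.
    tree : dendropy tree whose tips match the alignment rows; the likelihood
        is invariant to root placement for these reversible models.
    models : mapping site-class -> SubstitutionModel.  Classes present in the
        alignment but absent from the mapping raise KeyError.
    rates : optional mapping site-class -> rate multiplier (default 1.0).
    """

    def __init__(self, aln: PartitionedAlignment, tree: dendropy.Tree,
                 models: dict[str, SubstitutionModel],
                 rates: dict[str, float] | None = None):
        self.flat = flatten_tree(tree)
        if sorted(self.flat.tip_labels) != sorted(aln.ids):
            raise ValueError("tree tips do not match alignment rows")
        row = {s: i for i, s in enumerate(aln.ids)}
        self.tip_rows = [row[lab] for lab in self.flat.tip_labels]
        self.models = dict(models)
        self.rates = dict(rates or {})
        self.classes = []
        self._patterns = {}   # class -> (tip_states (n_tips, npat), counts)
        self._tip_partials = {}  # class -> (n_tips, 4, npat) one-hot
        for cls in dict.fromkeys(aln.site_class):  # preserve first-seen order
            if cls not in models:
                raise KeyError(f"no substitution model for site class {cls!r}")
            cols = aln.matrix[:, aln.site_class == cls][self.tip_rows, :]
            uniq, counts = np.unique(cols, axis=1, return_counts=True)
            self.classes.append(cls)
            self._patterns[cls] = (uniq, counts.astype(float))
            npat = uniq.shape[1]
            onehot = np.zeros((self.flat.n_tips, 4, npat))
            for t in range(self.flat.n_tips):
                onehot[t, uniq[t], np.arange(npat)] = 1.0
            self._tip_partials[cls] = onehot
        # traversal cache: children of each internal node, in postorder
        flat = self.flat
        self._children = {int(i): np.flatnonzero(flat.parent == i)
                          for i in flat.postorder if i >= flat.n_tips}
        self._internal_postorder = [int(i) for i in flat.postorder
                                    if i >= flat.n_tips]

    # -- likelihood -------------------------------------------------------
    def class_loglik(self, cls: str, lengths: np.ndarray | None = None,
                     model: SubstitutionModel | None = None,
                     rate: float | None = None) -> float:
        """Log-likelihood of one site class (overridable pieces for MCMC)."""
        flat = self.flat
        model = model or self.models[cls]
        rate = self.rates.get(cls, 1.0) if rate is None else rate
        lengths = flat.lengths if lengths is None else lengths
        tips, counts = self._patterns[cls]
        tip_partial = self._tip_partials[cls]
        npat = tips.shape[1]
        cat_rates = model.category_rates()
        ncat = len(cat_rates)
        # P[node, cat, a, b] for branch above each node
        bl = np.multiply.outer(np.maximum(lengths, 0.0) * rate, cat_rates)
        P = model.transition_probs(bl)  # (n_nodes, ncat, 4, 4)
        partial = [None] * flat.n_nodes
        logscale = np.zeros(npat)
        n_tips = flat.n_tips
        for k, idx in enumerate(self._internal_postorder):
            prod = None
            for child in self._children[idx]:
                cp = (tip_partial[child][None, :, :] if child < n_tips
                      else partial[child])
                msg = P[child] @ cp  # (ncat,4,4) @ (ncat,4,np) -> (ncat,4,np)
                prod = msg if prod is None else prod * msg
            if k % 8 == 7:  # rescale occasionally to dodge underflow
                mx = prod.max(axis=(0, 1))
                mx = np.where(mx > 0, mx, 1.0)
                prod = prod / mx
                logscale += np.log(mx)
            partial[idx] = prod
        root = self._internal_postorder[-1]
        pi = np.asarray(model.freqs)
        site_lik = np.einsum("a,cap->p", pi, partial[root]) / ncat
        site_lik = np.maximum(site_lik, 1e-300)
        return float(np.dot(counts, np.log(site_lik) + logscale))

    def loglik(self, lengths: np.ndarray | None = None) -> float:
        return sum(self.class_loglik(c, lengths=lengths) for c in self.classes)

    @property
    def n_branches(self) -> int:
        return self.flat.n_nodes - 1  # every non-root node owns one branch


def partition_loglik(aln: PartitionedAlignment, tree: dendropy.Tree,
                     models: dict[str, SubstitutionModel],
                     rates: dict[str, float] | None = None) -> float:
    """Total log-likelihood of ``aln`` on ``tree`` under per-class HKY+Gamma.

    ``rates[cls]`` multiplies every branch length for that class (defaults 1).
    """
    return TreeLikelihood(aln, tree, models, rates).loglik()


def optimize_branch_lengths(tree: dendropy.Tree, aln: PartitionedAlignment,
                            models: dict[str, SubstitutionModel],
                            rates: dict[str, float] | None = None,
                            max_length: float = 20.0,
                            tol: float = 1e-9):
    """ML branch lengths on a fixed topology (L-BFGS-B, lengths >= 0).

    Returns ``(tree_with_new_lengths, max_loglik)``; the input tree is not
    modified.  The optimiser is warned-but-tolerant: if it stops early the
    best point seen is returned, and the result never has lower likelihood
    than the starting lengths.
    """
    engine = TreeLikelihood(aln, tree, models, rates)
    flat = engine.flat
    free = np.flatnonzero(flat.parent >= 0)
    orig = np.maximum(flat.lengths[free], 0.0)
    x0 = np.maximum(orig, 1e-7)

    def objective(x):
        lengths = np.zeros(flat.n_nodes)
        lengths[free] = x
        return -engine.loglik(lengths)

    res = minimize(objective, x0, method="L-BFGS-B",
                   bounds=[(0.0, max_length)] * len(free),
                   options={"ftol": tol, "maxiter": 500})
    # never return a tree worse than the input lengths
    candidates = [res.x, x0, orig]
    values = [-objective(c) for c in candidates]
    best_i = int(np.argmax(values))
    best_x, best = candidates[best_i], values[best_i]
    out = tree.clone(depth=1)
    out_flat = flatten_tree(out)
    lengths = np.zeros(flat.n_nodes)
    lengths[free] = best_x
    # flatten_tree indexes identically for a cloned tree (same traversal order)
    for i in range(out_flat.n_nodes):
        if out_flat.parent[i] >= 0:
            out_flat.nodes[i].edge.length = float(lengths[i])
    return out, float(best)
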