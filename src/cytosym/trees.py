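"""Genealogy construction and measurement.

Trees are held as :class:`dendropy.Tree` objects throughout the package.
Topologies are inferred by neighbor joining (Saitou & Nei) from a distance
matrix; support values come from column-resampling bootstrap; rooting for
display and dating uses the midpoint of the longest tip-to-tip path.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

logger = logging.getLogger(__name__)


def taxon_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Negative branch-length estimates are clamped to zero.  Ties in the
    Q-criterion are broken by the lowest (i, j) label-order index pair, so the
    result is a deterministic function of the matrix and label order.
    Returns an unrooted tree (trifurcating seed node) for >=3 taxa.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix / label mismatch")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    active = list(range(n))
    D = D.copy()

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest index pair among minimisers (indices into `active`)
        flat = np.argwhere(Q <= Q.min() + 1e-12 * max(1.0, abs(Q.min())))
        flat = flat[flat[:, 0] < flat[:, 1]]
        i_loc, j_loc = min(map(tuple, flat))
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new node u to every other active node
        new_row = np.empty(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = max(new_row[k], 0.0)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    # two nodes left: the last-created internal node becomes the seed and the
    # other hangs off it, giving the usual trifurcating unrooted NJ tree
    i, j = active
    if not nodes[j].is_leaf():
        seed_idx, other = j, i
    else:
        seed_idx, other = i, j
    nodes[seed_idx].add_child(nodes[other])
    nodes[other].edge.length = max(D[i, j], 0.0)
    tree.seed_node = nodes[seed_idx]
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# path-length machinery
# ---------------------------------------------------------------------------

def _adjacency(tree: dendropy.Tree):
    """Undirected adjacency {node: [(neighbor, edge_length), ...]}."""
    adj = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(node, [])
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adj[node].append((child, w))
            adj.setdefault(child, []).append((node, w))
    return adj

def patristic_distances(tree: dendropy.Tree, labels: list[str] | None = None
                        ) -> tuple[np.ndarray, list[str]]:
    """Tip-to-tip path-length matrix.

    Returns ``(matrix, labels)`` with rows ordered by ``labels`` (default:
    the tree's leaf order).
    """
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if labels is None:
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    adj = _adjacency(tree)
    n = len(labels)
    M = np.zeros((n, n))
    for a, lab in enumerate(labels):
        # single-source path lengths by DFS
        start = leaves[lab]
        dist = {start: 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            for nbr, w in adj[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        for b, lab2 in enumerate(labels):
            M[a, b] = dist[leaves[lab2]]
    np.fill_diagonal(M, 0.0)
    return M, list(labels)


def _tip_path(adj, src, dst):
    """Node path from src to dst (inclusive)."""
    prev = {src: None}
    stack = [src]
    while stack:
        node = stack.pop()
        if node is dst:
            break
        for nbr, _ in adj[node]:
            if nbr not in prev:
                prev[nbr] = node
                stack.append(nbr)
    path = [dst]
    while path[-1] is not src:
        path.append(prev[path[-1]])
    return path[::-1]


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest tip-to-tip path.

    Ties on the diameter are broken by the lexicographically smallest tip-label
    pair.  A zero-diameter tree is rooted at its seed node with a warning.
    """
    tree = tree.clone(depth=1)
    M, labels = patristic_distances(tree)
    n = len(labels)
    if n < 2 or M.max() <= 0:
        logger.warning("zero-diameter tree: rooting at the existing seed node")
        tree.is_rooted = True
        return tree
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            pair = tuple(sorted((labels[i], labels[j])))
            key = (-M[i, j], pair)
            if best is None or key < best[0]:
                best = (key, i, j)
    _, i, j = best
    half = M[i, j] / 2.0
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    adj = _adjacency(tree)
    path = _tip_path(adj, leaves[labels[i]], leaves[labels[j]])
    # walk from tip i until the cumulative length reaches the midpoint
    acc = 0.0
    for a, b in zip(path[:-1], path[1:]):
        w = next(wt for nbr, wt in adj[a] if nbr is b)
        if acc + w >= half - 1e-12:
            # midpoint lies on edge (a, b); dendropy edges point parent->child
            edge = b.edge if b.parent_node is a else a.edge
            along = half - acc  # distance from node a
            if b.parent_node is a:
                l_child = w - along   # child-side piece (toward b)
            else:
                l_child = along
            tree.reroot_at_edge(edge, length1=w - l_child, length2=l_child,
                                update_bipartitions=False)
            tree.is_rooted = True
            return tree
        acc += w
    raise AssertionError("midpoint not found on path")  # pragma: no cover


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _splits(tree: dendropy.Tree, all_labels: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions, each canonicalised as the side not holding
    the lexicographically smallest label."""
    anchor = min(all_labels)
    out = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = all_labels - side
        if 2 <= len(side) <= len(all_labels) - 2:
            out.add(side)
    return out


def bootstrap_support(aln, n_reps: int, seed: int,
                      distance_model: str = "raw"):
    """Column-resampling NJ bootstrap.

    Builds the full-data NJ tree, then for each replicate resamples alignment
    columns with replacement, rebuilds the tree, and scores each internal edge
    of the full tree by the percentage of replicates containing its
    bipartition.  Support values are attached as internal-node labels.

    Returns ``(tree, support)`` where ``support`` maps each canonical
    bipartition (frozenset of labels) to a percentage.
    """
    from .alignment import pairwise_distances

    if n_reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    full = neighbor_joining(pairwise_distances(aln, distance_model), aln.ids)
    all_labels = frozenset(aln.ids)
    target = _splits(full, all_labels)
    counts = {s: 0 for s in target}
    L = aln.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        from .alignment import PartitionedAlignment
        boot = PartitionedAlignment(   # fresh coords: resampling breaks order
            ids=aln.ids, matrix=aln.matrix[:, cols],
            site_class=aln.site_class[cols], coords=np.arange(1, L + 1))
        btree = neighbor_joining(pairwise_distances(boot, distance_model), aln.ids)
        for s in _splits(btree, all_labels):
            if s in counts:
                counts[s] += 1
    support = {s: 100.0 * c / n_reps for s, c in counts.items()}
    for node in full.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        canon = side if min(all_labels) not in side else all_labels - side
        if canon in support:
            node.label = f"{support[canon]:.0f}"
    return full, support
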