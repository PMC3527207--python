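"""Do the endosymbiont and the mitochondrion share one genealogy?

Under strict maternal co-transmission the two cytoplasmic genomes descend
through a single genealogy.  The test compares a single-topology model (one
tree shared by both partitions, with a free relative-rate multiplier) against
a two-topology model (each partition gets its own tree), fit by maximum
likelihood on neighbor-joining topologies and compared by AIC.  Bayes
factors are computed from log marginal likelihoods (harmonic-mean estimates)
when those are available.  Randomized host-symbiont associations, stratified
by sampling location, continent, or globally, provide the negative control:
on shuffled pairings the two-topology model should win decisively.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alignment import PartitionedAlignment, concatenate, pairwise_distances
from .likelihood import TreeLikelihood
from .substitution import SubstitutionModel
from .trees import neighbor_joining

LN10 = np.log(10.0)


@dataclass
class PartitionFit:
    tree: object
    loglik: float
    n_parameters: int
    kappa: dict
    alpha: dict
    rate: dict


@dataclass
class ModelComparison:
    lnL_single: float
    lnL_two: float
    k_single: int
    k_two: int
    AIC_single: float
    AIC_two: float
    lnML_single: float | None = None
    lnML_two: float | None = None
    log10_BF: float | None = None

    @property
    def delta_aic(self) -> float:
        """AIC_two - AIC_single: positive favours the single topology."""
        return self.AIC_two - self.AIC_single


def _monoclass(aln: PartitionedAlignment, label: str) -> PartitionedAlignment:
    """Collapse site classes: the congruence fit uses one HKY+G per genome."""
    return replace(aln, site_class=np.full(aln.n_columns, label, dtype=object))


KAPPA_BOUNDS = (np.log(0.2), np.log(50.0))
ALPHA_BOUNDS = (np.log(0.05), np.log(20.0))
RATE_BOUNDS = (np.log(1e-4), np.log(1e4))


LEN_BOUNDS = (np.log(1e-9), np.log(10.0))


def _fit_shared(topology, parts: list[PartitionedAlignment],
                free_rates: bool) -> PartitionFit:
    """ML fit of HKY+G partitions on one topology with shared branch lengths.

    Each partition gets its own kappa, alpha and empirical base frequencies;
    with ``free_rates`` the partitions after the first get a free rate
    multiplier on the shared branch lengths.  Branch lengths, rates and
    shape parameters are optimised on the log scale (scale-free steps), with
    initial branch lengths taken from the topology and the rate multipliers
    seeded by the partitions' relative mean pairwise divergence.
    """
    labels = [p.reference_id or f"part{i}" for i, p in enumerate(parts)]
    engines = []
    for lab, p in zip(labels, parts):
        mono = _monoclass(p, lab)
        model = SubstitutionModel(kappa=2.0, freqs=tuple(p.base_frequencies()),
                                  alpha=1.0)
        engines.append((lab, TreeLikelihood(mono, topology, {lab: model}),
                        tuple(p.base_frequencies())))
    flat = engines[0][1].flat
    free = np.flatnonzero(flat.parent >= 0)
    nb = free.size
    n_rates = (len(parts) - 1) if free_rates else 0

    # data-driven scale: mean pairwise p-distance per partition
    scale = []
    for p in parts:
        d = pairwise_distances(p, "raw")
        scale.append(max(d[np.triu_indices(p.n_sequences, 1)].mean(), 1e-6))
    # rescale the topology's lengths (which may be on a concatenated-distance
    # scale) so the tree's mean patristic distance matches the first
    # partition's mean p-distance
    from .trees import patristic_distances
    M, _ = patristic_distances(topology)
    n = M.shape[0]
    tree_scale = M[np.triu_indices(n, 1)].mean()
    init_lengths = np.maximum(flat.lengths[free], 1e-7)
    if tree_scale > 0:
        init_lengths = np.maximum(init_lengths * scale[0] / tree_scale, 1e-7)

    x0 = np.concatenate([
        np.log(init_lengths),
        np.tile([np.log(2.0), 0.0], len(parts)),
        [np.log(max(scale[i] / scale[0], 1e-4)) for i in range(1, len(parts))
         ] if n_rates else [],
    ])
    bounds = ([LEN_BOUNDS] * nb
              + [KAPPA_BOUNDS, ALPHA_BOUNDS] * len(parts)
              + [RATE_BOUNDS] * n_rates)

    def unpack(x):
        lengths = np.zeros(flat.n_nodes)
        lengths[free] = np.exp(x[:nb])
        shapes = x[nb:nb + 2 * len(parts)].reshape(len(parts), 2)
        rates = np.ones(len(parts))
        if n_rates:
            rates[1:] = np.exp(x[nb + 2 * len(parts):])
        return lengths, shapes, rates

    def objective(x):
        lengths, shapes, rates = unpack(x)
        total = 0.0
        for i, (lab, eng, freqs) in enumerate(engines):
            model = SubstitutionModel(kappa=float(np.exp(shapes[i, 0])),
                                      freqs=freqs,
                                      alpha=float(np.exp(shapes[i, 1])))
            total += eng.class_loglik(lab, lengths=lengths, model=model,
                                      rate=float(rates[i]))
        return -total

    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-10})
    x = res.x if res.fun <= objective(x0) else x0
    lengths, shapes, rates = unpack(x)
    out = topology.clone(depth=1)
    from .likelihood import flatten_tree
    oflat = flatten_tree(out)
    for i in range(oflat.n_nodes):
        if oflat.parent[i] >= 0:
            oflat.nodes[i].edge.length = float(lengths[i])
    # parameters: branches + per-partition (kappa, alpha, 3 free freqs) +
    # free rate multipliers
    k = nb + len(parts) * 5 + n_rates
    return PartitionFit(
        tree=out, loglik=float(-objective(x)), n_parameters=k,
        kappa={lab: float(np.exp(shapes[i, 0]))
               for i, (lab, _, _) in enumerate(engines)},
        alpha={lab: float(np.exp(shapes[i, 1]))
               for i, (lab, _, _) in enumerate(engines)},
        rate={lab: float(rates[i]) for i, (lab, _, _) in enumerate(engines)},
    )


def fit_topology_models(wol_aln: PartitionedAlignment,
                        mt_aln: PartitionedAlignment):
    """Fit the single-topology and two-topology models.

    Both alignments must cover the same strain set (the infected strains).
    Topologies are neighbor-joining trees on p-distances: each partition's own
    tree for the two-topology model, the concatenated data's tree for the
    single-topology model.  Returns ``(single_fit, two_fit)`` where each is a
    :class:`PartitionFit` carrying total lnL and the AIC parameter count.
    """
    if sorted(wol_aln.ids) != sorted(mt_aln.ids):
        raise ValueError("alignments cover different strain sets")
    wol = replace(wol_aln, reference_id=wol_aln.reference_id or "wolbachia")
    mt = replace(mt_aln, reference_id=mt_aln.reference_id or "mtdna")

    # two-topology: independent NJ tree + fit per partition
    two_fits = []
    for part in (mt, wol):
        topo = neighbor_joining(pairwise_distances(part, "raw"), part.ids)
        two_fits.append(_fit_shared(topo, [part], free_rates=False))
    two = PartitionFit(
        tree=[f.tree for f in two_fits],
        loglik=sum(f.loglik for f in two_fits),
        n_parameters=sum(f.n_parameters for f in two_fits),
        kappa={**two_fits[0].kappa, **two_fits[1].kappa},
        alpha={**two_fits[0].alpha, **two_fits[1].alpha},
        rate={**two_fits[0].rate, **two_fits[1].rate},
    )

    concat = concatenate([mt, wol])
    topo = neighbor_joining(pairwise_distances(concat, "raw"), concat.ids)
    single = _fit_shared(topo, [mt, wol], free_rates=True)
    return single, two


def model_comparison(single: PartitionFit | None = None,
                     two: PartitionFit | None = None,
                     lnml_single: float | None = None,
                     lnml_two: float | None = None,
                     lnl_single: float | None = None,
                     lnl_two: float | None = None,
                     k_single: int | None = None,
                     k_two: int | None = None) -> ModelComparison:
    """Assemble the comparison record: AIC = 2k - 2 lnL per model and
    log10 BF = (lnML_single - lnML_two) / ln 10.

    Accepts either fitted models or raw numbers (as printed analyses supply).
    """
    if single is not None:
        lnl_single, k_single = single.loglik, single.n_parameters
    if two is not None:
        lnl_two, k_two = two.loglik, two.n_parameters
    if lnl_single is None or lnl_two is None:
        raise ValueError("need log-likelihoods (fits or raw values)")
    aic_s = 2.0 * k_single - 2.0 * lnl_single
    aic_t = 2.0 * k_two - 2.0 * lnl_two
    bf = None
    if lnml_single is not None and lnml_two is not None:
        bf = (lnml_single - lnml_two) / LN10
    return ModelComparison(
        lnL_single=lnl_single, lnL_two=lnl_two,
        k_single=k_single, k_two=k_two,
        AIC_single=aic_s, AIC_two=aic_t,
        lnML_single=lnml_single, lnML_two=lnml_two, log10_BF=bf)


def harmonic_mean_lnml(loglik_samples) -> float:
    """Harmonic-mean estimator of the log marginal likelihood.

    lnML = -[logsumexp(-lnL_i) - ln m]; numerically stabilised, scale-free in
    the number of samples (duplicating the sample leaves it unchanged).
    """
    lnl = np.asarray(loglik_samples, dtype=float)
    if lnl.size == 0:
        raise ValueError("need at least one log-likelihood sample")
    if not np.all(np.isfinite(lnl)):
        raise ValueError("log-likelihood samples must be finite")
    return float(-(logsumexp(-lnl) - np.log(lnl.size)))


def randomize_associations(metadata: pd.DataFrame, level: str,
                           seed: int) -> dict[str, str]:
    """Randomly re-pair symbionts with hosts within geographic strata.

    ``metadata`` needs columns strain_id, latitude, longitude, region.
    ``level``: 'location' permutes within identical (latitude, longitude);
    'continent' within region; 'global' across everything.  Returns a mapping
    host strain -> strain whose symbiont sequence it receives; the multiset
    of symbiont sequences is preserved and strata are never mixed.
    """
    rng = np.random.default_rng(seed)
    if level == "location":
        strata = metadata.groupby(["latitude", "longitude"], sort=True)
    elif level == "continent":
        strata = metadata.groupby("region", sort=True)
    elif level == "global":
        strata = [(None, metadata)]
    else:
        raise ValueError(f"unknown randomization level {level!r}")
    mapping = {}
    for _, grp in strata:
        ids = list(grp["strain_id"])
        perm = rng.permutation(len(ids))
        for host, donor in zip(ids, (ids[p] for p in perm)):
            mapping[host] = donor
    return mapping


def apply_association(wol_aln: PartitionedAlignment,
                      mapping: dict[str, str]) -> PartitionedAlignment:
    """Reassign symbiont rows to hosts according to ``mapping``."""
    index = {s: i for i, s in enumerate(wol_aln.ids)}
    rows = [index[mapping.get(s, s)] for s in wol_aln.ids]
    return replace(wol_aln, matrix=wol_aln.matrix[rows])
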