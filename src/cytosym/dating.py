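"""Fixed-topology Bayesian dating of the shared cytoplasmic genealogy.

A Metropolis–Hastings sampler explores internal-node ages (in host
generations), five site-class substitution rates, per-class HKY shape
parameters and the coalescent effective size, on a fixed rooted topology.
The calibration is a lognormal prior on the mitochondrial third-position
rate: mean -16.59613 and standard deviation 1/3 on the natural-log scale,
implying a central rate of exp(-16.59613) ~ 6.2e-8 substitutions per site
per host generation.  Node ages are converted to years by assuming ten host
generations per year.

Ancestral geographic locations are reconstructed separately, by maximum
likelihood on the fixed dated tree, under a non-reversible 3-state
continuous-time Markov chain over {Africa, Europe, NorthAmerica}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import lognorm

from .alignment import PartitionedAlignment, concatenate
from .likelihood import TreeLikelihood, flatten_tree
from .substitution import SubstitutionModel
from .synthetic import RATE_CLASSES, rate_class_of

logger = logging.getLogger(__name__)

GENERATIONS_PER_YEAR = 10.0

#: published calibration: mean of ln(rate) at mitochondrial third positions
MT3_PRIOR_MU = -16.59613
MT3_PRIOR_SIGMA = 1.0 / 3.0


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class RatePrior:
    """Lognormal prior on a substitution rate: ln(rate) ~ N(mu_log, sigma_log)."""

    mu_log: float = MT3_PRIOR_MU
    sigma_log: float = MT3_PRIOR_SIGMA

    def __post_init__(self):
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")

    @property
    def central_rate(self) -> float:
        """exp(mu_log): the distribution's median (the quoted central rate)."""
        return float(np.exp(self.mu_log))

    def logpdf_log_rate(self, log_rate: float) -> float:
        """Log-density in the ln(rate) parameterisation (a plain normal)."""
        if self.sigma_log == 0:
            return 0.0 if log_rate == self.mu_log else -np.inf
        z = (log_rate - self.mu_log) / self.sigma_log
        return -0.5 * z * z - np.log(self.sigma_log * np.sqrt(2 * np.pi))

    def pdf(self, rate):
        if self.sigma_log == 0:
            raise ValueError("point-mass prior has no density")
        return lognorm.pdf(rate, s=self.sigma_log, scale=np.exp(self.mu_log))

    def quantile(self, q):
        if self.sigma_log == 0:
            return np.full_like(np.asarray(q, dtype=float), self.central_rate)
        return lognorm.ppf(q, s=self.sigma_log, scale=np.exp(self.mu_log))


def lognormal_rate_prior(mu_log: float = MT3_PRIOR_MU,
                         sigma_log: float = MT3_PRIOR_SIGMA) -> RatePrior:
    """Construct the calibration prior; see :class:`RatePrior`."""
    return RatePrior(mu_log=mu_log, sigma_log=sigma_log)


def coalescent_intervals_log_density(internal_ages: np.ndarray,
                                     effective_size: float) -> float:
    """Constant-size Kingman coalescent log-density of ordered node ages.

    ``internal_ages`` are the n-1 coalescence times (generations) of a sample
    of n tips at age 0; ``effective_size`` is the haploid effective size in
    generations.  Each coalescence contributes -ln(N) - C(k,2) * dt / N.
    """
    ages = np.sort(np.asarray(internal_ages, dtype=float))
    if np.any(ages < 0):
        raise ValueError("node ages must be non-negative")
    N = effective_size
    if N <= 0:
        raise ValueError("effective size must be positive")
    n = ages.size + 1
    prev = 0.0
    logp = 0.0
    for i, t in enumerate(ages):
        k = n - i
        logp += -np.log(N) - (k * (k - 1) / 2.0) * (t - prev) / N
        prev = t
    return float(logp)


def coalescent_tree_log_prior(tree: dendropy.Tree, effective_size: float) -> float:
    """Coalescent prior of a dated tree (node ``age`` attributes, tips at 0)."""
    ages = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            if child.age > node.age + 1e-9:
                raise ValueError("inconsistent ages: child older than parent")
        if not node.is_leaf():
            ages.append(node.age)
    return coalescent_intervals_log_density(np.asarray(ages), effective_size)


# ---------------------------------------------------------------------------
# alignment preparation
# ---------------------------------------------------------------------------

def prepare_dating_alignment(mt_aln: PartitionedAlignment,
                             wol_aln: PartitionedAlignment
                             ) -> PartitionedAlignment:
    """Concatenate mtDNA + *Wolbachia* rows of the shared (infected) strains
    and relabel columns with the five dating rate classes."""
    shared = [s for s in wol_aln.ids if s in set(mt_aln.ids)]
    if not shared:
        raise ValueError("no shared strains between the two alignments")
    mt = mt_aln.subset_rows(shared)
    wol = wol_aln.subset_rows(shared)
    cat = concatenate([mt, wol], class_prefixes=["mt:", "wol:"])
    mapped = np.array([
        rate_class_of("mtdna" if c.startswith("mt:") else "wolbachia",
                      c.split(":", 1)[1])
        for c in cat.site_class], dtype=object)
    cat.site_class = mapped
    return cat


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class ChainSettings:
    n_iterations: int = 4000        # sweeps; one sweep updates every parameter
    burn_in: float = 0.10
    thin: int = 2
    age_window: float = 0.40        # root-age log-scale step
    rate_step: float = 0.70         # sd of log random walks
    shape_step: float = 0.60
    size_step: float = 1.00
    scale_step: float = 0.25        # sd of the joint age/rate scale move
    rate_bounds: tuple = (1e-13, 1e-5)   # log-uniform prior for uncalibrated rates
    size_bounds: tuple = (10.0, 1e9)
    likelihood_off: bool = False    # prior-only validation runs


@dataclass
class PosteriorSummary:
    rate_median: dict
    rate_ci: dict
    age_median: dict            # node key -> generations
    age_ci: dict
    age_median_years: dict
    age_ci_years: dict
    effective_size_median: float
    acceptance: dict
    seed: int
    generations_per_year: float = GENERATIONS_PER_YEAR


def _node_keys(flat) -> dict:
    """Stable human-readable node keys: a tip is its label; an internal node
    is ``mrca(a,b)`` where a and b are the smallest tip labels of two of its
    child subtrees — that pair identifies the node uniquely as their MRCA."""
    children_of = {i: np.flatnonzero(flat.parent == i)
                   for i in range(flat.n_nodes)}
    mins = {}
    keys = {}
    for idx in flat.postorder:
        if idx < flat.n_tips:
            mins[idx] = flat.tip_labels[idx]
            keys[idx] = flat.tip_labels[idx]
        else:
            reps = sorted(mins[c] for c in children_of[idx])
            mins[idx] = reps[0]
            keys[idx] = f"mrca({reps[0]},{reps[1]})"
    return keys


def _initial_ages(flat, lengths, scale_to: float) -> np.ndarray:
    """Consistent starting ages: node age = max path length to a descendant
    tip, rescaled so the root sits at ``scale_to`` generations."""
    ages = np.zeros(flat.n_nodes)
    for idx in flat.postorder:
        children = np.flatnonzero(flat.parent == idx)
        if children.size:
            ages[idx] = max(ages[c] + max(lengths[c], 1e-9) for c in children)
    root = flat.postorder[-1]
    if ages[root] <= 0:
        ages[:] = 0.0
        for idx in flat.postorder:
            children = np.flatnonzero(flat.parent == idx)
            if children.size:
                ages[idx] = ages[children].max() + 1.0
    ages *= scale_to / ages[flat.postorder[-1]]
    return ages


def run_dating_mcmc(aln: PartitionedAlignment, tree: dendropy.Tree,
                    rate_prior: RatePrior | None = None,
                    settings: ChainSettings | None = None,
                    seed: int = 0,
                    calibrated_class: str = "mt_codon3") -> pd.DataFrame:
    """MCMC over node ages, per-class rates, kappa, alpha and effective size.

    The topology is fixed and must be rooted; tip ages are zero.  Branch
    lengths for class c are rate_c x (parent age - child age).  Site classes
    with no columns are dropped with a warning.  Returns a tidy DataFrame of
    retained samples (one row per thinned iteration), including every
    internal-node age (columns ``age_<k>`` keyed by the node's smallest
    descendant tip set representative) plus ``rate_<class>``, ``kappa_<class>``,
    ``alpha_<class>``, ``effective_size``, ``loglik`` and ``logprior``.
    """
    if not tree.is_rooted:
        raise ValueError("dating requires a rooted topology")
    rate_prior = rate_prior or lognormal_rate_prior()
    settings = settings or ChainSettings()
    rng = np.random.default_rng(seed)

    classes = [c for c in RATE_CLASSES if (aln.site_class == c).any()]
    dropped = [c for c in RATE_CLASSES if c not in classes]
    if dropped:
        logger.warning("dropping empty site classes: %s", dropped)
    if not classes:
        raise ValueError("alignment contains none of the dating site classes")

    freqs = tuple(aln.base_frequencies())
    base_model = {c: SubstitutionModel(kappa=2.0, freqs=freqs, alpha=0.5)
                  for c in classes}
    engine = TreeLikelihood(aln, tree, {c: base_model[c] for c in classes})
    flat = engine.flat
    root = flat.postorder[-1]
    internal = [i for i in range(flat.n_nodes) if i >= flat.n_tips]
    children_of = {i: np.flatnonzero(flat.parent == i) for i in internal}

    node_key = {i: f"age_{k}" for i, k in _node_keys(flat).items()
                if i >= flat.n_tips}

    # state
    log_rates = {c: np.log(rate_prior.central_rate) if c == calibrated_class
                 else np.log(1e-9) for c in classes}
    log_kappa = {c: np.log(2.0) for c in classes}
    log_alpha = {c: 0.0 for c in classes}
    log_N = np.log(50_000.0)
    ages = _initial_ages(flat, flat.lengths,
                         scale_to=2.0 * np.exp(log_N))

    lo_r, hi_r = np.log(settings.rate_bounds[0]), np.log(settings.rate_bounds[1])
    lo_N, hi_N = np.log(settings.size_bounds[0]), np.log(settings.size_bounds[1])

    def gen_lengths(a):
        out = np.zeros(flat.n_nodes)
        mask = flat.parent >= 0
        out[mask] = a[flat.parent[mask]] - a[mask]
        return out

    model_cache: dict = {}

    def class_model(c):
        # rebuilt only when kappa/alpha move; keeps the eigendecomposition
        if c not in model_cache:
            model_cache[c] = SubstitutionModel(
                kappa=float(np.exp(log_kappa[c])), freqs=freqs,
                alpha=float(np.exp(log_alpha[c])))
        return model_cache[c]

    def class_ll(c, a):
        if settings.likelihood_off:
            return 0.0
        return engine.class_loglik(c, lengths=gen_lengths(a) * np.exp(log_rates[c]),
                                   model=class_model(c), rate=1.0)

    def log_prior():
        lp = 0.0
        for c in classes:
            if c == calibrated_class:
                lp += rate_prior.logpdf_log_rate(log_rates[c])
            else:
                if not (lo_r <= log_rates[c] <= hi_r):
                    return -np.inf
            # kappa ~ LogNormal(ln 2, 1.25); alpha ~ LogNormal(0, 1); densities
            # expressed in log-parameter space (plain normals)
            lp += -0.5 * ((log_kappa[c] - np.log(2.0)) / 1.25) ** 2
            lp += -0.5 * (log_alpha[c] / 1.0) ** 2
        if not (lo_N <= log_N <= hi_N):
            return -np.inf
        lp += coalescent_intervals_log_density(ages[flat.n_tips:],
                                               np.exp(log_N))
        return lp

    cur_ll = {c: class_ll(c, ages) for c in classes}
    cur_prior = log_prior()
    accept = {"age": 0, "root": 0, "rate": 0, "kappa": 0, "alpha": 0, "N": 0,
              "scale": 0}
    tries = {k: 0 for k in accept}
    rows = []
    n_burn = int(settings.burn_in * settings.n_iterations)

    for it in range(settings.n_iterations):
        # --- node ages ---------------------------------------------------
        for idx in internal:
            tries["age" if idx != root else "root"] += 1
            lb = max(ages[c] for c in children_of[idx])
            if idx == root:
                u = rng.uniform(-settings.age_window, settings.age_window)
                new_age = ages[idx] * np.exp(u)
                log_hastings = u  # d(new)/d(old) Jacobian of the scale move
                if new_age <= lb:
                    continue
            else:
                ub = ages[flat.parent[idx]]
                if ub - lb <= 0:
                    continue
                new_age = rng.uniform(lb, ub)
                log_hastings = 0.0
            old = ages[idx]
            ages[idx] = new_age
            new_prior = log_prior()
            if not np.isfinite(new_prior):
                ages[idx] = old
                continue
            new_ll = {c: class_ll(c, ages) for c in classes}
            delta = (sum(new_ll.values()) - sum(cur_ll.values())
                     + new_prior - cur_prior + log_hastings)
            if np.log(rng.random()) < delta:
                cur_ll, cur_prior = new_ll, new_prior
                accept["age" if idx != root else "root"] += 1
            else:
                ages[idx] = old

        # --- scalar parameters -------------------------------------------
        for c in classes:
            for name, store, step in (
                    ("rate", log_rates, settings.rate_step),
                    ("kappa", log_kappa, settings.shape_step),
                    ("alpha", log_alpha, settings.shape_step)):
                tries[name] += 1
                old = store[c]
                store[c] = old + rng.normal(0.0, step)
                if name in ("kappa", "alpha"):
                    model_cache.pop(c, None)
                new_prior = log_prior()
                if not np.isfinite(new_prior):
                    store[c] = old
                    if name in ("kappa", "alpha"):
                        model_cache.pop(c, None)
                    continue
                new_c_ll = class_ll(c, ages)
                delta = new_c_ll - cur_ll[c] + new_prior - cur_prior
                if np.log(rng.random()) < delta:
                    cur_ll[c] = new_c_ll
                    cur_prior = new_prior
                    accept[name] += 1
                else:
                    store[c] = old
                    if name in ("kappa", "alpha"):
                        model_cache.pop(c, None)

        tries["N"] += 1
        old = log_N
        log_N = old + rng.normal(0.0, settings.size_step)
        new_prior = log_prior()
        if np.isfinite(new_prior) and np.log(rng.random()) < new_prior - cur_prior:
            cur_prior = new_prior
            accept["N"] += 1
        else:
            log_N = old

        # joint scale: ages*f, every rate/f, N*f — branch substitution
        # amounts (and hence the likelihood) are exactly invariant, so this
        # move decorrelates the slow age/rate scale mode at zero cost
        tries["scale"] += 1
        u = rng.normal(0.0, settings.scale_step)
        old_ages = ages.copy()
        old_rates = dict(log_rates)
        old_N = log_N
        ages *= np.exp(u)          # tip entries are 0 and stay 0
        for c in classes:
            log_rates[c] -= u
        log_N += u
        new_prior = log_prior()
        log_hastings = len(internal) * u   # ages are scaled in natural space
        if (np.isfinite(new_prior)
                and np.log(rng.random()) < new_prior - cur_prior + log_hastings):
            cur_prior = new_prior
            accept["scale"] += 1
        else:
            ages[:] = old_ages
            log_rates.update(old_rates)
            log_N = old_N

        if it >= n_burn and (it - n_burn) % settings.thin == 0:
            row = {"iteration": it,
                   "loglik": sum(cur_ll.values()),
                   "logprior": cur_prior,
                   "effective_size": float(np.exp(log_N))}
            for c in classes:
                row[f"rate_{c}"] = float(np.exp(log_rates[c]))
                row[f"kappa_{c}"] = float(np.exp(log_kappa[c]))
                row[f"alpha_{c}"] = float(np.exp(log_alpha[c]))
            for i in internal:
                row[node_key[i]] = float(ages[i])
            rows.append(row)

    samples = pd.DataFrame(rows)
    samples.attrs["acceptance"] = {
        k: (accept[k] / tries[k] if tries[k] else np.nan) for k in accept}
    samples.attrs["seed"] = seed
    samples.attrs["classes"] = classes
    return samples


def summarize_posterior(samples: pd.DataFrame,
                        generations_per_year: float = GENERATIONS_PER_YEAR
                        ) -> PosteriorSummary:
    """Medians and central 95% credible intervals of rates and node ages.

    Ages are reported both in host generations and in years
    (years = generations / generations_per_year).
    """
    if len(samples) == 0:
        raise ValueError("no post-burn-in samples")

    def ci(col):
        return (float(samples[col].quantile(0.025)),
                float(samples[col].quantile(0.975)))

    rate_cols = [c for c in samples.columns if c.startswith("rate_")]
    age_cols = [c for c in samples.columns if c.startswith("age_")]
    rate_median = {c[5:]: float(samples[c].median()) for c in rate_cols}
    rate_ci = {c[5:]: ci(c) for c in rate_cols}
    age_median = {c[4:]: float(samples[c].median()) for c in age_cols}
    age_ci = {c[4:]: ci(c) for c in age_cols}
    g = generations_per_year
    return PosteriorSummary(
        rate_median=rate_median, rate_ci=rate_ci,
        age_median=age_median, age_ci=age_ci,
        age_median_years={k: v / g for k, v in age_median.items()},
        age_ci_years={k: (lo / g, hi / g) for k, (lo, hi) in age_ci.items()},
        effective_size_median=float(samples["effective_size"].median()),
        acceptance=samples.attrs.get("acceptance", {}),
        seed=samples.attrs.get("seed", -1),
    )


# ---------------------------------------------------------------------------
# phylogeography
# ---------------------------------------------------------------------------

LOCATIONS = ("Africa", "Europe", "NorthAmerica")


def _geo_loglik(Q: np.ndarray, flat, tip_states: np.ndarray,
                root_freqs: np.ndarray):
    """3-state pruning log-likelihood and per-node partials."""
    n_nodes = flat.n_nodes
    partial = np.zeros((n_nodes, 3))
    logscale = 0.0
    P = {}
    for i in range(n_nodes):
        if flat.parent[i] >= 0:
            P[i] = expm(Q * max(flat.lengths[i], 0.0))
    for idx in flat.postorder:
        if idx < flat.n_tips:
            partial[idx, tip_states[idx]] = 1.0
        else:
            prod = np.ones(3)
            for child in np.flatnonzero(flat.parent == idx):
                prod *= P[child] @ partial[child]
            m = prod.max()
            if m <= 0:
                return -np.inf, partial, P, logscale
            partial[idx] = prod / m
            logscale += np.log(m)
    root = flat.postorder[-1]
    lik = float(root_freqs @ partial[root])
    return np.log(lik) + logscale, partial, P, logscale


def phylogeo_ancestral_states(tree: dendropy.Tree, tip_locations: dict,
                              locations: tuple = LOCATIONS):
    """ML non-reversible CTMC over locations on a fixed dated tree.

    Fits the six off-diagonal rates of a 3x3 generator Q by maximum
    likelihood (the root state is drawn from the chain's stationary
    distribution), then computes marginal ancestral-location probabilities
    per node by the up-down algorithm.  Returns ``(Q, node_probs)`` where ``node_probs`` maps
    each internal node key (smallest descendant tip label) to a probability
    vector over ``locations``; tips are included with point masses.
    """
    flat = flatten_tree(tree)
    try:
        tip_states = np.array([locations.index(tip_locations[lab])
                               for lab in flat.tip_labels])
    except KeyError as exc:
        raise ValueError(f"tip without a location label: {exc}") from exc
    depth = max(flat.lengths.sum(), 1e-9)

    def build_Q(log_r):
        r = np.exp(log_r)
        Q = np.zeros((3, 3))
        Q[np.triu_indices(3, 1)] = r[:3]
        Q[np.tril_indices(3, -1)] = r[3:]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary(Q):
        """Left null vector of Q (the chain's equilibrium distribution)."""
        w, V = np.linalg.eig(Q.T)
        v = np.real(V[:, np.argmin(np.abs(w))])
        v = np.abs(v)
        s = v.sum()
        return v / s if s > 0 else np.full(3, 1.0 / 3.0)

    def nll(log_r):
        Q = build_Q(log_r)
        ll, *_ = _geo_loglik(Q, flat, tip_states, stationary(Q))
        return -ll

    # bounded log-rates keep the generator numerically sane on degenerate
    # inputs (e.g. all tips in one location, where the ML rate is 0)
    x0 = np.full(6, np.clip(np.log(flat.n_tips / depth), -20.0, 8.0))
    bounds = [(-25.0, 8.0)] * 6
    res = minimize(nll, x0, method="Nelder-Mead", bounds=bounds,
                   options={"maxiter": 2000, "xatol": 1e-4, "fatol": 1e-7})
    Q = build_Q(res.x)

    # up-down: outside[v] = likelihood of everything except v's subtree
    root_freqs = stationary(Q)
    ll, partial, P, _ = _geo_loglik(Q, flat, tip_states, root_freqs)
    root = flat.postorder[-1]
    outside = np.zeros((flat.n_nodes, 3))
    outside[root] = root_freqs
    for idx in flat.postorder[::-1]:
        for child in np.flatnonzero(flat.parent == idx):
            sibs = np.ones(3)
            for other in np.flatnonzero(flat.parent == idx):
                if other != child:
                    sibs *= P[other] @ partial[other]
            outside[child] = (outside[idx] * sibs) @ P[child]

    keys = _node_keys(flat)
    node_probs = {}
    for idx in flat.postorder:
        joint = outside[idx] * partial[idx]
        total = joint.sum()
        node_probs[keys[idx]] = joint / total if total > 0 else joint
    return Q, node_probs
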