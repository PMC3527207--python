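"""Population-genetic summary statistics and hypothesis tests.

Implements per-site nucleotide diversity (pi), Watterson's theta (based on
the total number of mutations by default, so a triallelic site counts
twice), Tajima's D with significance from neutral coalescent simulations
conditioned on the observed number of segregating sites, a patristic-distance
variant of Hudson's Kst with a within-population permutation test, exact
binomial proportion intervals, and call-set concordance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta

from .alignment import PartitionedAlignment

logger = logging.getLogger(__name__)


@dataclass
class DiversityEstimate:
    n: int
    L: int
    S: int
    eta: int
    pi: float
    theta_w: float
    tajimas_d: float | None
    p_value: float | None = None


@dataclass
class KstResult:
    per_population: dict
    weights: dict
    weighted_kst: float
    p_value: float
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# site-frequency machinery
# ---------------------------------------------------------------------------

def _allele_counts(aln: PartitionedAlignment):
    """Per-column allele counts (4, L)."""
    X = aln.matrix
    return np.stack([(X == b).sum(axis=0) for b in range(4)])


def segregating_sites(aln: PartitionedAlignment) -> tuple[int, int]:
    """(S, eta): number of variable sites and total mutations.

    eta counts a site with k distinct alleles as k-1 mutations (the minimum
    number of mutations explaining it), so eta >= S with equality when every
    variable site is biallelic.
    """
    counts = _allele_counts(aln)
    n_alleles = (counts > 0).sum(axis=0)
    S = int((n_alleles > 1).sum())
    eta = int((n_alleles - 1).sum())
    return S, eta


def harmonic_number(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float((1.0 / i ** power).sum())


def nucleotide_diversity_pi(aln: PartitionedAlignment) -> float:
    """Mean pairwise difference per site over all n(n-1)/2 sequence pairs."""
    n, L = aln.matrix.shape
    if n < 2:
        raise ValueError("pi needs at least two sequences")
    if L < 1:
        raise ValueError("alignment has no columns")
    counts = _allele_counts(aln)
    # sum over pairs of mismatches = C(n,2) - sum_b C(count_b, 2) per column
    same = (counts * (counts - 1) // 2).sum(axis=0)
    pairs = n * (n - 1) / 2
    return float(((pairs - same).sum()) / (pairs * L))


def watterson_theta(aln: PartitionedAlignment, count: str = "eta") -> float:
    """Watterson's estimator per site: count / (a1 * L).

    ``count='eta'`` (default) uses the total number of mutations;
    ``count='S'`` uses the number of variable sites.
    """
    n, L = aln.matrix.shape
    if n < 2:
        raise ValueError("theta needs at least two sequences")
    S, eta = segregating_sites(aln)
    value = {"S": S, "eta": eta}[count]
    return value / (harmonic_number(n) * L)


def _tajima_constants(n: int):
    a1 = harmonic_number(n)
    a2 = harmonic_number(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajimas_d_from_parts(n: int, S: int, pi_total: float) -> float:
    """Tajima's D from sample size, segregating sites and total (not per-site)
    mean pairwise difference."""
    if S < 1:
        raise ValueError("Tajima's D is undefined when S = 0")
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_total - S / a1) / np.sqrt(var)


def tajimas_d(aln: PartitionedAlignment) -> float:
    """Tajima's (1989) D for the alignment; raises when no site varies."""
    n, L = aln.matrix.shape
    S, _ = segregating_sites(aln)
    if S < 1:
        raise ValueError("Tajima's D is undefined when S = 0")
    pi_total = nucleotide_diversity_pi(aln) * L
    return float(tajimas_d_from_parts(n, S, pi_total))


def diversity_summary(aln: PartitionedAlignment) -> DiversityEstimate:
    n, L = aln.matrix.shape
    S, eta = segregating_sites(aln)
    return DiversityEstimate(
        n=n, L=L, S=S, eta=eta,
        pi=nucleotide_diversity_pi(aln),
        theta_w=watterson_theta(aln),
        tajimas_d=(tajimas_d(aln) if S >= 1 else None),
    )


# ---------------------------------------------------------------------------
# conditional-on-S coalescent null for Tajima's D
# ---------------------------------------------------------------------------

def _simulate_sfs_conditional(n: int, S: int, rng) -> np.ndarray:
    """One neutral no-recombination genealogy; place exactly S mutations on
    branches with probability proportional to branch length.  Returns the
    unfolded SFS (counts of derived-allele frequencies 1..n-1)."""
    # lineage bookkeeping: each active lineage knows its subtree size and its
    # accumulated branch length since it arose
    sizes = [1] * n
    lens = [0.0] * n
    segments = []   # (branch_length, subtree_size) of completed branches
    k = n
    while k > 1:
        dt = rng.exponential(2.0 / (k * (k - 1)))
        for m in range(k):
            lens[m] += dt
        i, j = sorted(rng.choice(k, size=2, replace=False))
        segments.append((lens[i], sizes[i]))
        segments.append((lens[j], sizes[j]))
        merged = sizes[i] + sizes[j]
        for idx in (j, i):
            del sizes[idx], lens[idx]
        sizes.append(merged)
        lens.append(0.0)
        k -= 1
    lengths = np.array([s[0] for s in segments])
    subtree = np.array([s[1] for s in segments])
    probs = lengths / lengths.sum()
    muts = rng.multinomial(S, probs)
    sfs = np.zeros(n - 1, dtype=np.int64)
    for cnt, size in zip(muts, subtree):
        if cnt:
            sfs[size - 1] += cnt
    return sfs


def _d_from_sfs(n: int, sfs: np.ndarray) -> float:
    k = np.arange(1, n)
    pi_total = (sfs * k * (n - k)).sum() / (n * (n - 1) / 2)
    S = int(sfs.sum())
    return tajimas_d_from_parts(n, S, pi_total)


def conditional_coalescent_null(n: int, S: int, n_reps: int, seed: int,
                                observed_d: float | None = None,
                                alternative: str = "less"):
    """Null distribution of Tajima's D conditioned on S segregating sites.

    Each replicate draws a Kingman coalescent genealogy without
    recombination, drops exactly ``S`` mutations on branches with probability
    proportional to branch length (every mutation treated as a distinct
    site), and evaluates D.  Returns ``(d_values, p_value)``; the p-value is
    the fraction of simulated D at or below the observed value
    (``alternative='less'``, matching tests for an excess of rare variants)
    or a two-sided tail doubling with ``alternative='two-sided'``.
    """
    if n < 2 or S < 1 or n_reps < 1:
        raise ValueError("need n >= 2, S >= 1, n_reps >= 1")
    rng = np.random.default_rng(seed)
    d = np.array([_d_from_sfs(n, _simulate_sfs_conditional(n, S, rng))
                  for _ in range(n_reps)])
    p = None
    if observed_d is not None:
        lower = (d <= observed_d).mean()
        if alternative == "less":
            p = max(lower, 1.0 / n_reps)
        elif alternative == "two-sided":
            p = max(min(2 * min(lower, (d >= observed_d).mean()), 1.0),
                    1.0 / n_reps)
        else:
            raise ValueError("alternative must be 'less' or 'two-sided'")
    return d, p


# ---------------------------------------------------------------------------
# Kst on patristic distances
# ---------------------------------------------------------------------------

def _mean_within(D: np.ndarray, idx: np.ndarray) -> float:
    if idx.size < 2:
        return np.nan
    sub = D[np.ix_(idx, idx)]
    m = idx.size
    return sub[np.triu_indices(m, k=1)].mean()


def kst_statistic(D: np.ndarray, labels: np.ndarray) -> float:
    """Kst = 1 - Ks/Kt for a binary partition of one population.

    Ks is the sample-size-weighted mean of within-group mean pairwise
    distances; Kt the mean over all pairs.  Raises when undefined (a group
    empty, both groups singletons, or Kt = 0).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("Kst needs exactly two groups present")
    n = labels.size
    Kt = D[np.triu_indices(n, k=1)].mean()
    if Kt == 0:
        raise ValueError("Kst undefined: all distances are zero")
    Ks = 0.0
    usable = 0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        Ki = _mean_within(D, idx)
        if not np.isnan(Ki):
            usable += 1
            Ks += idx.size / n * Ki
    if usable == 0:
        raise ValueError("Kst undefined: no group has two members")
    return 1.0 - Ks / Kt


def kst_permutation_test(D: np.ndarray, labels, populations, n_perm: int,
                         seed: int, tip_order: list[str] | None = None
                         ) -> KstResult:
    """Weighted-mean Kst across populations with a stratified permutation test.

    ``labels`` (binary, e.g. infected/uninfected) and ``populations`` are
    arrays aligned with the rows of the patristic matrix ``D``.  The observed
    statistic is the mean of per-population Kst values weighted by population
    sample size.  Each permutation shuffles labels independently *within*
    each population; p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    labels = np.asarray(labels)
    populations = np.asarray(populations)
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    pops = [p for p in dict.fromkeys(populations)]

    def stat(lab):
        per, weights = {}, {}
        for p in pops:
            idx = np.flatnonzero(populations == p)
            sub_lab = lab[idx]
            if np.unique(sub_lab).size < 2:
                logger.debug("population %s has uniform labels; skipped", p)
                continue
            try:
                per[p] = kst_statistic(D[np.ix_(idx, idx)], sub_lab)
            except ValueError:
                continue
            weights[p] = idx.size
        if not per:
            raise ValueError("Kst undefined in every population")
        total = sum(weights.values())
        weights = {p: w / total for p, w in weights.items()}
        return sum(weights[p] * per[p] for p in per), per, weights

    observed, per, weights = stat(labels)
    count = 0
    work = labels.copy()
    pop_idx = [np.flatnonzero(populations == p) for p in pops]
    for _ in range(n_perm):
        for idx in pop_idx:
            work[idx] = work[idx][rng.permutation(idx.size)]
        val, _, _ = stat(work)
        if val >= observed - 1e-12:
            count += 1
    p_value = (1 + count) / (1 + n_perm)
    return KstResult(per_population=per, weights=weights,
                     weighted_kst=float(observed), p_value=float(p_value),
                     n_permutations=n_perm, seed=seed)


def exhaustive_kst_pvalue(D: np.ndarray, labels) -> float:
    """Exact within-population permutation p-value for a single population
    (oracle-sized inputs only)."""
    labels = np.asarray(labels)
    observed = kst_statistic(D, labels)
    n = labels.size
    vals = []
    for perm in itertools.permutations(range(n)):
        vals.append(kst_statistic(D, labels[list(perm)]))
    vals = np.asarray(vals)
    return float((vals >= observed - 1e-12).mean())


# ---------------------------------------------------------------------------
# proportions and concordance
# ---------------------------------------------------------------------------

def binomial_proportion_ci(x: int, n: int, level: float = 0.95):
    """Exact (Clopper–Pearson) confidence interval for a binomial proportion."""
    if not 0 <= x <= n or n < 1:
        raise ValueError("need 0 <= x <= n and n >= 1")
    a = 1.0 - level
    lower = 0.0 if x == 0 else float(beta.ppf(a / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta.ppf(1 - a / 2, x + 1, n - x))
    return lower, upper


def infection_fraction_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided Fisher exact test comparing infected fractions of two
    panels (x infected of n strains each).  Returns the p-value."""
    from scipy.stats import fisher_exact

    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts out of range")
    _, p = fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])
    return float(p)


def concordance(calls_a: dict, calls_b: dict):
    """Agreement between two call sets over identical strain keys.

    Returns ``(n_agree, n_total, fraction, discordant_ids)``.
    """
    if set(calls_a) != set(calls_b):
        raise ValueError("call sets cover different strains")
    if not calls_a:
        raise ValueError("empty call sets")
    discordant = sorted(k for k in calls_a if calls_a[k] != calls_b[k])
    n_total = len(calls_a)
    n_agree = n_total - len(discordant)
    return n_agree, n_total, n_agree / n_total, discordant
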