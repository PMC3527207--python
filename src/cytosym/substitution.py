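"""HKY85 nucleotide substitution model with discrete-gamma rate variation.

The model is parameterised by a transition/transversion ratio ``kappa``,
stationary base frequencies and (optionally) a gamma shape ``alpha`` for
among-site rate variation.  Rate variation uses Yang's discrete approximation:
``n_categories`` equal-probability categories, each represented by its
conditional mean rate, so the category rates average to 1.

The rate matrix is normalised so that branch lengths are expected
substitutions per site at rate multiplier 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

# nucleotide integer codes used throughout the package
ALPHABET = "ACGT"
CODE = {b: i for i, b in enumerate(ALPHABET)}
N_CODE = -1  # ambiguous / missing


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability gamma categories.

    Gamma has shape ``alpha`` and mean 1 (scale ``1/alpha``).  Returns an array
    of category rates with mean exactly 1 (renormalised against truncation
    error of the incomplete-gamma evaluation).
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    if n_categories == 1:
        return np.ones(1)
    probs = np.arange(1, n_categories) / n_categories
    cuts = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], cuts, [np.inf]])
    # E[X | a < X < b] for Gamma(alpha, 1/alpha) via the shape alpha+1 identity
    upper = gammainc(alpha + 1, bounds[1:] * alpha)
    lower = gammainc(alpha + 1, bounds[:-1] * alpha)
    rates = n_categories * (upper - lower)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """HKY+Gamma model.

    Parameters
    ----------
    kappa : transition/transversion rate ratio (>0).
    freqs : stationary frequencies (pi_A, pi_C, pi_G, pi_T), summing to 1.
    alpha : gamma shape for rate variation; ``None`` disables rate variation.
    n_categories : number of discrete gamma categories.
    """

    kappa: float = 2.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alpha: float | None = None
    n_categories: int = 4
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("freqs must be 4 non-negative values summing to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")

    # -- rate matrix ------------------------------------------------------
    def rate_matrix(self) -> np.ndarray:
        """Normalised HKY generator Q (rows sum to 0, mean rate 1)."""
        pi = np.asarray(self.freqs, dtype=float)
        k = self.kappa
        Q = np.empty((4, 4))
        # transitions: A<->G (0,2), C<->T (1,3)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = pi[j]
                if (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1)):
                    rate *= k
                Q[i, j] = rate
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        return Q / mu

    def _eigen(self):
        if self._eig is None:
            Q = self.rate_matrix()
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            object.__setattr__(self, "_eig", (w.real, V.real, Vinv.real))
        return self._eig

    def transition_probs(self, t) -> np.ndarray:
        """P(t) = expm(Q t); ``t`` may be a scalar or an array of lengths.

        Returns shape ``t.shape + (4, 4)``.
        """
        w, V, Vinv = self._eigen()
        t = np.asarray(t, dtype=float)
        expwt = np.exp(np.multiply.outer(t, w))  # t.shape + (4,)
        P = np.einsum("...k,ik,kj->...ij", expwt, V, Vinv)
        return np.clip(P, 0.0, 1.0)

    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.n_categories)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string to int8 codes (N and gaps -> -1)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, N_CODE, dtype=np.int8)
    for base, code in CODE.items():
        out[arr == ord(base)] = code
    return out


def decode_sequence(codes: np.ndarray) -> str:
    lookup = np.array(list(ALPHABET + "N"))
    idx = np.where(codes < 0, 4, codes)
    return "".join(lookup[idx])
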