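"""Reversible nucleotide substitution models (GTR, F84) with discrete-gamma rates.

Rate matrices are normalised to one expected substitution per site per unit
branch length, so branch lengths everywhere in the package are expected
substitutions/site. Among-site rate variation uses the standard discrete
approximation of a mean-one gamma distribution: equal-probability categories
represented by their conditional means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

NUCLEOTIDES = "ACGT"

# Order of the six exchangeability parameters: AC, AG, AT, CG, CT, GT.
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Category rates for a mean-one gamma with shape ``alpha``.

    Categories have equal probability 1/n; each is represented by its
    conditional mean, so the discretised distribution keeps mean exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    if n_categories == 1:
        return np.ones(1)
    # Gamma(alpha, scale=1/alpha) has mean 1. Category mean over (a, b]:
    #   n * [I(alpha+1, b*alpha) - I(alpha+1, a*alpha)]
    # with I the regularised lower incomplete gamma function.
    probs = np.arange(1, n_categories) / n_categories
    cuts = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate(([0.0], cuts * alpha, [np.inf]))
    upper = np.where(np.isinf(bounds[1:]), 1.0, gammainc(alpha + 1, bounds[1:]))
    lower = gammainc(alpha + 1, bounds[:-1])
    rates = n_categories * (upper - lower)
    return rates / rates.mean()  # guard against round-off drift


@dataclass
class SubstModelParams:
    """Parameters of a reversible nucleotide model.

    model
        "GTR" (six exchangeabilities) or "F84" (single transition/transversion
        parameter ``kappa``; internally expanded to its GTR representation).
    exchangeabilities
        Six positive values in the order AC, AG, AT, CG, CT, GT (GTR only).
    kappa
        F84 transition/transversion parameter (>= 0). F84 is the GTR special
        case s_AG = 1 + kappa/pi_R, s_CT = 1 + kappa/pi_Y, transversions 1.
    pi
        Stationary base frequencies (A, C, G, T); positive, summing to 1.
    alpha
        Gamma shape for among-site rate variation.
    n_categories
        Number of discrete gamma categories (1 disables rate variation).
    blen_multiplier
        Per-partition branch-length scaler used by the partitioned engine.
    """

    model: str = "GTR"
    exchangeabilities: np.ndarray | None = None
    kappa: float | None = None
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float = 0.5
    n_categories: int = 4
    blen_multiplier: float = 1.0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (4,) or np.any(self.pi <= 0):
            raise ValueError("pi must be 4 positive frequencies")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")
        if self.model == "GTR":
            if self.exchangeabilities is None:
                self.exchangeabilities = np.ones(6)
            self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
            if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities <= 0):
                raise ValueError("GTR needs 6 positive exchangeabilities")
        elif self.model == "F84":
            if self.kappa is None:
                self.kappa = 0.0
            if self.kappa < 0:
                raise ValueError("F84 kappa must be >= 0")
        else:
            raise ValueError(f"unknown model {self.model!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.blen_multiplier <= 0:
            raise ValueError("blen_multiplier must be > 0")

    def effective_exchangeabilities(self) -> np.ndarray:
        if self.model == "GTR":
            return self.exchangeabilities
        pi_r = self.pi[0] + self.pi[2]  # purines A+G
        pi_y = self.pi[1] + self.pi[3]  # pyrimidines C+T
        s = np.ones(6)
        s[1] = 1.0 + self.kappa / pi_r  # AG
        s[4] = 1.0 + self.kappa / pi_y  # CT
        return s

    def rate_matrix(self) -> np.ndarray:
        """Normalised instantaneous rate matrix Q (rows sum to 0)."""
        s = self.effective_exchangeabilities()
        q = np.zeros((4, 4))
        for val, (i, j) in zip(s, _PAIRS):
            q[i, j] = val * self.pi[j]
            q[j, i] = val * self.pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.pi * np.diag(q)).sum()
        return q / mu

    def gamma_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)


class EigenSystem:
    """Spectral decomposition of a reversible Q for fast P(t) = exp(Qt).

    Uses the pi^(1/2) symmetrisation, so eigenvalues are real and the
    decomposition is numerically stable for any admissible parameters.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        sym = sqrt_pi[:, None] * q / sqrt_pi[None, :]   # D^1/2 Q D^-1/2
        eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2.0)
        self.eigval = eigval
        self.right = eigvec / sqrt_pi[:, None]      # U = D^-1/2 V
        self.left = eigvec.T * sqrt_pi[None, :]     # U^-1 = V^T D^1/2

    def transition_probs(self, t: float | np.ndarray) -> np.ndarray:
        """P(t); broadcasts over an array of times -> (..., 4, 4)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("branch length must be >= 0")
        expd = np.exp(np.multiply.outer(t, self.eigval))
        p = np.einsum("ik,...k,kj->...ij", self.right, expd, self.left)
        return np.maximum(p, 0.0)  # clip round-off negatives only


def transition_probs(params: SubstModelParams, t: float) -> np.ndarray:
    """Convenience single-call P(t) for ``params`` at branch length ``t``."""
    return EigenSystem(params.rate_matrix(), params.pi).transition_probs(t)
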