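"""Substitution models for likelihood computation.

All models are continuous-time reversible Markov processes specified by a
symmetric exchangeability matrix and stationary frequencies; the rate matrix
is normalized to one expected substitution per unit branch length. Transition
probabilities come from the eigendecomposition of the similarity-transformed
(symmetric) rate matrix. Among-site rate variation uses Yang's discrete
gamma with equal-probability categories and mean-per-category rates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

DNA_STATES = "ACGT"
RY_STATES = "RY"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of k equal-probability categories of a Gamma(alpha, alpha)
    distribution (mean 1)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k == 1:
        return np.ones(1)
    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], cuts * alpha, [np.inf]])
    cdf = gammainc(alpha + 1, edges)
    return (cdf[1:] - cdf[:-1]) * k


@dataclass
class SubstitutionModel:
    name: str
    states: str
    rate_matrix: np.ndarray  # normalized Q, rows sum to 0
    freqs: np.ndarray
    gamma_shape: float | None = None
    n_rate_categories: int = 1
    _eig: tuple | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.states)
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rate_matrix.shape != (n, n):
            raise ValueError("rate matrix shape mismatch")
        if not np.allclose(self.rate_matrix.sum(axis=1), 0, atol=1e-10):
            raise ValueError("rate matrix rows must sum to zero")
        if not np.isclose(self.freqs.sum(), 1.0):
            raise ValueError("frequencies must sum to one")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None or self.n_rate_categories == 1:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)

    def _eigendecomposition(self):
        if self._eig is None:
            d = np.sqrt(self.freqs)
            # similarity transform B = D^{1/2} Q D^{-1/2} is symmetric for
            # reversible Q; then P(t) = D^{-1/2} U exp(wt) U^T D^{1/2}
            B = (self.rate_matrix * d[:, None]) / d[None, :]
            B = (B + B.T) / 2  # enforce symmetry against roundoff
            w, U = np.linalg.eigh(B)
            right = U / d[:, None]
            left = (U * d[:, None]).T
            self._eig = (w, right, left)
        return self._eig

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) for one rate category; t <= 0 gives the identity."""
        n = self.n_states
        if t * rate <= 0:
            return np.eye(n)
        w, R, L = self._eigendecomposition()
        P = (R * np.exp(w * t * rate)[None, :]) @ L
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def with_gamma(self, alpha: float, k: int = 4) -> "SubstitutionModel":
        return SubstitutionModel(self.name + f"+G{k}", self.states,
                                 self.rate_matrix, self.freqs, alpha, k)


def _build(name: str, states: str, exchangeabilities: np.ndarray,
           freqs: np.ndarray, gamma_shape=None, k=1) -> SubstitutionModel:
    S = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(freqs, dtype=float)
    pi = pi / pi.sum()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    if mean_rate > 0:
        Q = Q / mean_rate
    return SubstitutionModel(name, states, Q, pi, gamma_shape, k)


def jc69(gamma_shape=None, k=4) -> SubstitutionModel:
    S = np.ones((4, 4))
    return _build("JC69", DNA_STATES, S, np.full(4, 0.25), gamma_shape,
                  k if gamma_shape else 1)


def k2p(kappa: float = 2.0, gamma_shape=None, k=4) -> SubstitutionModel:
    S = np.ones((4, 4))
    # transitions: A<->G (0,2), C<->T (1,3)
    S[0, 2] = S[2, 0] = S[1, 3] = S[3, 1] = kappa
    return _build("K2P", DNA_STATES, S, np.full(4, 0.25), gamma_shape,
                  k if gamma_shape else 1)


def hky(kappa: float = 2.0, freqs=(0.25, 0.25, 0.25, 0.25),
        gamma_shape=None, k=4) -> SubstitutionModel:
    S = np.ones((4, 4))
    S[0, 2] = S[2, 0] = S[1, 3] = S[3, 1] = kappa
    return _build("HKY", DNA_STATES, S, np.asarray(freqs), gamma_shape,
                  k if gamma_shape else 1)


def tn93(kappa_r: float = 2.0, kappa_y: float = 2.0,
         freqs=(0.25, 0.25, 0.25, 0.25), gamma_shape=None, k=4
         ) -> SubstitutionModel:
    S = np.ones((4, 4))
    S[0, 2] = S[2, 0] = kappa_r  # purine transition A<->G
    S[1, 3] = S[3, 1] = kappa_y  # pyrimidine transition C<->T
    return _build("TN93", DNA_STATES, S, np.asarray(freqs), gamma_shape,
                  k if gamma_shape else 1)


def gtr(rates=(1, 1, 1, 1, 1, 1), freqs=(0.25, 0.25, 0.25, 0.25),
        gamma_shape=None, k=4) -> SubstitutionModel:
    """General time-reversible; rates ordered AC, AG, AT, CG, CT, GT."""
    ac, ag, at, cg, ct, gt_ = rates
    S = np.array([[0, ac, ag, at],
                  [ac, 0, cg, ct],
                  [ag, cg, 0, gt_],
                  [at, ct, gt_, 0]], dtype=float)
    return _build("GTR", DNA_STATES, S, np.asarray(freqs), gamma_shape,
                  k if gamma_shape else 1)


def binary_ry(freqs=(0.5, 0.5), gamma_shape=None, k=4) -> SubstitutionModel:
    """Two-state purine/pyrimidine model for RY-recoded columns."""
    S = np.ones((2, 2))
    return _build("binary-RY", RY_STATES, S, np.asarray(freqs), gamma_shape,
                  k if gamma_shape else 1)


def poisson_aa(gamma_shape=None, k=4) -> SubstitutionModel:
    S = np.ones((20, 20))
    return _build("Poisson-AA", AA_STATES, S, np.full(20, 0.05), gamma_shape,
                  k if gamma_shape else 1)


def empirical_aa(exchangeabilities: np.ndarray, freqs: np.ndarray,
                 name: str = "empirical-AA", gamma_shape=None, k=4
                 ) -> SubstitutionModel:
    """Empirical amino-acid model from a supplied 20x20 symmetric
    exchangeability table (PAML ordering ARNDCQEGHILKMFPSTWYV)."""
    return _build(name, AA_STATES, exchangeabilities, freqs, gamma_shape,
                  k if gamma_shape else 1)


def load_paml_dat(path, gamma_shape=None, k=4) -> SubstitutionModel:
    """Read a PAML-format .dat empirical amino-acid model file: 19 rows of
    the lower-triangular exchangeability matrix followed by 20 frequencies."""
    numbers: list[float] = []
    with open(path) as fh:
        for line in fh:
            numbers.extend(float(x) for x in line.split())
    tri = numbers[:190]
    freqs = np.array(numbers[190:210])
    S = np.zeros((20, 20))
    idx = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = tri[idx]
            idx += 1
    return empirical_aa(S, freqs, name="empirical-AA", gamma_shape=gamma_shape, k=k)
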