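"""Goldman–Yang codon rate matrices and transition probabilities.

The instantaneous rate from codon *i* to codon *j* is zero unless they
differ at exactly one nucleotide position, and otherwise proportional to
the target codon's equilibrium frequency pi_j, multiplied by kappa for
transitions and by omega for nonsynonymous changes.  The matrix is scaled
so that the mean substitution rate at equilibrium is one, i.e. branch
lengths are expected substitutions per codon site.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from ..codes import GeneticCode, standard_code

_PI_TOL = 1e-6


def equal_frequencies(code: GeneticCode | None = None) -> np.ndarray:
    """Uniform equilibrium frequencies over the sense codons."""
    code = code or standard_code()
    return np.full(code.n_codons, 1.0 / code.n_codons)


def f3x4_frequencies(alignment, floor: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide composition.

    The frequency of a sense codon is the product of the empirical
    frequencies of its three nucleotides at codon positions 1–3,
    renormalized over the 61 sense codons.  A small floor keeps every
    codon reachable even when a nucleotide is absent at some position.
    """
    code = alignment.code
    counts = np.zeros((3, 4))  # position x T,C,A,G
    nt_index = {"T": 0, "C": 1, "A": 2, "G": 3}
    for row in alignment.codons:
        for idx in row:
            for p, nt in enumerate(code.codons[idx]):
                counts[p, nt_index[nt]] += 1
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, nt_index[c[0]]] * pos_freq[1, nt_index[c[1]]] * pos_freq[2, nt_index[c[2]]]
            for c in code.codons
        ]
    )
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def build_rate_matrix(
    code: GeneticCode, kappa: float, omega: float, pi: np.ndarray
) -> np.ndarray:
    """Scaled GY-style rate matrix Q over the sense codons.

    Parameters
    ----------
    kappa : float
        Transition/transversion rate ratio, > 0.
    omega : float
        Nonsynonymous/synonymous rate ratio dN/dS, >= 0.
    pi : array of shape (61,)
        Equilibrium codon frequencies (must sum to 1).
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if omega < 0:
        raise ValueError(f"omega must be non-negative, got {omega}")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (code.n_codons,):
        raise ValueError(f"pi must have length {code.n_codons}")
    if abs(pi.sum() - 1.0) > _PI_TOL or (pi < 0).any():
        raise ValueError("pi must be a probability distribution over sense codons")

    n = code.n_codons
    Q = np.zeros((n, n))
    rates = pi[code.nb_j].copy()
    rates[code.nb_ts] *= kappa
    rates[~code.nb_syn] *= omega
    Q[code.nb_i, code.nb_j] = rates
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    scale = -(pi * np.diag(Q)).sum()
    if scale <= 0:
        # omega = 0 with a code where every change is nonsynonymous cannot
        # happen for the standard code; guard against degenerate pi anyway
        raise ValueError("degenerate rate matrix: zero mean substitution rate")
    return Q / scale


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to one, entries clipped to be non-negative."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    P = expm(Q * t)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


class SpectralPropagator:
    """Reusable P(t) evaluator exploiting reversibility of the GY process.

    With D = diag(sqrt(pi)), the similarity transform B = D Q D^-1 is
    symmetric, so one eigendecomposition gives P(t) for every t.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(np.asarray(pi, dtype=float))
        B = (d[:, None] * Q) / d[None, :]
        B = 0.5 * (B + B.T)
        self.eigenvalues, self.U = np.linalg.eigh(B)
        self.d = d
        self._cache: dict = {}

    def prob(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"time must be non-negative, got {t}")
        P = self._cache.get(t)
        if P is None:
            E = self.U * np.exp(self.eigenvalues * t)
            P = (E @ self.U.T) * (self.d[None, :] / self.d[:, None])
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            self._cache[t] = P
        return P
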