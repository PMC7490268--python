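"""Codon-alignment simulation along a tree under GY-style dN/dS regimes.

Evolution is simulated by exact Gillespie event sampling per site and
branch using the same rate matrices as the likelihood engine, so every
replicate carries ground truth: the root sequence, per-site site-class
labels, and exact synonymous/nonsynonymous substitution counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..alignment import CodonAlignment
from ..codes import GeneticCode, standard_code
from ..trees import LabeledTree
from .rng import stream

_REGIMES = ("M0", "two_ratio", "branch_site")


@dataclass
class CodonSimSpec:
    """What to simulate: tree, kappa, frequency mode, omega regime, length.

    ``regime_params`` by regime:

    - ``M0``: ``{"omega"}``
    - ``two_ratio``: ``{"omega0", "omega1"}`` (background, foreground)
    - ``branch_site``: ``{"p0", "p1", "omega0", "omega2"}`` — Model A class
      structure with omega1 = 1 and the class-2 remainder split
      proportionally between 2a and 2b
    """

    tree: LabeledTree
    kappa: float = 2.0
    regime: str = "M0"
    regime_params: dict = field(default_factory=lambda: {"omega": 0.3})
    n_sites: int = 300
    pi: np.ndarray | None = None  # defaults to equal sense-codon frequencies
    seed: int = 0
    code: GeneticCode = field(default_factory=standard_code)

    def __post_init__(self):
        if self.regime not in _REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {_REGIMES}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if any(v < 0 for v in self.regime_params.values()):
            raise ValueError("all regime parameters must be non-negative")
        if self.regime == "branch_site":
            p0, p1 = self.regime_params["p0"], self.regime_params["p1"]
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1 and p0 + p1 <= 1 + 1e-12):
                raise ValueError("site-class proportions must lie in [0,1] and sum to <= 1")


@dataclass
class SimulatedAlignment:
    """A simulated alignment plus its generating ground truth."""

    alignment: CodonAlignment
    site_classes: np.ndarray  # per-site class index (0 for M0/two_ratio)
    root_codons: np.ndarray
    n_synonymous: int
    n_nonsynonymous: int


def _site_class_table(spec: CodonSimSpec):
    """(weights, omega_bg, omega_fg) arrays for the simulated site classes."""
    p = spec.regime_params
    if spec.regime == "M0":
        return np.array([1.0]), np.array([p["omega"]]), np.array([p["omega"]])
    if spec.regime == "two_ratio":
        return np.array([1.0]), np.array([p["omega0"]]), np.array([p["omega1"]])
    p0, p1, w0, w2 = p["p0"], p["p1"], p["omega0"], p["omega2"]
    p2 = max(0.0, 1.0 - p0 - p1)
    s = p0 + p1
    p2a, p2b = (p2 * p0 / s, p2 * p1 / s) if s > 0 else (p2 / 2, p2 / 2)
    return (
        np.array([p0, p1, p2a, p2b]),
        np.array([w0, 1.0, w0, 1.0]),
        np.array([w0, 1.0, w2, w2]),
    )


def simulate_codon_alignment(spec: CodonSimSpec) -> SimulatedAlignment:
    """Evolve a codon alignment along ``spec.tree`` by Gillespie sampling.

    The root sequence is drawn from the equilibrium distribution; each
    branch then evolves every site with exponential waiting times under
    the (mean-rate-one scaled) rate matrix of that site's class and the
    branch's foreground status.  Branch lengths are therefore expected
    substitutions per codon site.
    """
    from ..selection.gy94 import build_rate_matrix, equal_frequencies

    code = spec.code
    pi = equal_frequencies(code) if spec.pi is None else np.asarray(spec.pi, float)
    rng = stream(spec.seed, "codon-sim")
    weights, om_bg, om_fg = _site_class_table(spec)
    site_classes = rng.choice(weights.size, size=spec.n_sites, p=weights / weights.sum())

    # unique omega values -> rate matrix with cumulative jump distributions
    omegas = sorted(set(np.concatenate([om_bg, om_fg])))
    Qs = {om: build_rate_matrix(code, spec.kappa, om, pi) for om in omegas}
    exit_rates = {om: -np.diag(Q) for om, Q in Qs.items()}
    jump_cdf = {}
    for om, Q in Qs.items():
        J = Q.copy()
        np.fill_diagonal(J, 0.0)
        rows = J.sum(axis=1, keepdims=True)
        jump_cdf[om] = np.cumsum(J / np.where(rows > 0, rows, 1.0), axis=1)

    root = rng.choice(code.n_codons, size=spec.n_sites, p=pi)
    syn_aa = np.array(code.amino_acids)
    n_syn = n_nonsyn = 0

    seqs = {}
    states = {id(spec.tree.root): root.copy()}
    for node in _preorder(spec.tree):
        if node is spec.tree.root:
            if node.is_leaf:
                seqs[node.name] = root.copy()
            continue
        parent_state = states[id(node.parent)]
        child_state = parent_state.copy()
        omega_of_site = (om_fg if node.foreground else om_bg)[site_classes]
        for s in range(spec.n_sites):
            om = omega_of_site[s]
            rate, cdf = exit_rates[om], jump_cdf[om]
            t, c = 0.0, child_state[s]
            while True:
                r = rate[c]
                if r <= 0:
                    break
                t += rng.exponential(1.0 / r)
                if t >= node.length:
                    break
                nxt = int(np.searchsorted(cdf[c], rng.random()))
                if syn_aa[nxt] == syn_aa[c]:
                    n_syn += 1
                else:
                    n_nonsyn += 1
                c = nxt
            child_state[s] = c
        states[id(node)] = child_state
        if node.is_leaf:
            seqs[node.name] = child_state

    taxa = spec.tree.taxa()
    aln = CodonAlignment(
        taxa=taxa, codons=np.array([seqs[t] for t in taxa]), code=code
    )
    return SimulatedAlignment(
        alignment=aln,
        site_classes=site_classes,
        root_codons=root,
        n_synonymous=n_syn,
        n_nonsynonymous=n_nonsyn,
    )


def _preorder(tree: LabeledTree):
    stack = [tree.root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))
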