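"""Felsenstein pruning over codon states with site-pattern compression."""

from __future__ import annotations

import numpy as np

from ..alignment import CodonAlignment
from ..trees import LabeledTree, Node


class PruningEngine:
    """Computes per-site-pattern log-likelihoods on a fixed alignment + tree.

    The engine compresses identical alignment columns into patterns once;
    each call to :meth:`pattern_logliks` supplies a transition matrix per
    branch (so site-class mixtures with branch-specific omega reuse the
    same engine) and returns the log-likelihood of every pattern.
    """

    def __init__(self, alignment: CodonAlignment, tree: LabeledTree):
        if set(alignment.taxa) != set(tree.taxa()):
            missing = set(alignment.taxa) ^ set(tree.taxa())
            raise ValueError(f"alignment/tree taxon mismatch: {sorted(missing)}")
        if alignment.n_sites == 0:
            raise ValueError("alignment has no usable sites")
        self.alignment = alignment
        self.tree = tree
        self.n_states = alignment.code.n_codons
        cols, inverse, counts = alignment.site_patterns()
        self.patterns = cols  # (n_taxa, n_patterns)
        self.pattern_of_site = inverse
        self.pattern_counts = counts.astype(float)
        self.postorder = list(tree.postorder())
        self.branches = [n for n in self.postorder if n is not tree.root]
        self._leaf_states = {
            id(node): cols[alignment.taxa.index(node.name)] for node in tree.leaves()
        }

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def branch_lengths(self) -> np.ndarray:
        return np.array([b.length for b in self.branches])

    def pattern_logliks(self, P_of_branch, root_freqs: np.ndarray) -> np.ndarray:
        """Log-likelihood of each site pattern.

        Parameters
        ----------
        P_of_branch : callable
            Maps a branch :class:`Node` to its transition matrix P(t).
        root_freqs : array (n_states,)
            Equilibrium distribution at the root.
        """
        n_pat = self.n_patterns
        partial: dict = {}
        logscale = np.zeros(n_pat)
        for node in self.postorder:
            if node.is_leaf:
                continue
            prod = np.ones((n_pat, self.n_states))
            for child in node.children:
                P = P_of_branch(child)
                if child.is_leaf:
                    # sum_j P[s, j] * 1{j = observed} = P[:, observed]
                    prod *= P.T[self._leaf_states[id(child)], :]
                else:
                    prod *= partial.pop(id(child)) @ P.T
            scale = prod.max(axis=1)
            # all-zero rows are impossible for strictly positive P
            prod /= scale[:, None]
            logscale += np.log(scale)
            partial[id(node)] = prod
        root = partial[id(self.tree.root)] if not self.tree.root.is_leaf else None
        if root is None:
            # single-taxon "tree": likelihood is the stationary probability
            states = self._leaf_states[id(self.tree.root)]
            return np.log(root_freqs[states])
        return np.log(root @ root_freqs) + logscale

    def site_logliks_from_patterns(self, pat_logliks: np.ndarray) -> np.ndarray:
        return pat_logliks[self.pattern_of_site]

    def total_loglik(self, pat_logliks: np.ndarray) -> float:
        return float(self.pattern_counts @ pat_logliks)


def enumeration_loglik(alignment: CodonAlignment, tree: LabeledTree,
                       P_of_branch, root_freqs: np.ndarray) -> float:
    """Brute-force likelihood summing over all internal-node state combinations.

    Exponential in the number of internal nodes — the independent oracle for
    the pruning recursion on tiny trees, never a production path.
    """
    internals = [n for n in tree.postorder() if not n.is_leaf]
    n_states = alignment.code.n_codons
    leaf_state = {n.name: alignment.row(n.name) for n in tree.leaves()}

    total = 0.0
    for site in range(alignment.n_sites):
        site_sum = 0.0
        assignment: dict = {}

        def branch_prob(node: Node, parent_state: int) -> float:
            state = (
                leaf_state[node.name][site] if node.is_leaf else assignment[id(node)]
            )
            return P_of_branch(node)[parent_state, state]

        def recurse(k: int) -> None:
            nonlocal site_sum
            if k == len(internals):
                root = internals[-1] if internals else None
                prob = root_freqs[assignment[id(tree.root)]]
                for node in tree.postorder():
                    if node is tree.root:
                        continue
                    prob *= branch_prob(node, assignment[id(node.parent)])
                site_sum += prob
                return
            for s in range(n_states):
                assignment[id(internals[k])] = s
                recurse(k + 1)

        recurse(0)
        total += np.log(site_sum)
    return float(total)
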