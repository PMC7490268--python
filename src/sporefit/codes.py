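"""Standard genetic code indexed for codon-model work.

The 61 sense codons of the standard nuclear code are held in a fixed
alphabetical order; all rate-matrix and likelihood code addresses codons
by their index in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code with a precomputed single-step neighbor map.

    Attributes
    ----------
    codons : tuple of str
        The 61 sense codons, alphabetically ordered.
    stop_codons : frozenset of str
        The three stop codons.
    amino_acids : tuple of str
        One-letter amino acid per sense codon, aligned with ``codons``.
    """

    codons: tuple
    stop_codons: frozenset
    amino_acids: tuple
    index: dict = field(repr=False)
    # neighbor arrays: pairs (i, j) of sense codons one nucleotide apart,
    # with the changed position, transition flag and synonymy flag
    nb_i: np.ndarray = field(repr=False)
    nb_j: np.ndarray = field(repr=False)
    nb_pos: np.ndarray = field(repr=False)
    nb_ts: np.ndarray = field(repr=False)
    nb_syn: np.ndarray = field(repr=False)

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    def translate(self, codon: str) -> str:
        return self.amino_acids[self.index[codon]]

    def encode(self, seq: str) -> np.ndarray:
        """Map an in-frame nucleotide string to codon indices.

        Raises ``ValueError`` on stop codons or characters outside ACGT.
        """
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError(f"sequence length {len(seq)} not divisible by 3")
        out = np.empty(len(seq) // 3, dtype=np.int64)
        for k in range(out.size):
            codon = seq[3 * k : 3 * k + 3]
            if codon in self.stop_codons:
                raise ValueError(f"stop codon {codon} at codon position {k + 1}")
            try:
                out[k] = self.index[codon]
            except KeyError:
                raise ValueError(f"unrecognized codon {codon!r} at codon position {k + 1}") from None
        return out

    def decode(self, indices) -> str:
        return "".join(self.codons[i] for i in indices)


def _build_standard() -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[1]
    stops = frozenset(table.stop_codons)
    sense = tuple(sorted(c for c in table.forward_table))
    aas = tuple(table.forward_table[c] for c in sense)
    index = {c: i for i, c in enumerate(sense)}

    nb_i, nb_j, nb_pos, nb_ts, nb_syn = [], [], [], [], []
    for i, ci in enumerate(sense):
        for j, cj in enumerate(sense):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            nb_i.append(i)
            nb_j.append(j)
            nb_pos.append(p)
            nb_ts.append(is_transition(ci[p], cj[p]))
            nb_syn.append(aas[i] == aas[j])
    return GeneticCode(
        codons=sense,
        stop_codons=stops,
        amino_acids=aas,
        index=index,
        nb_i=np.array(nb_i, dtype=np.int64),
        nb_j=np.array(nb_j, dtype=np.int64),
        nb_pos=np.array(nb_pos, dtype=np.int64),
        nb_ts=np.array(nb_ts, dtype=bool),
        nb_syn=np.array(nb_syn, dtype=bool),
    )


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (61 sense codons, 3 stops)."""
    return _build_standard()
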