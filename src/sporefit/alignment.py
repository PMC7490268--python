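"""In-frame codon alignments.

A :class:`CodonAlignment` stores one row of codon indices per taxon; columns
containing gaps or ambiguity codes are removed at construction when the
``cleandata`` policy is active (the default), mirroring common codon-model
practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .codes import GeneticCode, standard_code

_VALID = set("ACGT")


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences over the sense codons.

    Attributes
    ----------
    taxa : list of str
        Sequence names, one per row.
    codons : numpy.ndarray, shape (n_taxa, n_sites)
        Codon indices into ``code.codons``.
    """

    taxa: list
    codons: np.ndarray
    code: GeneticCode = field(default_factory=standard_code)

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=np.int64)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codon matrix must be (n_taxa, n_sites)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names in alignment")

    @property
    def n_taxa(self) -> int:
        return self.codons.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    def sequence(self, taxon: str) -> str:
        return self.code.decode(self.codons[self.taxa.index(taxon)])

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]

    @classmethod
    def from_sequences(cls, named_seqs, code: GeneticCode | None = None,
                       cleandata: bool = True) -> "CodonAlignment":
        """Build from ``(name, nucleotide_string)`` pairs.

        With ``cleandata`` (default) any codon column containing a gap,
        ambiguity character or stop codon in any taxon is dropped with a
        warning; with ``cleandata=False`` such columns raise.
        """
        code = code or standard_code()
        named_seqs = list(named_seqs)
        if not named_seqs:
            raise ValueError("empty alignment")
        names = [n for n, _ in named_seqs]
        seqs = [s.upper().replace("U", "T") for _, s in named_seqs]
        length = len(seqs[0])
        if any(len(s) != length for s in seqs):
            raise ValueError("sequences are not all the same length")
        if length % 3:
            raise ValueError(f"alignment length {length} not divisible by 3")

        n_sites = length // 3
        keep, rows = [], [[] for _ in names]
        for k in range(n_sites):
            col = [s[3 * k : 3 * k + 3] for s in seqs]
            bad = None
            for t, codon in enumerate(col):
                if not set(codon) <= _VALID:
                    bad = f"ambiguity/gap {codon!r} in {names[t]}"
                elif codon in code.stop_codons:
                    bad = f"internal stop {codon} in {names[t]}"
                if bad:
                    break
            if bad:
                if not cleandata:
                    raise ValueError(f"codon column {k + 1}: {bad}")
                continue
            keep.append(k)
            for t, codon in enumerate(col):
                rows[t].append(code.index[codon])
        dropped = n_sites - len(keep)
        if dropped:
            warnings.warn(f"cleandata: dropped {dropped} of {n_sites} codon columns")
        if not keep:
            raise ValueError("no usable codon columns after cleaning")
        return cls(taxa=names, codons=np.array(rows, dtype=np.int64), code=code)

    def site_patterns(self):
        """Unique site columns and their multiplicities (likelihood speedup)."""
        cols, inverse, counts = np.unique(
            self.codons, axis=1, return_inverse=True, return_counts=True
        )
        return cols, inverse, counts
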