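"""FASTA I/O for in-frame codon alignments."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from ..alignment import CodonAlignment


def read_codon_fasta(path, cleandata: bool = True) -> CodonAlignment:
    """Read an aligned in-frame FASTA into a :class:`CodonAlignment`.

    Validates equal lengths, length divisible by three and unique taxon
    names.  Under the default ``cleandata`` policy, codon columns with
    gaps, ambiguity characters or stops are dropped (with a warning);
    with ``cleandata=False`` they raise, naming the offending taxon.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate taxon names in {path}: {dupes}")
    return CodonAlignment.from_sequences(
        [(r.id, str(r.seq)) for r in records], cleandata=cleandata
    )


def write_codon_fasta(alignment: CodonAlignment, path) -> None:
    """Write the alignment back out as FASTA (60-column wrapping)."""
    lines = []
    for taxon in alignment.taxa:
        seq = alignment.sequence(taxon)
        lines.append(f">{taxon}")
        lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    Path(path).write_text("\n".join(lines) + "\n")
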