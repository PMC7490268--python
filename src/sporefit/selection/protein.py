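"""Protein-level utilities: GRAVY hydropathy and polymorphic-site tokens."""

from __future__ import annotations

import warnings

from Bio.SeqUtils.ProtParam import ProtParamData

_KD = ProtParamData.kd  # Kyte-Doolittle hydropathy scale
_STANDARD = set(_KD)


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value per residue."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - _STANDARD
    if bad:
        raise ValueError(f"non-standard amino acid letters: {sorted(bad)}")
    return sum(_KD[aa] for aa in seq) / len(seq)


def polymorphic_sites(seq_a: str, seq_b: str) -> list:
    """Substitution tokens between two aligned protein sequences.

    Tokens are ``"<res_a><1-based position><res_b>"`` (e.g. ``"N57D"``).
    Positions where either sequence has a gap are excluded with a warning;
    position numbering counts alignment columns.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length: {len(a)} vs {len(b)}")
    tokens, gapped = [], 0
    for pos, (ra, rb) in enumerate(zip(a, b), start=1):
        if ra in "-." or rb in "-.":
            gapped += 1
            continue
        if ra != rb:
            tokens.append(f"{ra}{pos}{rb}")
    if gapped:
        warnings.warn(f"excluded {gapped} gapped column(s) from polymorphic-site scan")
    return tokens
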