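"""Named, reproducible random streams.

One global seed governs a per-component stream split by stable names, so
regenerating a single input family never perturbs the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, name: str) -> np.random.Generator:
    """Generator for component ``name`` derived from the global ``seed``."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
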