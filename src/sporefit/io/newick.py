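"""File-level Newick I/O for foreground-labeled trees.

The parsing itself lives in :mod:`sporefit.trees` (codeml ``#1`` tag
dialect); this module adds the path-based convenience layer.
"""

from __future__ import annotations

from pathlib import Path

from ..trees import LabeledTree, parse_newick


def read_labeled_newick(path) -> LabeledTree:
    return parse_newick(Path(path).read_text())


def write_labeled_newick(tree: LabeledTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
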