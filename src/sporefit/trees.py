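"""Phylogenetic trees with codeml-style foreground branch tags.

Branch models of selection need per-branch foreground/background labels.
The conventional way to carry these in Newick is the codeml ``#1`` tag
dialect, e.g. ``((A:1,B:1)#1:1,C:2);`` — a dialect the general-purpose tree
libraries do not round-trip, so parsing and writing live here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass
class Node:
    """One node; the branch above it carries ``length`` and ``foreground``."""

    name: str = ""
    length: float = 0.0
    foreground: bool = False
    children: list = field(default_factory=list)
    parent: Optional["Node"] = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class LabeledTree:
    """Rooted tree whose branches may be tagged as selection foreground."""

    def __init__(self, root: Node):
        self.root = root
        for node in self.postorder():
            if node.length < 0:
                raise ValueError(f"negative branch length on {node.name or 'internal node'}")

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list:
        return [n for n in self.postorder() if n.is_leaf]

    def taxa(self) -> list:
        return [n.name for n in self.leaves()]

    def branches(self) -> list:
        """All non-root nodes (each identifies the branch above it)."""
        return [n for n in self.postorder() if n is not self.root]

    def has_foreground(self) -> bool:
        return any(n.foreground for n in self.branches())

    def tag_clade(self, taxa, include_stem: bool = True) -> None:
        """Mark the branches of the smallest clade spanning ``taxa`` as foreground."""
        want = set(taxa)
        below: dict = {}
        mrca = None
        for node in self.postorder():
            below[id(node)] = (
                {node.name} if node.is_leaf else set().union(*(below[id(c)] for c in node.children))
            )
            if mrca is None and want <= below[id(node)]:
                mrca = node
        if mrca is None:
            raise ValueError(f"taxa {sorted(want)} not all present in tree")
        stack = list(mrca.children)
        while stack:
            n = stack.pop()
            n.foreground = True
            stack.extend(n.children)
        if include_stem and mrca is not self.root:
            mrca.foreground = True

    def copy(self) -> "LabeledTree":
        return parse_newick(self.to_newick())

    def to_newick(self) -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                core = node.name
            else:
                core = "(" + ",".join(render(c) for c in node.children) + ")" + node.name
            if node is self.root:
                return core
            tag = " #1" if node.foreground else ""
            return f"{core}{tag}:{node.length:.10g}"

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"LabeledTree({len(self.taxa())} taxa, foreground={self.has_foreground()})"


_TOKEN = re.compile(r"\s*([(),;:]|#\s*\d+|[^\s(),;:#]+)")


def parse_newick(text: str) -> LabeledTree:
    """Parse Newick with optional codeml ``#<k>`` branch tags.

    A tag may follow either the node label or the branch length
    (``A#1:0.1`` and ``A:0.1 #1`` are both accepted); any nonzero tag
    number marks the branch as foreground.
    """
    tokens = _TOKEN.findall(text)
    if not tokens or tokens[-1] != ";":
        raise ValueError("Newick string must end with ';'")
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_node() -> Node:
        node = Node()
        if peek() == "(":
            take()
            node.add(parse_node())
            while peek() == ",":
                take()
                node.add(parse_node())
            if take() != ")":
                raise ValueError("unbalanced parentheses in Newick string")
        tok = peek()
        if tok is not None and tok not in "(),;:" and not tok.startswith("#"):
            node.name = take()
        _consume_tag(node)
        if peek() == ":":
            take()
            try:
                node.length = float(take())
            except ValueError:
                raise ValueError("malformed branch length") from None
        _consume_tag(node)
        return node

    def _consume_tag(node: Node) -> None:
        tok = peek()
        if tok is not None and tok.startswith("#"):
            take()
            node.foreground = int(tok[1:].strip()) != 0

    root = parse_node()
    if take() != ";":
        raise ValueError("trailing content after root node")
    if pos != len(tokens):
        raise ValueError("trailing content after ';'")
    tree = LabeledTree(root)
    names = tree.taxa()
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon names in tree")
    if root.foreground:
        raise ValueError("the root has no branch; a foreground tag on it is meaningless")
    return tree
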