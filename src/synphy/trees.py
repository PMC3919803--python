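"""Phylogenetic tree container and Newick round-tripping.

:class:`PhyloTree` is a minimal rooted view of an (implicitly unrooted)
tree: named leaves, branch lengths in expected substitutions per site,
polytomies allowed. Newick parsing is delegated to dendropy; the writer
emits 12 significant digits so round trips preserve lengths well below
the 1e-9 tolerance the rest of the package assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0  # branch to parent; ignored at the root
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Tree topology with branch lengths; leaf names unique."""

    def __init__(self, root: Node):
        self.root = root
        names = [n.name for n in self.leaves()]
        if len(names) != len(set(names)):
            raise ValueError("duplicate leaf names in tree")
        if any(name is None for name in names):
            raise ValueError("every leaf must be named")

    # -- traversal ----------------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[Node]:
        """All non-root nodes (each owns the branch to its parent)."""
        return [n for n in self.preorder() if n is not self.root]

    def total_length(self) -> float:
        return sum(n.length for n in self.branches())

    # -- manipulation -------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def rec(n: Node) -> Node:
            return Node(n.name, n.length, [rec(c) for c in n.children])

        return PhyloTree(rec(self.root))

    def deroot(self) -> "PhyloTree":
        """Collapse a bifurcating root into a trifurcation (in place).

        The two root-child branch lengths are merged; a no-op for roots of
        degree != 2 or for cherry-only trees.
        """
        r = self.root
        if len(r.children) == 2:
            a, b = r.children
            internal = b if b.children else a
            other = a if internal is b else b
            if internal.children:
                other.length = a.length + b.length
                internal.children.append(other)
                internal.length = 0.0
                self.root = internal
        return self

    def splits(self) -> frozenset[frozenset[str]]:
        """Canonical bipartition set (each side as the half not containing
        the lexicographically first leaf), including trivial splits."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out = set()

        def rec(n: Node) -> frozenset[str]:
            if n.is_leaf:
                below = frozenset([n.name])
            else:
                below = frozenset().union(*(rec(c) for c in n.children))
            if n is not self.root:
                side = below if ref not in below else all_leaves - below
                if side and side != all_leaves:
                    out.add(side)
            return below

        rec(self.root)
        return frozenset(out)

    def __repr__(self) -> str:
        return f"PhyloTree({len(self.leaf_names())} leaves)"


def read_newick(text: str) -> PhyloTree:
    """Parse a single Newick statement into a :class:`PhyloTree`.

    Unlabeled branch lengths default to 0. Unbalanced parentheses and
    duplicate leaf names raise ``ValueError``.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise ValueError(f"malformed Newick: {exc}") from exc

    def rec(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon is not None else None
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        return Node(name, float(length), [rec(c) for c in dnode.child_nodes()])

    return PhyloTree(rec(dtree.seed_node))


def write_newick(tree: PhyloTree) -> str:
    """Serialize with 12 significant digits on every branch length."""

    def needs_quotes(name: str) -> bool:
        return any(c in name for c in " ()[]:;,'")

    def fmt_name(name: str) -> str:
        if needs_quotes(name):
            return "'" + name.replace("'", "''") + "'"
        return name

    def rec(n: Node, at_root: bool) -> str:
        if n.is_leaf:
            body = fmt_name(n.name)
        else:
            body = "(" + ",".join(rec(c, False) for c in n.children) + ")"
        if at_root:
            return body
        return f"{body}:{n.length:.12g}"

    return rec(tree.root, True) + ";"
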