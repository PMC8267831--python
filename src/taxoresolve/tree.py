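"""Rooted labeled trees with branch lengths and per-node support values.

Newick dialect: support values are stored as internal-node labels (the
RAxML convention), branch lengths follow colons, the root may carry no
length.  Reading and writing are mutually inverse; branch lengths survive
a round trip to 6 decimals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy


class NewickParseError(ValueError):
    pass


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> "TreeNode":
        self.children.append(child)
        return child


class LabeledTree:
    """A rooted tree whose tips map to strain identifiers."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [t.name for t in self.tips()]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise NewickParseError(f"duplicate tip labels: {dupes}")

    # ------------------------------------------------------------------ walks
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def parent_map(self) -> dict[int, Optional[TreeNode]]:
        parents: dict[int, Optional[TreeNode]] = {id(self.root): None}
        for node in self.preorder():
            for child in node.children:
                parents[id(child)] = node
        return parents

    def tipsets(self) -> dict[int, frozenset]:
        """Map node id -> frozenset of descendant tip names."""
        sets: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[id(node)] = frozenset((node.name,))
            else:
                acc: set = set()
                for c in node.children:
                    acc |= sets[id(c)]
                sets[id(node)] = frozenset(acc)
        return sets

    def find_tip(self, name: str) -> TreeNode:
        for t in self.tips():
            if t.name == name:
                return t
        raise KeyError(f"tip {name!r} not in tree")

    def mrca(self, names) -> TreeNode:
        target = frozenset(names)
        missing = target - frozenset(self.tip_names())
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        sets = self.tipsets()
        best = self.root
        # Deepest node whose tipset covers the target.
        for node in self.postorder():
            if target <= sets[id(node)]:
                return node
        return best

    def depths(self) -> dict[int, float]:
        """Path length from the root to every node (missing lengths = 0)."""
        out = {id(self.root): 0.0}
        for node in self.preorder():
            for child in node.children:
                out[id(child)] = out[id(node)] + (child.length or 0.0)
        return out

    def copy(self) -> "LabeledTree":
        def clone(n: TreeNode) -> TreeNode:
            return TreeNode(n.name, n.length, n.support,
                            [clone(c) for c in n.children])
        return LabeledTree(clone(self.root))

    def prune(self, names) -> "LabeledTree":
        """Return a copy with the given tips removed.

        Unary nodes left behind are contracted, merging branch lengths so
        tip-to-root path lengths are preserved.
        """
        drop = set(names)
        keep = [n for n in self.tip_names() if n not in drop]
        if len(keep) < 2:
            raise ValueError("pruning would leave fewer than two tips")

        def rebuild(node: TreeNode) -> Optional[TreeNode]:
            if node.is_leaf:
                if node.name in drop:
                    return None
                return TreeNode(node.name, node.length, node.support)
            kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                only = kids[0]
                merged = TreeNode(only.name, only.length, only.support,
                                  only.children)
                if node.length is not None or only.length is not None:
                    merged.length = (node.length or 0.0) + (only.length or 0.0)
                return merged
            return TreeNode(node.name, node.length, node.support, kids)

        root = rebuild(self.root)
        if root is None:
            raise ValueError("pruning removed every tip")
        # A rooted tree's root should not be unary after pruning either.
        while len(root.children) == 1 and not root.children[0].is_leaf:
            only = root.children[0]
            root = TreeNode(root.name, None, only.support, only.children)
        return LabeledTree(root)

    def __len__(self) -> int:
        return len(self.tips())


# ---------------------------------------------------------------------- I/O

def _format_length(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_newick(tree: LabeledTree) -> str:
    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            inner = ",".join(fmt(c, False) for c in node.children)
            label = ""
            if node.support is not None:
                label = _format_length(node.support)
            elif node.name:
                label = node.name
            body = f"({inner}){label}"
        if node.length is not None and not is_root:
            body += f":{_format_length(node.length)}"
        return body

    return fmt(tree.root, True) + ";"


def read_newick(text: str) -> LabeledTree:
    """Parse a Newick string (internal labels interpreted as support)."""
    if text.count("(") != text.count(")"):
        # Find the first position where the parenthesis balance breaks.
        depth, pos = 0, len(text)
        for i, ch in enumerate(text):
            depth += (ch == "(") - (ch == ")")
            if depth < 0:
                pos = i
                break
        raise NewickParseError(
            f"unbalanced parentheses near position {pos}"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickParseError(f"invalid Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        node = TreeNode()
        node.length = (
            float(dnode.edge.length) if dnode.edge.length is not None else None
        )
        if dnode.is_leaf():
            node.name = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            label = dnode.label
            if label is not None:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    root.length = None  # the root carries no branch
    tree = LabeledTree(root)
    names = tree.tip_names()
    if any(n is None for n in names):
        raise NewickParseError("unlabeled tip in Newick input")
    return tree


def read_newick_file(path) -> LabeledTree:
    with io.open(path, "r", encoding="utf-8") as fh:
        return read_newick(fh.read().strip())


def write_newick_file(tree: LabeledTree, path) -> None:
    with io.open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(tree) + "\n")
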