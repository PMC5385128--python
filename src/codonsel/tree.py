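"""Rooted phylogenies with branch lengths and a foreground/background
branch partition.

Branch labels use the PAML ``#k`` suffix convention in Newick; only labels
0 (implicit, background) and 1 (foreground) are meaningful here, since all
models in this package are at most two-partition. Trees are stored rooted,
but every reversible-model computation downstream is invariant to root
placement (tested explicitly).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

DEFAULT_BRANCH_LENGTH = 0.1


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset."""

    def __init__(self, message: str, offset: int):
        self.offset = offset
        super().__init__(f"{message} (at character {offset})")


@dataclass
class Node:
    index: int
    name: str = ""
    length: float | None = None  # None for the root
    label: int = 0  # 0 background, 1 foreground (label of the parent edge)
    parent: int | None = None
    children: list[int] = field(default_factory=list)


class LabeledTree:
    """A rooted tree; every non-root node owns its parent edge (length and
    foreground/background label)."""

    def __init__(self, nodes: list[Node], root: int):
        self.nodes = nodes
        self.root = root

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "LabeledTree":
        return parse_newick(text)

    def copy(self) -> "LabeledTree":
        nodes = [
            Node(n.index, n.name, n.length, n.label, n.parent, list(n.children))
            for n in self.nodes
        ]
        return LabeledTree(nodes, self.root)

    # -- traversal ----------------------------------------------------------

    def postorder(self) -> list[int]:
        out, stack = [], [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.nodes[v].children)
        return out[::-1]

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def leaves(self) -> list[int]:
        return [v for v in self.postorder() if not self.nodes[v].children]

    @property
    def leaf_names(self) -> list[str]:
        return [self.nodes[v].name for v in self.leaves()]

    def branch_nodes(self) -> list[int]:
        """Indices of nodes owning a branch (all but the root)."""
        return [v for v in self.postorder() if v != self.root]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def total_length(self) -> float:
        return sum(
            self.nodes[v].length or 0.0 for v in self.branch_nodes()
        )

    def foreground_nodes(self) -> list[int]:
        return [v for v in self.branch_nodes() if self.nodes[v].label == 1]

    def find(self, name: str) -> int:
        for n in self.nodes:
            if n.name == name:
                return n.index
        raise KeyError(f"no node named {name!r}")

    def set_foreground(self, names) -> None:
        """Mark the parent edges of the named nodes as foreground."""
        for nm in names:
            self.nodes[self.find(nm)].label = 1

    def node_name(self, v: int) -> str:
        n = self.nodes[v]
        return n.name or f"node{v}"

    # -- edits --------------------------------------------------------------

    def scale_lengths(self, factor: float) -> None:
        for v in self.branch_nodes():
            self.nodes[v].length = (self.nodes[v].length or 0.0) * factor

    def set_lengths(self, lengths: dict[int, float]) -> None:
        for v, t in lengths.items():
            self.nodes[v].length = float(t)

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths (unrooted metric on the tree)."""
        # depth from root, then distance via LCA
        depth = {self.root: 0.0}
        for v in self.preorder():
            for c in self.nodes[v].children:
                depth[c] = depth[v] + (self.nodes[c].length or 0.0)
        leaves = self.leaves()
        out = {}
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                anc_a = set()
                x = a
                while x is not None:
                    anc_a.add(x)
                    x = self.nodes[x].parent
                x = b
                while x not in anc_a:
                    x = self.nodes[x].parent
                lca = x
                key = tuple(sorted((self.nodes[a].name, self.nodes[b].name)))
                out[key] = depth[a] + depth[b] - 2 * depth[lca]
        return out

    # -- serialization ------------------------------------------------------

    def to_newick(self, precision: int = 6) -> str:
        def fmt(v: int) -> str:
            n = self.nodes[v]
            if n.children:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")" + n.name
            else:
                s = n.name
            if n.label == 1:
                s += " #1"
            if v != self.root and n.length is not None:
                s += f":{n.length:.{precision}g}"
            return s

        return fmt(self.root) + ";"


_TOKEN = re.compile(r"\s*([(),;:]|#\d+|[^\s(),;:#]+)")


def parse_newick(text: str) -> LabeledTree:
    """Parse Newick with optional branch lengths and PAML '#k' labels.

    Unlabeled branches are background. Internal-node names that look like
    numbers are taken for bootstrap/support values and dropped with a
    warning. Missing branch lengths default to 0.1 with a warning.
    """
    nodes: list[Node] = []
    pos = 0
    n = len(text)

    def error(msg, at):
        raise NewickError(msg, at)

    def skip_ws():
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def peek() -> str:
        skip_ws()
        return text[pos] if pos < n else ""

    def new_node() -> Node:
        node = Node(index=len(nodes))
        nodes.append(node)
        return node

    def read_name() -> str:
        nonlocal pos
        skip_ws()
        m = re.match(r"[^\s(),;:#\[\]]+", text[pos:])
        if not m:
            return ""
        pos += m.end()
        return m.group(0)

    def read_suffix(node: Node, internal: bool):
        """Name, '#k' label, ':length' in any of the usual orders."""
        nonlocal pos
        name = read_name()
        if name:
            if internal and re.fullmatch(r"[0-9.]+([eE][+-]?\d+)?", name):
                warnings.warn(
                    f"ignoring internal-node support value {name!r}",
                    stacklevel=2,
                )
            else:
                node.name = name
        while True:
            c = peek()
            if c == "#":
                m = re.match(r"#(\d+)", text[pos:])
                if not m:
                    error("malformed branch label", pos)
                k = int(m.group(1))
                if k not in (0, 1):
                    error(f"unsupported branch label #{k}", pos)
                node.label = k
                pos += m.end()
            elif c == ":":
                pos += 1
                skip_ws()
                m = re.match(r"[+-]?\d*\.?\d+([eE][+-]?\d+)?", text[pos:])
                if not m:
                    error("expected branch length after ':'", pos)
                node.length = float(m.group(0))
                if node.length < 0:
                    error("negative branch length", pos)
                pos += m.end()
            else:
                break

    def subtree(parent: Node | None) -> Node:
        nonlocal pos
        c = peek()
        node = new_node()
        if parent is not None:
            node.parent = parent.index
        if c == "(":
            pos += 1
            node.children.append(subtree(node).index)
            while peek() == ",":
                pos += 1
                node.children.append(subtree(node).index)
            if peek() != ")":
                error("expected ')' or ','", pos)
            pos += 1
            read_suffix(node, internal=True)
        elif c in (",", ")", ";", ""):
            error("empty subtree", pos)
        else:
            read_suffix(node, internal=False)
            if not node.name:
                error("expected leaf name", pos)
        return node

    root = subtree(None)
    if peek() != ";":
        error("expected ';' at end of tree", pos)
    tree = LabeledTree(nodes, root.index)
    defaulted = []
    for v in tree.branch_nodes():
        if nodes[v].length is None:
            nodes[v].length = DEFAULT_BRANCH_LENGTH
            defaulted.append(v)
    if defaulted:
        warnings.warn(
            f"{len(defaulted)} branch length(s) missing; defaulted to "
            f"{DEFAULT_BRANCH_LENGTH}",
            stacklevel=2,
        )
    names = [nodes[v].name for v in tree.leaves()]
    if len(set(names)) != len(names):
        raise NewickError("duplicate leaf names", 0)
    return tree


def reroot(tree: LabeledTree, edge: int | str) -> LabeledTree:
    """Return a rooted representation with the root moved to the child node
    of the given edge (node index or name).

    The old root, if left with a single child, is suppressed by summing the
    two half-edge lengths; the merged edge is foreground if either half
    was. Total tree length and all leaf-to-leaf path lengths are preserved,
    so any reversible-model likelihood is unchanged.
    """
    t = tree.copy()
    v = t.find(edge) if isinstance(edge, str) else edge
    if v < 0 or v >= len(t.nodes):
        raise KeyError(f"unknown edge/node {edge!r}")
    if v == t.root:
        return t
    nodes = t.nodes
    # path from v up to old root
    path = [v]
    while nodes[path[-1]].parent is not None:
        path.append(nodes[path[-1]].parent)
    # reverse parent/child along the path; edge attributes travel with the
    # edge (stored on the child side before reversal, so capture them first)
    orig = {u: (nodes[u].length, nodes[u].label) for u in path}
    for child, parent in zip(path, path[1:]):
        nodes[parent].children.remove(child)
        nodes[child].children.append(parent)
        nodes[parent].parent = child
        nodes[parent].length, nodes[parent].label = orig[child]
    nodes[v].parent = None
    nodes[v].length = None
    nodes[v].label = 0
    old_root = path[-1]
    if len(nodes[old_root].children) == 1:
        # suppress the degree-2 old root
        only = nodes[old_root].children[0]
        up = nodes[old_root].parent
        nodes[only].length = (nodes[only].length or 0.0) + (
            nodes[old_root].length or 0.0
        )
        nodes[only].label = max(nodes[only].label, nodes[old_root].label)
        nodes[only].parent = up
        nodes[up].children[nodes[up].children.index(old_root)] = only
        nodes[old_root].children = []
        nodes[old_root].parent = None
        # compact: rebuild node list without the suppressed node
        keep = [n for n in nodes if n.index != old_root]
        remap = {n.index: k for k, n in enumerate(keep)}
        for n in keep:
            n.index = remap[n.index]
            n.parent = remap[n.parent] if n.parent is not None else None
            n.children = [remap[c] for c in n.children]
        t = LabeledTree(keep, remap[v])
    else:
        t = LabeledTree(nodes, v)
    return t
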