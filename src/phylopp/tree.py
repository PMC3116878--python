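"""Phylogenetic tree container: Newick I/O, traversal, splits, and the
topology surgery (NNI, SPR) used by the MCMC sampler.

Trees are stored rooted for computation — an unrooted tree is anchored at an
internal trifurcation — with branch lengths in expected substitutions/site on
every non-root node.
"""

from __future__ import annotations

from typing import Iterator

import dendropy
import numpy as np


class Node:
    __slots__ = ("id", "name", "length", "parent", "children", "support")

    def __init__(self, id: int, name: str | None = None, length: float = 0.0):
        self.id = id
        self.name = name
        self.length = length
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id}, {self.name or 'internal'})"


class PhyloTree:
    """Rooted representation of an (optionally unrooted) phylogeny."""

    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    # -- construction --------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=text, schema="newick",
                               preserve_underscores=True,
                               suppress_internal_node_taxa=True)
        counter = [0]

        def convert(dnode) -> Node:
            node = Node(counter[0])
            counter[0] += 1
            if dnode.taxon is not None:
                node.name = dnode.taxon.label
            elif dnode.label not in (None, ""):
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    node.name = dnode.label
            node.length = float(dnode.edge.length or 0.0)
            for ch in dnode.child_nodes():
                c = convert(ch)
                c.parent = node
                node.children.append(c)
            return node

        return cls(convert(dt.seed_node))

    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.8g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.4g}"
            if node.parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.8g}"

        return fmt(self.root) + ";"

    def copy(self) -> "PhyloTree":
        def dup(node: Node) -> Node:
            n = Node(node.id, node.name, node.length)
            n.support = node.support
            for c in node.children:
                d = dup(c)
                d.parent = n
                n.children.append(d)
            return n

        return PhyloTree(dup(self.root))

    # -- bookkeeping ---------------------------------------------------
    def _reindex(self) -> None:
        """Rebuild lookup tables; node ids are stable across topology moves.

        Ids are assigned once (postorder) at construction; surgery that
        replaces a node reuses the old id so external maps keyed by node id
        (the NDCH composition assignment) stay valid.
        """
        self.nodes: list[Node] = list(self.postorder())
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids) or min(ids) < 0:
            for i, n in enumerate(self.nodes):
                n.id = i
        self.leaf_map = {n.name: n for n in self.nodes if n.is_leaf}

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self.leaf_map)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_map)

    def total_length(self) -> float:
        return sum(n.length for n in self.nodes if n.parent is not None)

    # -- splits ---------------------------------------------------------
    def splits(self, nontrivial: bool = True) -> set[frozenset[str]]:
        """Unrooted bipartitions, each canonicalized as the side *not*
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_map)
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node.id] = frozenset([node.name])
            else:
                below[node.id] = frozenset().union(*(below[c.id] for c in node.children))
            if node.parent is None:
                continue
            side = below[node.id]
            if anchor in side:
                side = all_leaves - side
            if nontrivial and (len(side) < 2 or len(side) > len(all_leaves) - 2):
                continue
            out.add(side)
        return out

    # -- topology moves (used by the sampler) ----------------------------
    def internal_edges(self) -> list[Node]:
        """Child nodes of edges whose both endpoints are internal."""
        return [n for n in self.nodes
                if not n.is_leaf and n.parent is not None]

    def nni(self, edge_child: Node, rng: np.random.Generator) -> None:
        """Nearest-neighbour interchange around the edge above *edge_child*.

        Swaps a random child of ``edge_child`` with a random sibling subtree.
        """
        parent = edge_child.parent
        siblings = [c for c in parent.children if c is not edge_child]
        a = siblings[rng.integers(len(siblings))]
        b = edge_child.children[rng.integers(len(edge_child.children))]
        parent.children[parent.children.index(a)] = b
        edge_child.children[edge_child.children.index(b)] = a
        a.parent, b.parent = edge_child, parent
        self._reindex()

    def spr(self, rng: np.random.Generator) -> bool:
        """Subtree prune and regraft; returns False if no legal move exists."""
        candidates = [n for n in self.nodes
                      if n.parent is not None and n.parent.parent is not None]
        if not candidates:
            return False
        sub = candidates[rng.integers(len(candidates))]
        parent = sub.parent
        grand = parent.parent
        # prune: splice parent out of the tree
        sibs = [c for c in parent.children if c is not sub]
        grand.children[grand.children.index(parent)] = sibs[0] if len(sibs) == 1 else parent
        if len(sibs) == 1:
            sibs[0].parent = grand
            sibs[0].length += parent.length
        else:  # multifurcation: just detach sub
            parent.children.remove(sub)
        # choose a regraft edge outside the pruned subtree
        banned = set()
        stack = [sub]
        while stack:
            n = stack.pop()
            banned.add(id(n))
            stack.extend(n.children)
        targets = [n for n in self.nodes
                   if n.parent is not None and id(n) not in banned
                   and id(n) != id(parent)]
        targets = [t for t in targets if _still_attached(t, self.root)]
        if not targets:
            return False
        tgt = targets[rng.integers(len(targets))]
        # reuse the spliced-out parent's id so node-id keyed maps stay valid
        new_id = parent.id if len(sibs) == 1 else max(n.id for n in self.nodes) + 1
        new_parent = Node(new_id, length=tgt.length / 2)
        tgt.length /= 2
        up = tgt.parent
        up.children[up.children.index(tgt)] = new_parent
        new_parent.parent = up
        new_parent.children = [tgt, sub]
        tgt.parent = new_parent
        sub.parent = new_parent
        self._reindex()
        return True


def _still_attached(node: Node, root: Node) -> bool:
    while node.parent is not None:
        node = node.parent
    return node is root


def write_nexus_trees(trees: list["PhyloTree"], path) -> None:
    """Write a list of trees as a Nexus trees block (via dendropy)."""
    tl = dendropy.TreeList()
    for i, t in enumerate(trees):
        dt = dendropy.Tree.get(data=t.to_newick(), schema="newick",
                               taxon_namespace=tl.taxon_namespace,
                               preserve_underscores=True)
        dt.label = f"tree_{i}"
        tl.append(dt)
    tl.write(path=str(path), schema="nexus", unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def balanced_tree(n_taxa: int, branch_length: float = 0.1,
                  prefix: str = "t") -> PhyloTree:
    """A balanced unrooted topology on n_taxa leaves with equal branch lengths."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa for an unrooted tree")
    leaves = [Node(0, f"{prefix}{i+1}", branch_length) for i in range(n_taxa)]
    level = leaves
    while len(level) > 3:
        nxt = []
        for i in range(0, len(level) - 1, 2):
            p = Node(0, length=branch_length)
            p.children = [level[i], level[i + 1]]
            level[i].parent = p
            level[i + 1].parent = p
            nxt.append(p)
        if len(level) % 2:
            nxt.append(level[-1])
        level = nxt
    root = Node(0)
    root.children = list(level)
    for c in level:
        c.parent = root
    return PhyloTree(root)


def random_topology(taxa: list[str], rng: np.random.Generator,
                    branch_length_mean: float = 0.1) -> PhyloTree:
    """Random unrooted topology by sequential joining, exponential lengths."""
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    def bl() -> float:
        return float(rng.exponential(branch_length_mean))
    nodes = [Node(0, t, bl()) for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        p = Node(0, length=bl())
        p.children = [nodes[i], nodes[j]]
        nodes[i].parent = p
        nodes[j].parent = p
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [p]
    root = Node(0)
    root.children = nodes
    for c in nodes:
        c.parent = root
    return PhyloTree(root)


def quartet_tree(short: float, long: float, internal: float,
                 outgroup_length: float | None = None) -> PhyloTree:
    """The LBA test topology ((A,C),(B,D),O): true split AB|CD with the two
    *non-sister* leaves A and C on long branches.

    Leaves A,B sister and C,D sister; A and C carry the long branches so a
    method misled by convergence groups A with C (split AC|BD).
    """
    text = (f"((A:{long},B:{short}):{internal},"
            f"(C:{long},D:{short}):{internal},"
            f"O:{outgroup_length if outgroup_length is not None else short * 2});")
    return PhyloTree.from_newick(text)
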