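"""Rooted, dated (ultrametric) phylogenies.

A :class:`DatedTree` is a minimal array-of-nodes container: integer node
ids, parent/child links, branch lengths in Myr, and node ages (time before
present, so tips sit at age 0 and the root at the tree depth).  It is the
common currency between the synthetic generator, Newick I/O, and the
ancestral-state machinery; heavier tree libraries are only used at the
file boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import FormatError, InvalidInputError

ULTRAMETRIC_TOL = 1e-6


@dataclass
class TreeNode:
    id: int
    label: str | None = None
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    length: float = 0.0  # branch length to parent, Myr
    age: float = 0.0  # time before present, Myr


class DatedTree:
    """Rooted binary tree with node ages.

    Node ids are stable integers (indices into ``self.nodes``); traversal
    orders are deterministic (children kept in insertion order).
    """

    def __init__(self, nodes: list[TreeNode], root: int):
        self.nodes = nodes
        self.root = root

    # -- construction ------------------------------------------------

    @classmethod
    def from_parent_table(
        cls,
        parents: dict[int, int | None],
        lengths: dict[int, float],
        labels: dict[int, str],
    ) -> "DatedTree":
        n = max(parents) + 1
        nodes = [TreeNode(i) for i in range(n)]
        root = None
        for i in sorted(parents):
            nodes[i].parent = parents[i]
            nodes[i].length = lengths.get(i, 0.0)
            nodes[i].label = labels.get(i)
            if parents[i] is None:
                root = i
            else:
                nodes[parents[i]].children.append(i)
        if root is None:
            raise InvalidInputError("no root in parent table")
        tree = cls(nodes, root)
        tree.assign_ages()
        return tree

    # -- traversal ---------------------------------------------------

    def postorder(self) -> list[int]:
        out: list[int] = []
        stack = [(self.root, False)]
        while stack:
            nid, done = stack.pop()
            if done:
                out.append(nid)
            else:
                stack.append((nid, True))
                for c in reversed(self.nodes[nid].children):
                    stack.append((c, False))
        return out

    def preorder(self) -> list[int]:
        out: list[int] = []
        stack = [self.root]
        while stack:
            nid = stack.pop()
            out.append(nid)
            for c in reversed(self.nodes[nid].children):
                stack.append(c)
        return out

    def tips(self) -> list[int]:
        return [i for i in self.postorder() if not self.nodes[i].children]

    def internal_ids(self) -> list[int]:
        """Internal node ids in stable postorder."""
        return [i for i in self.postorder() if self.nodes[i].children]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def tip_labels(self) -> list[str]:
        return [self.nodes[i].label or f"t{i}" for i in self.tips()]

    def tip_id(self, label: str) -> int:
        for i in self.tips():
            if self.nodes[i].label == label:
                return i
        raise MismatchFromLabel(label)

    def parent_of(self, nid: int) -> int | None:
        return self.nodes[nid].parent

    def sibling_of(self, nid: int) -> int | None:
        p = self.nodes[nid].parent
        if p is None:
            return None
        sibs = [c for c in self.nodes[p].children if c != nid]
        return sibs[0] if sibs else None

    # -- ages --------------------------------------------------------

    def assign_ages(self) -> None:
        """Derive node ages from branch lengths assuming ultrametry.

        Root-to-node distances are computed from lengths; age = depth -
        distance.  If the tree is non-ultrametric beyond tolerance, a
        warning is issued and depth is taken as the maximum root-to-tip
        path (so tips may have small nonzero ages).
        """
        dist = {self.root: 0.0}
        for nid in self.preorder():
            if nid == self.root:
                continue
            dist[nid] = dist[self.nodes[nid].parent] + self.nodes[nid].length
        tip_d = [dist[i] for i in self.tips()]
        depth = max(tip_d)
        if max(tip_d) - min(tip_d) > ULTRAMETRIC_TOL * max(depth, 1.0):
            warnings.warn(
                "tree is not ultrametric; ages derived from the maximum "
                "root-to-tip path",
                stacklevel=2,
            )
        for nid, d in dist.items():
            self.nodes[nid].age = depth - d

    @property
    def depth(self) -> float:
        return self.nodes[self.root].age

    def root_to_tip_variance(self) -> float:
        import numpy as np

        dist = {self.root: 0.0}
        for nid in self.preorder():
            if nid == self.root:
                continue
            dist[nid] = dist[self.nodes[nid].parent] + self.nodes[nid].length
        return float(np.var([dist[i] for i in self.tips()]))

    # -- Newick ------------------------------------------------------

    def to_newick(self, label_internal: bool = False) -> str:
        def rec(nid: int) -> str:
            node = self.nodes[nid]
            if node.children:
                inner = ",".join(rec(c) for c in node.children)
                lab = node.label or (f"n{nid}" if label_internal else "")
                s = f"({inner}){lab}"
            else:
                s = node.label or f"t{nid}"
            if node.parent is not None:
                s += f":{float(node.length)!r}"
            return s

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        import dendropy

        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # dendropy raises several parse errors
            raise FormatError(f"cannot parse Newick: {exc}") from exc
        nodes: list[TreeNode] = []
        index: dict[object, int] = {}
        for dnode in dtree.preorder_node_iter():
            nid = len(nodes)
            index[dnode] = nid
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if dnode.is_leaf() and not label:
                raise FormatError("unlabeled tip in Newick tree")
            parent = index[dnode.parent_node] if dnode.parent_node else None
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            if parent is None:
                length = 0.0
            elif dnode.edge.length is None:
                raise FormatError("missing branch length in Newick tree")
            node = TreeNode(nid, label=label, parent=parent, length=float(length))
            nodes.append(node)
            if parent is not None:
                nodes[parent].children.append(nid)
        tree = cls(nodes, 0)
        tree.assign_ages()
        return tree


class MismatchFromLabel(InvalidInputError):
    def __init__(self, label: str):
        super().__init__(f"no tip labeled {label!r}")
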