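"""Dated ultrametric trees as flat node arrays.

The package's universal substrate is the rooted, binary, time-calibrated
tree of extant taxa.  Node ages (time before present) are the primary
coordinates; branch lengths are derived as ``age[parent] - age[child]``,
which keeps every tree exactly ultrametric under manipulation.  A light
mutable :class:`Node` form is used while building or editing trees
(simulation, pruning, grafting); the frozen :class:`DatedTree` form backs
all likelihood computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["Node", "DatedTree", "TreeError", "ULTRAMETRIC_RTOL"]

#: relative tolerance on root-to-tip path spread for a tree to count as dated
ULTRAMETRIC_RTOL = 1e-9


class TreeError(ValueError):
    """Raised for structurally invalid trees (polytomy, non-ultrametric, ...)."""


@dataclass
class Node:
    """Mutable tree node used during construction and editing."""

    length: float = 0.0  # stem branch length (0.0 for the root)
    label: str | None = None
    children: list["Node"] = field(default_factory=list)

    def is_tip(self) -> bool:
        return not self.children

    def walk_postorder(self) -> Iterator["Node"]:
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_tip():
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def copy(self) -> "Node":
        return Node(
            self.length, self.label, [c.copy() for c in self.children]
        )


class DatedTree:
    """Rooted binary ultrametric tree with node ages in time units.

    Nodes are integer ids ``0 .. n_nodes-1``; tips occupy ``0 .. n_tips-1``
    in the order they appear left-to-right in the source tree, internal
    nodes follow in postorder with the root last.

    Attributes
    ----------
    parent : array of int
        Parent id per node; ``-1`` for the root.
    left, right : arrays of int
        Child ids per node; ``-1`` for tips.
    age : array of float
        Node age (time before present); exactly ``0.0`` at tips.
    labels : list of str or None
        Tip labels are mandatory and unique; internal labels optional
        (the simulator marks the grafted crown node ``SHIFT``).
    """

    def __init__(
        self,
        parent: np.ndarray,
        left: np.ndarray,
        right: np.ndarray,
        age: np.ndarray,
        labels: list[str | None],
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.age = np.asarray(age, dtype=np.float64)
        self.labels = list(labels)
        n = self.parent.size
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.n_nodes = n
        self.is_tip = self.left < 0
        self.n_tips = int(self.is_tip.sum())
        self._validate()
        # internal nodes in postorder (children before parents), root last
        self.postorder_internal = self._postorder_internal()

    # -- construction -------------------------------------------------

    @classmethod
    def from_node(cls, root: Node) -> "DatedTree":
        """Freeze a mutable :class:`Node` tree (root stem length ignored)."""
        order: list[Node] = list(root.walk_postorder())
        for nd in order:
            if nd.children and len(nd.children) != 2:
                raise TreeError(
                    f"polytomy or unary node with {len(nd.children)} children"
                )
        tips = [nd for nd in order if nd.is_tip()]
        internals = [nd for nd in order if not nd.is_tip()]
        index: dict[int, int] = {}
        for i, nd in enumerate(tips + internals):
            index[id(nd)] = i
        n = len(order)
        parent = np.full(n, -1, dtype=np.int64)
        left = np.full(n, -1, dtype=np.int64)
        right = np.full(n, -1, dtype=np.int64)
        depth = np.zeros(n, dtype=np.float64)
        labels: list[str | None] = [None] * n
        # depths by preorder
        stack = [(root, 0.0)]
        while stack:
            nd, d = stack.pop()
            i = index[id(nd)]
            labels[i] = nd.label
            depth[i] = d
            if nd.children:
                l, r = nd.children
                left[i], right[i] = index[id(l)], index[id(r)]
                parent[index[id(l)]] = i
                parent[index[id(r)]] = i
                stack.append((l, d + l.length))
                stack.append((r, d + r.length))
        tip_mask = left < 0
        tip_depths = depth[tip_mask]
        crown = float(tip_depths.max())
        if crown <= 0:
            raise TreeError("tree has zero depth")
        spread = float(tip_depths.max() - tip_depths.min())
        if spread > ULTRAMETRIC_RTOL * crown:
            raise TreeError(
                f"non-ultrametric tree: root-to-tip spread {spread:g} "
                f"exceeds {ULTRAMETRIC_RTOL:g} x crown age {crown:g}"
            )
        age = crown - depth
        age[tip_mask] = 0.0
        return cls(parent, left, right, age, labels)

    def to_node(self) -> tuple[Node, dict[int, Node]]:
        """Thaw to a mutable Node tree; also return the id -> Node map."""
        nodes = {i: Node(length=self.branch_length(i), label=self.labels[i])
                 for i in range(self.n_nodes)}
        for i in range(self.n_nodes):
            if self.left[i] >= 0:
                nodes[i].children = [nodes[int(self.left[i])],
                                     nodes[int(self.right[i])]]
        return nodes[self.root], nodes

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        if self.n_nodes != 2 * self.n_tips - 1:
            raise TreeError("tree is not strictly binary")
        bl = self.branch_lengths()
        bl = np.delete(bl, self.root)
        if np.any(bl <= 0):
            raise TreeError("all branch lengths must be positive")
        tip_labels = [self.labels[i] for i in range(self.n_nodes) if self.is_tip[i]]
        if any(lab is None for lab in tip_labels):
            raise TreeError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            raise TreeError("tip labels must be unique")

    def _postorder_internal(self) -> np.ndarray:
        out: list[int] = []
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            i, expanded = stack.pop()
            if self.is_tip[i]:
                continue
            if expanded:
                out.append(i)
            else:
                stack.append((i, True))
                stack.append((int(self.left[i]), False))
                stack.append((int(self.right[i]), False))
        return np.asarray(out, dtype=np.int64)

    # -- queries ------------------------------------------------------

    @property
    def crown_age(self) -> float:
        return float(self.age[self.root])

    def branch_length(self, i: int) -> float:
        p = int(self.parent[i])
        return 0.0 if p < 0 else float(self.age[p] - self.age[i])

    def branch_lengths(self) -> np.ndarray:
        bl = self.age[self.parent] - self.age
        bl[self.root] = 0.0
        return bl

    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in range(self.n_nodes) if self.is_tip[i]]

    def tip_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    def internal_ids(self, include_root: bool = True) -> np.ndarray:
        ids = np.flatnonzero(~self.is_tip)
        if not include_root:
            ids = ids[ids != self.root]
        return ids

    def find_by_label(self, label: str) -> int:
        for i, lab in enumerate(self.labels):
            if lab == label:
                return i
        raise KeyError(f"no node labelled {label!r}")

    def clade_mask(self, node: int) -> np.ndarray:
        """Boolean mask over node ids: node itself and all descendants."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        stack = [int(node)]
        while stack:
            i = stack.pop()
            mask[i] = True
            if not self.is_tip[i]:
                stack.append(int(self.left[i]))
                stack.append(int(self.right[i]))
        return mask

    def clade_tips(self, node: int) -> list[str]:
        mask = self.clade_mask(node)
        return [self.labels[i] for i in np.flatnonzero(mask & self.is_tip)]

    def branching_ages(self) -> np.ndarray:
        """Internal node ages, sorted descending (crown age first)."""
        ages = self.age[~self.is_tip]
        return np.sort(ages)[::-1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<DatedTree {self.n_tips} tips, crown age "
                f"{self.crown_age:.4g}>")
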