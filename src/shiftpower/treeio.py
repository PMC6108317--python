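"""Readers and writers: Newick trees, tip-state tables, run configuration.

Newick dialect: branch lengths mandatory, optional plain-string internal
labels (the simulator writes ``SHIFT`` on the grafted crown node), no NHX.
Written trees use canonical child order (lexicographic by smallest
subtended tip label) and fixed 12-decimal branch lengths, so identical
trees serialize byte-identically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import yaml

from .trees import DatedTree, Node, TreeError

__all__ = [
    "read_newick",
    "write_newick",
    "newick_string",
    "read_states",
    "write_states",
    "RunConfig",
]


def _node_from_dendropy(dnode) -> Node:
    children = [_node_from_dendropy(c) for c in dnode.child_nodes()]
    if len(children) not in (0, 2):
        raise TreeError(f"polytomy: node with {len(children)} children")
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    length = dnode.edge.length
    if length is None:
        if dnode.parent_node is None:
            length = 0.0
        else:
            raise TreeError("missing branch length")
    if length < 0:
        raise TreeError("negative branch length")
    return Node(length=float(length), label=label, children=children)


def read_newick(source: str | Path) -> DatedTree:
    """Parse one Newick tree (path or literal string) into a DatedTree.

    Rejects polytomies, missing branch lengths and non-ultrametric trees.
    """
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as err:
        # normalize parser-level failures (duplicate taxa, malformed
        # statements) to the package's tree error type
        if "uplicate" in str(err):
            raise TreeError(f"tip labels must be unique: {err}") from err
        raise TreeError(f"newick parse error: {err}") from err
    root = _node_from_dendropy(dtree.seed_node)
    return DatedTree.from_node(root)


def _min_tip_label(tree: DatedTree) -> list[str]:
    """Smallest subtended tip label per node (canonical sort key)."""
    key: list[str] = [""] * tree.n_nodes
    for i in tree.tip_ids():
        key[int(i)] = tree.labels[int(i)]
    for i in tree.postorder_internal:
        key[int(i)] = min(key[int(tree.left[i])], key[int(tree.right[i])])
    return key


def newick_string(tree: DatedTree, precision: int = 12) -> str:
    """Canonical Newick serialization (sorted children, fixed precision)."""
    key = _min_tip_label(tree)
    fmt = f":%.{precision}f"

    buf = io.StringIO()
    # iterative to cope with ladder trees
    stack: list[tuple[int, int]] = [(tree.root, 0)]
    while stack:
        i, phase = stack.pop()
        children = []
        if not tree.is_tip[i]:
            children = sorted(
                (int(tree.left[i]), int(tree.right[i])), key=lambda c: key[c]
            )
        if phase == 0:
            if tree.is_tip[i]:
                buf.write(tree.labels[i])
                if tree.parent[i] >= 0:
                    buf.write(fmt % tree.branch_length(i))
            else:
                buf.write("(")
                stack.append((i, 1))
                stack.append((children[1], 2))  # marker: write comma before
                stack.append((children[0], 0))
        elif phase == 1:
            buf.write(")")
            if tree.labels[i]:
                buf.write(tree.labels[i])
            if tree.parent[i] >= 0:
                buf.write(fmt % tree.branch_length(i))
        else:  # phase == 2: second child, prefix a comma
            buf.write(",")
            stack.append((i, 0))
    buf.write(";")
    return buf.getvalue()


def write_newick(tree: DatedTree, path: str | Path, precision: int = 12) -> None:
    Path(path).write_text(newick_string(tree, precision) + "\n")


def read_states(path: str | Path, header: bool = False) -> dict[str, int]:
    """Read a two-column ``tip<TAB>state`` table with binary states."""
    states: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh):
            if header and ln == 0:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {ln + 1}: expected 2 tab-separated fields")
            tip, raw = parts
            if tip in states:
                raise ValueError(f"duplicate tip {tip!r}")
            if raw not in ("0", "1"):
                raise ValueError(f"tip {tip!r}: state must be 0 or 1, got {raw!r}")
            states[tip] = int(raw)
    return states


def write_states(states: dict[str, int], path: str | Path,
                 header: bool = False) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("tip_id\tstate\n")
        for tip in states:
            fh.write(f"{tip}\t{states[tip]}\n")


def check_states_against_tree(tree: DatedTree, states: dict[str, int]) -> None:
    """Every tip must have a state and vice versa."""
    tips = set(tree.tip_labels())
    missing = tips - states.keys()
    if missing:
        raise ValueError(f"missing state for tips: {sorted(missing)[:5]}")
    extra = states.keys() - tips
    if extra:
        raise ValueError(f"states for unknown tips: {sorted(extra)[:5]}")


@dataclass
class RunConfig:
    """Experiment configuration; round-trips losslessly through YAML/JSON."""

    set_id: int = 1
    size_classes: list = field(default_factory=lambda: [[100, 10]])
    asymmetries: list = field(default_factory=lambda: [3.5])
    rel_ages: list = field(default_factory=lambda: [40.0])
    tip_ratios: list = field(default_factory=list)
    replicates: int = 20
    base_seed: int = 1
    methods: list = field(default_factory=lambda: ["bisse"])
    approaches: list = field(default_factory=lambda: [1])
    n_restarts: int = 3
    out_dir: str = "."
    log_level: str = "INFO"

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
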