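"""Label taxonomy: the rooted tree over hierarchical (EC-style) class labels.

A dotted label such as ``"1.6.5"`` names a leaf; every proper prefix
(``"1"``, ``"1.6"``) is an internal node.  The tree supplies, for each leaf y,
the set path(y) of nodes on the root-to-leaf path (root excluded) and the
binary attribute vector Lambda(y) over all s non-root nodes that indicates
that path.  Inner products of attribute vectors count shared path nodes, which
is what lets a structured SVM score decompose along the hierarchy.

Node numbering is deterministic: leaves get ids 1..q in lexicographic label
order, internal nodes get q+1..s in lexicographic prefix order.  The root is
excluded from numbering and from attribute vectors.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LabelTree",
    "build_tree_from_labels",
    "path",
    "attribute_vector",
    "label_inner_product",
    "project_to_level",
    "filter_min_class_size",
    "glass_tree",
]

_LABEL_RE = re.compile(r"^\d+(\.\d+)*$")

ROOT = 0  # sentinel id for the (unnumbered) root


def _label_key(label: str) -> tuple[str, ...]:
    return tuple(label.split("."))


def _validate_label(label: str) -> None:
    if not isinstance(label, str) or not _LABEL_RE.match(label):
        raise ValueError(f"malformed hierarchical label: {label!r}")


@dataclass(frozen=True)
class LabelTree:
    """Rooted taxonomy over q leaf labels and s total non-root nodes.

    ``parent`` maps every node id (1..s) to its parent id, with 0 standing for
    the root.  ``node_names`` maps each node id to its dotted prefix string;
    ``leaves`` lists leaf ids in increasing order (1..q).
    """

    parent: dict[int, int]
    node_names: dict[int, str]
    leaves: tuple[int, ...]
    depth: dict[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        depths: dict[int, int] = {}

        def d(node: int) -> int:
            if node == ROOT:
                return 0
            if node not in depths:
                depths[node] = d(self.parent[node]) + 1
            return depths[node]

        for node in self.parent:
            d(node)
        object.__setattr__(self, "depth", depths)
        names = [self.node_names[leaf] for leaf in self.leaves]
        if len(set(names)) != len(names):
            raise ValueError("leaf labels must be unique")
        if len(self.leaves) < 2:
            raise ValueError("a label tree needs at least 2 leaves")

    @property
    def q(self) -> int:
        """Number of leaf labels."""
        return len(self.leaves)

    @property
    def s(self) -> int:
        """Total number of non-root nodes."""
        return len(self.parent)

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(self.node_names[leaf] for leaf in self.leaves)

    def leaf_id(self, label: str) -> int:
        try:
            return self._name_to_leaf[label]
        except KeyError:
            raise KeyError(f"unknown leaf label: {label!r}") from None

    @property
    def _name_to_leaf(self) -> dict[str, int]:
        return {self.node_names[leaf]: leaf for leaf in self.leaves}

    def children(self, node: int) -> list[int]:
        return sorted(n for n, p in self.parent.items() if p == node)

    def sibling_leaves(self, leaf: int) -> list[int]:
        """Leaf children of this leaf's parent, excluding the leaf itself."""
        leaf_set = set(self.leaves)
        return [
            n for n in self.children(self.parent[leaf]) if n in leaf_set and n != leaf
        ]

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"id": n, "name": self.node_names[n], "parent": self.parent[n]}
                for n in sorted(self.parent)
            ],
            "leaves": list(self.leaves),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LabelTree":
        parent = {int(n["id"]): int(n["parent"]) for n in data["nodes"]}
        names = {int(n["id"]): str(n["name"]) for n in data["nodes"]}
        return cls(parent=parent, node_names=names, leaves=tuple(data["leaves"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelTree":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_tree_from_labels(labels: list[str]) -> LabelTree:
    """Build the taxonomy implied by a collection of dotted leaf labels.

    One node per distinct prefix; single-child chains are kept as distinct
    nodes so every EC prefix maps 1:1 to a node.  A label that is also a
    proper prefix of another label is rejected (a leaf cannot be internal).
    """
    if not labels:
        raise ValueError("no labels given")
    for lab in labels:
        _validate_label(lab)
    leaf_labels = sorted(set(labels), key=_label_key)
    internal: set[str] = set()
    for lab in leaf_labels:
        parts = lab.split(".")
        for k in range(1, len(parts)):
            internal.add(".".join(parts[:k]))
    clash = internal & set(leaf_labels)
    if clash:
        raise ValueError(f"label(s) {sorted(clash)} are both leaves and prefixes")
    ordered_internal = sorted(internal, key=_label_key)

    name_to_id: dict[str, int] = {}
    for i, lab in enumerate(leaf_labels, start=1):
        name_to_id[lab] = i
    q = len(leaf_labels)
    for j, pref in enumerate(ordered_internal, start=q + 1):
        name_to_id[pref] = j

    parent: dict[int, int] = {}
    for name, nid in name_to_id.items():
        parts = name.split(".")
        parent[nid] = ROOT if len(parts) == 1 else name_to_id[".".join(parts[:-1])]

    node_names = {nid: name for name, nid in name_to_id.items()}
    return LabelTree(
        parent=parent, node_names=node_names, leaves=tuple(range(1, q + 1))
    )


def path(tree: LabelTree, leaf: int | str) -> list[int]:
    """Node ids on the root-to-leaf path, root excluded, leaf last."""
    node = tree.leaf_id(leaf) if isinstance(leaf, str) else leaf
    if node not in set(tree.leaves):
        raise KeyError(f"node {node} is not a leaf")
    out: list[int] = []
    while node != ROOT:
        out.append(node)
        node = tree.parent[node]
    return out[::-1]


def attribute_vector(tree: LabelTree, leaf: int | str) -> np.ndarray:
    """Binary indicator Lambda(y) of path(y) over nodes 1..s."""
    vec = np.zeros(tree.s, dtype=float)
    for node in path(tree, leaf):
        vec[node - 1] = 1.0
    return vec


def label_inner_product(tree: LabelTree, y: int | str, y2: int | str) -> int:
    """Lambda(y) . Lambda(y2) = number of shared path nodes = depth of the
    deepest common ancestor (root counts as depth 0)."""
    return len(set(path(tree, y)) & set(path(tree, y2)))


def project_to_level(tree: LabelTree, leaf: int | str, level: int) -> str:
    """Dotted prefix of the leaf's label at the given 1-based hierarchy level."""
    name = leaf if isinstance(leaf, str) else tree.node_names[leaf]
    _validate_label(name)
    parts = name.split(".")
    if not 1 <= level <= len(parts):
        raise ValueError(
            f"level {level} invalid for label {name!r} of depth {len(parts)}"
        )
    return ".".join(parts[:level])


def filter_min_class_size(
    labels: list[str], min_count: int
) -> tuple[np.ndarray, dict[str, int]]:
    """Drop all samples whose leaf class has fewer than ``min_count`` members.

    Returns (boolean keep-mask aligned with ``labels``, removal report mapping
    each removed class to its size).  Mirrors the standard practice of
    excluding sub-subfamilies with too few proteins to avoid extreme class
    bias; the threshold is strict ("fewer than").
    """
    labels = list(labels)
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    removed = {lab: n for lab, n in counts.items() if n < min_count}
    keep = np.array([lab not in removed for lab in labels], dtype=bool)
    kept_classes = {lab for lab in labels if lab not in removed}
    if len(kept_classes) < 2:
        raise ValueError(
            f"min_count={min_count} leaves {len(kept_classes)} class(es); need >= 2"
        )
    return keep, removed


def glass_tree() -> LabelTree:
    """The two-family / three-leaf tree of the classic glass toy problem:
    one singleton family ("1.1", non-window) and a sibling pair ("2.1", "2.2",
    window glass).  Leaf ids 1..3, internal nodes 4 ("1") and 5 ("2")."""
    return build_tree_from_labels(["1.1", "2.1", "2.2"])
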