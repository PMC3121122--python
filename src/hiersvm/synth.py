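"""Synthetic benchmarks with planted hierarchical structure.

Real enzyme data has two features the hierarchical model exploits: sibling
sub-subfamilies share sequence signal with their common subfamily, and class
sizes are strongly imbalanced.  Both generators plant exactly that structure.

* ``generate_sequences`` assigns each non-root tree node a private set of
  conjoint-triad motifs (class triples drawn without replacement, so signal is
  identifiable).  A leaf's sequences are built from 3-residue blocks: with
  probability ``motif_rate`` a block realises a motif of a node on the leaf's
  root path (siblings therefore share their subfamily motifs and differ only
  in leaf motifs); otherwise the block is uniform background.  Point
  substitutions are applied at ``noise_rate`` per residue.

* ``generate_vectors`` is the numeric-feature analogue: Gaussian leaf
  clusters whose centers decompose along the tree, with the leaf-level offset
  smaller than the family-level offset, so sibling clusters sit closer
  together than non-sibling clusters.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ctf import AMBIGUITY_RESIDUES, AMINO_CLASSES, STANDARD_RESIDUES, ProteinRecord
from .hierarchy import LabelTree, build_tree_from_labels, glass_tree, path

__all__ = [
    "SynthSpec",
    "generate_sequences",
    "generate_vectors",
    "split_by_leaf",
    "glass_shape_spec",
    "GLASS_TRAIN_COUNTS",
    "GLASS_TEST_COUNTS",
    "sibling_overlap_spec",
    "SIBLING_OVERLAP_TRAIN_COUNTS",
]


@dataclass
class SynthSpec:
    """Conditions for one synthetic dataset.

    ``n_per_leaf`` maps dotted leaf labels to sample counts (imbalance is
    expressed here).  Sequence-mode knobs: ``seq_length`` (residues),
    ``motif_rate`` (fraction of 3-residue blocks carrying a planted triad),
    ``noise_rate`` (per-residue substitution probability),
    ``motifs_per_node`` and ``ambiguity_rate`` (rate of non-standard codes,
    off by default).  Vector-mode knobs: ``feature_dim``, ``family_separation``
    and ``sibling_separation`` (center offsets per internal/leaf node) and
    ``noise_std`` (within-cluster standard deviation).
    """

    n_per_leaf: dict[str, int]
    seed: int = 0
    # sequence mode
    seq_length: int = 120
    motif_rate: float = 0.3
    noise_rate: float = 0.05
    motifs_per_node: int = 2
    ambiguity_rate: float = 0.0
    # vector mode
    feature_dim: int = 5
    family_separation: float = 6.0
    sibling_separation: float = 1.5
    noise_std: float = 1.0
    tree: LabelTree | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.n_per_leaf:
            raise ValueError("n_per_leaf must be non-empty")
        if any(n < 1 for n in self.n_per_leaf.values()):
            raise ValueError("per-leaf counts must be >= 1")
        for rate in (self.motif_rate, self.noise_rate, self.ambiguity_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.seq_length < 3:
            raise ValueError("seq_length must be >= 3")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")

    def resolve_tree(self) -> LabelTree:
        tree = self.tree or build_tree_from_labels(sorted(self.n_per_leaf))
        missing = set(self.n_per_leaf) - set(tree.leaf_names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} are not leaves of the tree")
        return tree


def _plant_motifs(
    tree: LabelTree, per_node: int, rng: np.random.Generator
) -> dict[int, list[tuple[int, int, int]]]:
    """Assign each non-root node ``per_node`` distinct class triads, without
    replacement across nodes so every node's signal is identifiable."""
    nodes = sorted(tree.parent)
    need = per_node * len(nodes)
    if need > 343:
        raise ValueError("tree too large for disjoint triad motifs")
    chosen = rng.choice(343, size=need, replace=False)
    triads = [(int(t) // 49 + 1, (int(t) // 7) % 7 + 1, int(t) % 7 + 1) for t in chosen]
    return {
        node: triads[k * per_node : (k + 1) * per_node]
        for k, node in enumerate(nodes)
    }


def _triad_to_residues(
    triad: tuple[int, int, int], rng: np.random.Generator
) -> str:
    return "".join(
        AMINO_CLASSES[c - 1][rng.integers(len(AMINO_CLASSES[c - 1]))] for c in triad
    )


def generate_sequences(
    spec: SynthSpec,
) -> tuple[list[ProteinRecord], list[str], LabelTree]:
    """Generate FASTA-ready records with hierarchical triad signal.

    Returns (records, leaf labels aligned with records, the label tree).
    """
    tree = spec.resolve_tree()
    rng = np.random.default_rng(spec.seed)
    motifs = _plant_motifs(tree, spec.motifs_per_node, rng)
    n_blocks = -(-spec.seq_length // 3)  # ceil
    records: list[ProteinRecord] = []
    labels: list[str] = []
    idx = 0
    for leaf_name in sorted(spec.n_per_leaf):
        node_path = path(tree, leaf_name)
        for _ in range(spec.n_per_leaf[leaf_name]):
            blocks: list[str] = []
            for _ in range(n_blocks):
                if rng.random() < spec.motif_rate:
                    node = node_path[rng.integers(len(node_path))]
                    triad = motifs[node][rng.integers(len(motifs[node]))]
                    blocks.append(_triad_to_residues(triad, rng))
                else:
                    blocks.append(
                        "".join(
                            STANDARD_RESIDUES[j]
                            for j in rng.integers(20, size=3)
                        )
                    )
            seq = list("".join(blocks)[: spec.seq_length])
            for pos in range(len(seq)):
                if spec.noise_rate and rng.random() < spec.noise_rate:
                    seq[pos] = STANDARD_RESIDUES[rng.integers(20)]
                if spec.ambiguity_rate and rng.random() < spec.ambiguity_rate:
                    seq[pos] = AMBIGUITY_RESIDUES[
                        rng.integers(len(AMBIGUITY_RESIDUES))
                    ]
            idx += 1
            records.append(ProteinRecord(id=f"S{idx:05d}", sequence="".join(seq)))
            labels.append(leaf_name)
    return records, labels, tree


def generate_vectors(
    spec: SynthSpec,
) -> tuple[np.ndarray, list[str], LabelTree]:
    """Gaussian leaf clusters whose centers decompose along the tree.

    Each node gets a random unit direction; a leaf's center is the sum over
    its root path of direction * separation, where internal nodes use
    ``family_separation`` and leaves use ``sibling_separation``.  Sibling
    centers therefore differ only by leaf offsets and sit closer together
    than non-siblings.
    """
    tree = spec.resolve_tree()
    rng = np.random.default_rng(spec.seed)
    leaf_set = set(tree.leaves)
    directions: dict[int, np.ndarray] = {}
    for node in sorted(tree.parent):
        v = rng.normal(size=spec.feature_dim)
        directions[node] = v / np.linalg.norm(v)
    X_rows: list[np.ndarray] = []
    labels: list[str] = []
    for leaf_name in sorted(spec.n_per_leaf):
        center = np.zeros(spec.feature_dim)
        for node in path(tree, leaf_name):
            sep = spec.sibling_separation if node in leaf_set else spec.family_separation
            center = center + sep * directions[node]
        n = spec.n_per_leaf[leaf_name]
        X_rows.append(center + spec.noise_std * rng.normal(size=(n, spec.feature_dim)))
        labels.extend([leaf_name] * n)
    return np.vstack(X_rows), labels, tree


def split_by_leaf(
    labels: list[str], n_train_per_leaf: dict[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-leaf train/test split of one generated dataset.

    The first ``n_train_per_leaf[leaf]`` samples of each leaf (generation
    order; samples are i.i.d. within a leaf) go to training, the remainder to
    test.  Splitting one dataset — rather than generating a second one —
    keeps the test set drawn from the same planted structure.
    Returns (train index array, test index array).
    """
    train_idx: list[int] = []
    test_idx: list[int] = []
    seen: dict[str, int] = {}
    for i, lab in enumerate(labels):
        k = seen.get(lab, 0)
        seen[lab] = k + 1
        want = n_train_per_leaf.get(lab, 0)
        (train_idx if k < want else test_idx).append(i)
    for lab, want in n_train_per_leaf.items():
        if seen.get(lab, 0) < want:
            raise ValueError(f"leaf {lab!r} has fewer samples than requested for training")
    return np.array(train_idx, dtype=int), np.array(test_idx, dtype=int)


#: Train/test convention for the glass-shaped toy: 146 training points
#: (20 / 60 / 66) and 29 test points (9 / 10 / 10).
GLASS_TRAIN_COUNTS: dict[str, int] = {"1.1": 20, "2.1": 60, "2.2": 66}
GLASS_TEST_COUNTS: dict[str, int] = {"1.1": 9, "2.1": 10, "2.2": 10}


def glass_shape_spec(seed: int = 0, **overrides) -> SynthSpec:
    """The classic two-family / three-leaf toy shape: a lone 29-sample family
    ("1.1") and a near-balanced confusable sibling pair ("2.1" 70, "2.2" 76),
    175 points in total (split 146 train / 29 test by ``GLASS_TRAIN_COUNTS``)."""
    kwargs = dict(
        n_per_leaf={"1.1": 29, "2.1": 70, "2.2": 76},
        tree=glass_tree(),
        seed=seed,
    )
    kwargs.update(overrides)
    return SynthSpec(**kwargs)


#: Train counts for the sibling-overlap regime; the remaining 20/20/20
#: samples per leaf are the test set.
SIBLING_OVERLAP_TRAIN_COUNTS: dict[str, int] = {"1.1": 60, "1.2": 20, "2.1": 40}


def sibling_overlap_spec(seed: int = 0, **overrides) -> SynthSpec:
    """The sibling-overlap regime used for hierarchy-benefit comparisons: an
    imbalanced confusable sibling pair ("1.1" 60 vs "1.2" 20 training samples)
    plus a well-separated lone family ("2.1" 40), with 20 held-out test
    samples per leaf on top of the training counts."""
    kwargs = dict(
        n_per_leaf={"1.1": 80, "1.2": 40, "2.1": 60},
        seed=seed,
    )
    kwargs.update(overrides)
    return SynthSpec(**kwargs)
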