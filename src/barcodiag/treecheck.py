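"""Distance-tree sanity check: p-distance NJ, bootstrap, support categories.

This is deliberately lightweight: uncorrected p-distances, saitou-nei
neighbor joining, and a nonparametric column-resampling bootstrap.  The
point is qualitative — whether a tree built from the fragment can separate
the two species at all — so no substitution-model machinery is involved.
Support values are classified with the conventional thresholds: bootstrap
>= 75% strong, >50% and <75% moderate, <=50% negligible; posterior
probability >= 0.95 strong, 0.90-0.94 moderate, <0.90 negligible.

The NJ core is vectorised so that thousands of bootstrap replicates on an
~80-taxon alignment run in seconds; ties in the join criterion are broken
deterministically by the lowest (row, column) index pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import NUCLEOTIDES, LabeledAlignment

BOOTSTRAP_PCT = "bootstrap_pct"
POSTERIOR_PROB = "posterior_prob"

STRONG = "strong"
MODERATE = "moderate"
NEGLIGIBLE = "negligible"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with taxon labels."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SupportedTree:
    """Unrooted tree as a set of bipartitions plus a newick serialisation.

    ``splits`` maps each nontrivial bipartition — canonicalised as the
    frozenset of labels on the side *not* containing the first taxon — to
    its bootstrap percentage (None when support has not been computed).
    """

    taxa: tuple[str, ...]
    newick: str
    splits: dict[frozenset, float | None] = field(default_factory=dict)

    def canonical(self, labels: frozenset) -> frozenset:
        full = frozenset(self.taxa)
        if not labels <= full:
            raise ValueError("labels not a subset of the taxon set")
        return labels if self.taxa[0] not in labels else full - labels


def _encode(alignment: LabeledAlignment) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Sequences as a (n, L) byte matrix plus an unambiguous-site mask."""
    length = alignment.sequence_length()
    n = len(alignment)
    enc = np.zeros((n, length), dtype=np.uint8)
    for i, rec in enumerate(alignment):
        enc[i] = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
    valid_codes = np.array([ord(c) for c in NUCLEOTIDES], dtype=np.uint8)
    ok = np.isin(enc, valid_codes)
    labels = tuple(rec.id for rec in alignment)
    return enc, ok, labels


def _pairwise_p_distance(enc: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """p-distance over sites where both members of a pair are unambiguous."""
    # Collapse duplicate rows first: bootstrap alignments of population data
    # carry many identical haplotypes and the pairwise step is the hot path.
    merged = np.where(ok, enc, 0)
    uniq, inv = np.unique(merged, axis=0, return_inverse=True)
    u_ok = uniq != 0
    diff = (uniq[:, None, :] != uniq[None, :, :]) & u_ok[:, None, :] & u_ok[None, :, :]
    comparable = (u_ok[:, None, :] & u_ok[None, :, :]).sum(axis=2)
    if (comparable == 0).any():
        bad = np.argwhere(comparable == 0)
        i, j = bad[0]
        raise ValueError(f"sequence pair ({i}, {j}) shares no comparable site")
    d_uniq = diff.sum(axis=2) / comparable
    d = d_uniq[inv][:, inv]
    np.fill_diagonal(d, 0.0)
    return d


def p_distance_matrix(alignment: LabeledAlignment) -> DistanceMatrix:
    """Proportion of differing comparable sites for every sequence pair."""
    enc, ok, labels = _encode(alignment)
    return DistanceMatrix(labels=labels, matrix=_pairwise_p_distance(enc, ok))


def _nj_splits(d: np.ndarray) -> tuple[list[frozenset], "_Node"]:
    """Run neighbor joining; return nontrivial leaf-index splits and the tree.

    Ties in the Q criterion resolve to the lowest (i, j) pair in current
    active order, which makes the whole procedure deterministic.
    """
    n = d.shape[0]
    d = d.astype(float, copy=True)
    active = list(range(n))  # positions index into d
    nodes: list[_Node] = [_Node(leaf=i, leaves=frozenset([i])) for i in range(n)]
    splits: list[frozenset] = []

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major => lowest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        node_i, node_j = nodes[active[i]], nodes[active[j]]
        new = _Node(
            children=[(node_i, li), (node_j, lj)],
            leaves=node_i.leaves | node_j.leaves,
        )
        if 2 <= len(new.leaves) <= n - 2:
            splits.append(new.leaves)
        # distances from the new node to every other active node
        others = [a for k, a in enumerate(active) if k not in (i, j)]
        new_d = 0.5 * (d[active[i], others] + d[active[j], others] - dij)
        idx = len(nodes)
        nodes.append(new)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[idx, others] = new_d
        d[others, idx] = new_d
        active = others + [idx]

    a, b = active
    root = _Node(
        children=[(nodes[a], d[a, b] / 2.0), (nodes[b], d[a, b] / 2.0)],
        leaves=nodes[a].leaves | nodes[b].leaves,
    )
    return splits, root


class _Node:
    __slots__ = ("leaf", "children", "leaves")

    def __init__(self, leaf: int | None = None, children=None, leaves=frozenset()):
        self.leaf = leaf
        self.children = children or []
        self.leaves = leaves


def _to_newick(node: _Node, labels: tuple[str, ...],
               support: dict[frozenset, float | None] | None = None,
               canonical=None) -> str:
    if node.leaf is not None:
        return labels[node.leaf]
    parts = []
    for child, length in node.children:
        parts.append(f"{_to_newick(child, labels, support, canonical)}:{length:.6g}")
    inner = f"({','.join(parts)})"
    if support is not None and canonical is not None:
        key = canonical(frozenset(labels[i] for i in node.leaves))
        val = support.get(key)
        if val is not None:
            inner += f"{val:.0f}"
    return inner


def neighbor_joining(matrix: DistanceMatrix) -> SupportedTree:
    """Standard neighbor-joining agglomeration (no support values yet)."""
    if len(matrix) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    splits, root = _nj_splits(matrix.matrix)
    labels = matrix.labels
    tree = SupportedTree(taxa=labels, newick="")
    tree.splits = {
        tree.canonical(frozenset(labels[i] for i in s)): None for s in splits
    }
    tree.newick = _to_newick(root, labels) + ";"
    return tree


def bootstrap_support(
    alignment: LabeledAlignment, n_replicates: int = 1000, seed: int = 0
) -> SupportedTree:
    """NJ tree with column-resampling bootstrap percentages on its splits.

    Columns are resampled with replacement; each pseudoreplicate alignment
    is re-tabulated into p-distances and re-joined, and every split of the
    original tree is scored by the percentage of replicates containing it.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    enc, ok, labels = _encode(alignment)
    n, length = enc.shape
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    d0 = _pairwise_p_distance(enc, ok)
    splits0, root = _nj_splits(d0)
    tree = SupportedTree(taxa=labels, newick="")
    full = frozenset(range(n))
    # canonical index-level split: the side not containing leaf 0
    canonical_splits = [(full - s) if 0 in s else s for s in splits0]

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(canonical_splits), dtype=np.int64)
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        d = _pairwise_p_distance(enc[:, cols], ok[:, cols])
        rep_splits, _ = _nj_splits(d)
        rep_canon = {full - s if 0 in s else s for s in rep_splits}
        for k, s in enumerate(canonical_splits):
            if s in rep_canon:
                hits[k] += 1

    support = {
        frozenset(labels[i] for i in s): 100.0 * h / n_replicates
        for s, h in zip(canonical_splits, hits)
    }
    tree.splits = support
    tree.newick = _to_newick(root, labels, support, tree.canonical) + ";"
    return tree


def classify_support(value: float, scale: str = BOOTSTRAP_PCT) -> str:
    """Support category under the conventional thresholds for each scale."""
    if scale == BOOTSTRAP_PCT:
        if not 0 <= value <= 100:
            raise ValueError("bootstrap percentage must be in [0, 100]")
        if value >= 75:
            return STRONG
        if value > 50:
            return MODERATE
        return NEGLIGIBLE
    if scale == POSTERIOR_PROB:
        if not 0 <= value <= 1:
            raise ValueError("posterior probability must be in [0, 1]")
        if value >= 0.95:
            return STRONG
        if value >= 0.90:
            return MODERATE
        return NEGLIGIBLE
    raise ValueError(f"unknown support scale {scale!r}")


def is_monophyletic(tree: SupportedTree, label_set: set[str] | frozenset) -> bool:
    """True iff some edge of the tree separates exactly *label_set*."""
    labels = frozenset(label_set)
    full = frozenset(tree.taxa)
    if not labels <= full:
        raise ValueError("unknown labels in query set")
    if len(labels) in (0, 1, len(full) - 1, len(full)):
        return len(labels) > 0  # pendant edges and the whole set are trivial
    return tree.canonical(labels) in tree.splits


def split_support(tree: SupportedTree, label_set: set[str] | frozenset) -> float | None:
    """Bootstrap percentage of the bipartition isolating *label_set*.

    Returns None when the split is not in the tree at all.
    """
    labels = frozenset(label_set)
    return tree.splits.get(tree.canonical(labels))
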