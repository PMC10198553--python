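"""Neighbor-Joining trees, bootstrap support and taxonomic-outlier flagging.

NJ follows Saitou & Nei with the Studier–Keppler selection criterion

    Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

joining the pair with minimal Q (ties broken by the first minimal (i, j) in
scan order), limb lengths d(i,j)/2 +- (row-sum difference)/(2(r-2)), and
reduced distances d(u, k) = (d(i,k) + d(j,k) - d(i,j)) / 2. The algorithm is
exact on additive matrices. Trees are scikit-bio TreeNode objects with a
trifurcating root (the unrooted representation).

Bootstrap support resamples alignment columns with replacement, rebuilds the
tree per replicate, and scores each internal bipartition of the point tree
by the fraction of replicates containing it.

Outlier flagging automates the manual cluster review used when assembling
reference libraries: a leaf is flagged when most of its k nearest leaves by
patristic distance carry a different label at the chosen rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio.tree import TreeNode

from .distances import DistanceMatrix, codes_to_distances
from .library_io import LibraryError, ReferenceLibrary, encode_sequences

__all__ = [
    "neighbor_joining",
    "bootstrap_support",
    "sum_branch_lengths",
    "flag_taxonomic_outliers",
    "bipartitions",
    "robinson_foulds",
    "write_newick",
    "OutlierFlag",
]

logger = logging.getLogger(__name__)


def _nj_from_array(
    d: np.ndarray, names: Sequence[str], clamp_negative: bool = False
) -> TreeNode:
    nodes = [TreeNode(name=n) for n in names]
    d = d.astype(float).copy()
    while len(nodes) > 3:
        r = len(nodes)
        s = d.sum(axis=1)
        q = (r - 2) * d - s[:, None] - s[None, :]
        np.fill_diagonal(q, np.inf)
        # first minimal entry in row-major scan = smallest (i, j) index pair
        i, j = divmod(int(np.argmin(q)), r)
        if i > j:
            i, j = j, i
        limb_i = 0.5 * d[i, j] + (s[i] - s[j]) / (2.0 * (r - 2))
        limb_j = d[i, j] - limb_i
        if clamp_negative:
            if limb_i < 0:
                limb_j += limb_i
                limb_i = 0.0
            elif limb_j < 0:
                limb_i += limb_j
                limb_j = 0.0
        nodes[i].length = float(limb_i)
        nodes[j].length = float(limb_j)
        parent = TreeNode(children=[nodes[i], nodes[j]])

        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        new_d = np.zeros((r - 1, r - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = du[keep]
        new_d[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        d = new_d

    if len(nodes) == 3:
        a, b, c = 0, 1, 2
        limbs = (
            0.5 * (d[a, b] + d[a, c] - d[b, c]),
            0.5 * (d[a, b] + d[b, c] - d[a, c]),
            0.5 * (d[a, c] + d[b, c] - d[a, b]),
        )
        if clamp_negative:
            # transfer any negative limb onto the other two star edges so the
            # total branch length is preserved
            limbs = list(limbs)
            for _ in range(3):
                for idx in range(3):
                    if limbs[idx] < 0:
                        others = [o for o in range(3) if o != idx]
                        for o in others:
                            limbs[o] += limbs[idx] / 2.0
                        limbs[idx] = 0.0
            limbs = tuple(max(0.0, x) for x in limbs)
        for node, limb in zip(nodes, limbs):
            node.length = float(limb)
        return TreeNode(children=list(nodes))
    raise AssertionError("unreachable: NJ requires n >= 3")


def neighbor_joining(matrix: DistanceMatrix, clamp_negative: bool = False) -> TreeNode:
    """Build an NJ tree from a complete distance matrix.

    Negative limb lengths are retained by default; ``clamp_negative=True``
    clamps them to zero and transfers the deficit to the sister edge so the
    pair's summed limb length is preserved.
    """
    if matrix.undefined_pairs:
        raise LibraryError(
            f"matrix has {len(matrix.undefined_pairs)} undefined pair(s); "
            "exclude those records before tree building"
        )
    if len(matrix) < 3:
        raise LibraryError("NJ requires at least 3 records")
    return _nj_from_array(matrix.data, matrix.ids, clamp_negative=clamp_negative)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of the leaf set, one per internal edge.

    Each bipartition is canonicalised as a frozenset of the two frozensets of
    tip names, so it is invariant to rooting.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    parts: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) >= 2 and len(other) >= 2:
            parts.add(frozenset((side, other)))
    return parts


def robinson_foulds(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Unrooted Robinson–Foulds distance (symmetric bipartition difference)."""
    pa, pb = bipartitions(tree_a), bipartitions(tree_b)
    return len(pa ^ pb)


def sum_branch_lengths(tree: TreeNode) -> float:
    """Total branch length over all edges of the tree."""
    return float(
        sum(n.length or 0.0 for n in tree.traverse(include_self=False))
    )


def bootstrap_support(
    library: ReferenceLibrary,
    model: str = "JC",
    n_reps: int = 1000,
    seed: int | None = None,
    clamp_negative: bool = False,
) -> tuple[TreeNode, int]:
    """NJ point tree with bootstrap support on its internal edges.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    replicate tree is rebuilt and the support of every internal bipartition
    of the point tree is the fraction of replicates containing it. Replicates
    with a saturated (undefined) pair are skipped and counted; support is over
    completed replicates. The resampling stream depends only on the seed and
    the alignment length, never on leaf order. Supports are stored on internal
    nodes (``node.name``, 0..1 as text) and returned with the skip count.
    """
    if n_reps < 1:
        raise LibraryError("n_reps must be >= 1")
    codes = encode_sequences(library)
    ids = library.ids
    d0 = codes_to_distances(codes, model)
    if np.isnan(d0).any():
        raise LibraryError("point-estimate matrix has undefined pairs")
    point = _nj_from_array(d0, ids, clamp_negative=clamp_negative)
    point_parts = bipartitions(point)

    rng = np.random.default_rng(seed)
    counts = {part: 0 for part in point_parts}
    n_skipped = 0
    n_cols = codes.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        d = codes_to_distances(codes[:, cols], model)
        if np.isnan(d).any():
            n_skipped += 1
            logger.warning("bootstrap replicate skipped: saturated pair")
            continue
        rep_parts = bipartitions(_nj_from_array(d, ids, clamp_negative=clamp_negative))
        for part in point_parts & rep_parts:
            counts[part] += 1

    n_done = n_reps - n_skipped
    all_tips = frozenset(ids)
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        part = frozenset((side, all_tips - side))
        if part in counts and n_done > 0:
            node.name = f"{counts[part] / n_done:.4f}"
    return point, n_skipped


@dataclass(frozen=True)
class OutlierFlag:
    record_id: str
    label: str
    neighbour_labels: tuple[str, ...]
    agreeing: int


def flag_taxonomic_outliers(
    tree: TreeNode,
    rank_labels: Mapping[str, str],
    k: int = 5,
) -> tuple[list[OutlierFlag], list[str]]:
    """Flag leaves whose tree neighbourhood contradicts their taxonomy.

    A leaf is flagged when a strict majority of its k nearest leaves by
    patristic distance carry a different label at the chosen rank. Leaves
    whose label has no other member cannot be assessed and are returned in
    the skipped list.
    """
    if k < 1:
        raise LibraryError("k must be >= 1")
    tip_dm = tree.tip_tip_distances()
    ids = list(tip_dm.ids)
    missing = [i for i in ids if i not in rank_labels]
    if missing:
        raise LibraryError(f"leaves without labels: {missing[:5]}")
    dist = np.asarray(tip_dm.data)
    label_counts: dict[str, int] = {}
    for i in ids:
        label_counts[rank_labels[i]] = label_counts.get(rank_labels[i], 0) + 1

    flagged: list[OutlierFlag] = []
    skipped: list[str] = []
    for idx, rid in enumerate(ids):
        label = rank_labels[rid]
        if label_counts[label] < 2:
            skipped.append(rid)
            continue
        order = np.argsort(dist[idx], kind="stable")
        nearest = [ids[o] for o in order if o != idx][:k]
        labels = tuple(rank_labels[n] for n in nearest)
        agreeing = sum(1 for l in labels if l == label)
        if len(labels) - agreeing > len(labels) / 2:
            flagged.append(OutlierFlag(rid, label, labels, agreeing))
    return flagged, skipped


def write_newick(tree: TreeNode, dest) -> None:
    """Write newick with 6-decimal branch lengths; internal-node names carry
    bootstrap supports when present."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            base = node.name or ""
        else:
            base = "(" + ",".join(fmt(c) for c in node.children) + ")" + (node.name or "")
        if node.length is not None:
            base += f":{node.length:.6f}"
        return base

    text = fmt(tree) + ";\n"
    if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__"):
        with open(dest, "w") as fh:
            fh.write(text)
    else:
        dest.write(text)
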