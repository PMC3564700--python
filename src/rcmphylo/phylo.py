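"""Tree construction and comparison: neighbor joining, Robinson-Foulds
symmetric distance, extended-majority-rule consensus, Newick I/O.

Trees are held as :class:`dendropy.Tree` objects.  All topology comparison
runs on *bipartitions*: the leaf-label splits induced by internal edges,
stored in a canonical orientation (the side not containing the
lexicographically smallest leaf label) so that set operations are
well-defined across trees regardless of where they happen to be rooted.
Trivial splits (one leaf against the rest) are excluded.  Branch lengths
play no role in any of the comparisons here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import dendropy
import numpy as np

from .rcm import DistanceMatrix

__all__ = [
    "read_tree",
    "read_trees",
    "write_tree",
    "write_trees",
    "leaf_labels",
    "bipartitions",
    "nj_tree",
    "rf_distance",
    "consensus_mre",
    "split_counts",
    "RobustnessPoint",
    "robustness_curve",
]

Split = frozenset  # frozenset[str], canonical side of a bipartition


# ---------------------------------------------------------------------------
# Newick I/O


def read_trees(source: Union[str, Path]) -> list[dendropy.Tree]:
    """Read all trees from a Newick file (or a raw Newick string)."""
    text = str(source)
    if "(" in text and ";" in text:
        tl = dendropy.TreeList.get(data=text, schema="newick", preserve_underscores=True)
    else:
        tl = dendropy.TreeList.get(path=text, schema="newick", preserve_underscores=True)
    return list(tl)


def read_tree(source: Union[str, Path]) -> dendropy.Tree:
    trees = read_trees(source)
    if not trees:
        raise ValueError(f"no trees found in {source}")
    return trees[0]


def write_tree(tree: dendropy.Tree, path: Union[str, Path, None] = None) -> str:
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def write_trees(trees: Iterable[dendropy.Tree], path: Union[str, Path, None] = None) -> str:
    text = "".join(write_tree(t) for t in trees)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Bipartitions


def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> frozenset:
    """Non-trivial splits of the (unrooted view of the) tree.

    Each split is the frozenset of leaf labels on the side *not* containing
    the reference leaf (the minimum label), so identical splits from
    differently rooted trees compare equal.  A degree-2 root contributes its
    split only once.
    """
    labels = leaf_labels(tree)
    n = len(labels)
    ref = min(labels)
    below: dict = {}
    out = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset((node.taxon.label,))
            continue
        s = frozenset().union(*(below[c] for c in node.child_nodes()))
        below[node] = s
        if node.parent_node is None:
            continue
        side = s if ref not in s else labels - s
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return frozenset(out)


def _check_same_leaves(t1: dendropy.Tree, t2: dendropy.Tree) -> frozenset:
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ; symmetric difference: {sorted(l1 ^ l2)}"
        )
    return l1


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix, *, clamp_negative: bool = False) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on a labelled distance matrix.

    Deterministic: ties on the Q-criterion are broken by the lowest
    (row, column) index pair in the current working order, where each join
    replaces the first of the joined entries in place and removes the
    second.  Negative branch lengths are kept as computed unless
    ``clamp_negative`` is set, in which case a negative length is zeroed
    and the difference moved to the sibling branch of the same join
    (PHYLIP-style); in the terminal 3-branch join the deficit is added to
    the longest branch.

    Returns an unrooted tree stored with a degree-3 pseudo-root.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError(f"neighbor joining needs at least 3 taxa, got {n}")
    D = np.array(dm.values, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite values")

    tns = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = [dendropy.Node(taxon=t) for t in tns]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major argmin = lowest (i, j) tie-break
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        if clamp_negative:
            if vi < 0:
                vj += vi
                vi = 0.0
            if vj < 0:
                vi = max(vi + vj, 0.0)
                vj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(vi)
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(vj)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        nodes[i] = parent
        del nodes[j]

    v = [
        0.5 * (D[0, 1] + D[0, 2] - D[1, 2]),
        0.5 * (D[0, 1] + D[1, 2] - D[0, 2]),
        0.5 * (D[0, 2] + D[1, 2] - D[0, 1]),
    ]
    if clamp_negative:
        deficit = sum(x for x in v if x < 0)
        v = [max(x, 0.0) for x in v]
        if deficit:
            v[int(np.argmax(v))] += deficit
            v = [max(x, 0.0) for x in v]
    root = dendropy.Node()
    for node, length in zip(nodes, v):
        root.add_child(node)
        node.edge.length = float(length)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Robinson-Foulds symmetric distance


def rf_distance(
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    *,
    normalized: bool = False,
) -> Union[int, float]:
    """Robinson-Foulds symmetric distance: size of the symmetric difference
    of the two bipartition sets.  Branch lengths are ignored; multifurcating
    trees contribute only the splits they actually resolve.

    ``normalized=True`` divides by 2(n-3), the maximum over fully resolved
    unrooted trees on n leaves (0.0 is returned for n <= 3).
    """
    leaves = _check_same_leaves(t1, t2)
    d = len(bipartitions(t1) ^ bipartitions(t2))
    if normalized:
        denom = 2 * (len(leaves) - 3)
        return d / denom if denom > 0 else 0.0
    return d


# ---------------------------------------------------------------------------
# Extended majority rule consensus


def split_counts(trees: Sequence[dendropy.Tree]) -> Counter:
    """Occurrence count of every non-trivial split across the input trees."""
    counts: Counter = Counter()
    for t in trees:
        counts.update(bipartitions(t))
    return counts


def _compatible(a: Split, b: Split) -> bool:
    # canonical sides exclude the reference leaf, so two splits are
    # compatible iff the sides are nested or disjoint
    return a <= b or b <= a or not (a & b)


def consensus_mre(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Extended majority rule (MRe) consensus.

    All splits present in more than half the input trees are retained, then
    the remaining splits are scanned greedily — ordered by occurrence count
    descending, ties by the sorted label tuple — and each one compatible
    with everything retained so far is added, until no compatible splits
    remain.  Every retained internal branch is labelled with its occurrence
    count, mirroring how consensus branch support is reported.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("consensus requires at least one tree")
    labels = leaf_labels(trees[0])
    for t in trees[1:]:
        _check_same_leaves(trees[0], t)
    n_trees = len(trees)
    counts = split_counts(trees)

    accepted = [s for s in counts if 2 * counts[s] > n_trees]
    rest = sorted(
        (s for s in counts if 2 * counts[s] <= n_trees),
        key=lambda s: (-counts[s], tuple(sorted(s))),
    )
    for s in rest:
        if all(_compatible(s, a) for a in accepted):
            accepted.append(s)

    # retained splits must be pairwise compatible by construction; verify
    for a_idx, a in enumerate(accepted):
        for b in accepted[a_idx + 1:]:
            assert _compatible(a, b), "incompatible splits in consensus"

    ref = min(labels)
    tns = dendropy.TaxonNamespace(sorted(labels))
    root = dendropy.Node()
    # nest clades (canonical sides, all excluding ref) largest-first; the
    # parent of a clade is the smallest previously placed clade containing
    # it, which is unique because compatible same-size clades cannot nest
    ordered = sorted(accepted, key=lambda s: (-len(s), tuple(sorted(s))))
    placed: list[tuple[Split, dendropy.Node]] = []
    for clade in ordered:
        node = dendropy.Node(label=str(counts[clade]))
        parent = root
        for cs, cn in placed:
            if clade <= cs:
                parent = cn
        parent.add_child(node)
        placed.append((clade, node))
    for lab in sorted(labels):
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        parent = root
        if lab != ref:
            for cs, cn in placed:
                if lab in cs:
                    parent = cn
        parent.add_child(leaf)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Robustness curve


@dataclass(frozen=True)
class RobustnessPoint:
    """Per-rate result of the perturbation robustness experiment."""

    rate: float
    consensus: dendropy.Tree
    rf_consensus: int
    replicate_rf: tuple[int, ...]

    @property
    def mean_replicate_rf(self) -> float:
        return float(np.mean(self.replicate_rf)) if self.replicate_rf else 0.0


def robustness_curve(
    original: dendropy.Tree,
    replicate_trees_by_rate: Mapping[float, Sequence[dendropy.Tree]],
) -> dict:
    """Per mutation rate: MRe consensus of the replicate trees, its RF
    distance to the original tree, and the per-replicate RF distribution.
    Rate order of the input mapping is preserved in the output.
    """
    out: dict[float, RobustnessPoint] = {}
    for rate, trees in replicate_trees_by_rate.items():
        cons = consensus_mre(list(trees))
        out[rate] = RobustnessPoint(
            rate=rate,
            consensus=cons,
            rf_consensus=int(rf_distance(cons, original)),
            replicate_rf=tuple(int(rf_distance(t, original)) for t in trees),
        )
    return out
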