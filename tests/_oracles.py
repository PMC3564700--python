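"""Independent reference implementations used only by the test suite.

Everything here deliberately avoids the package's own code paths: the LZ
parser is a naive O(L^3) history scan, bipartitions come from networkx
edge-removal connectivity, and the consensus is rebuilt straight from its
definition.  These are the oracles the fast implementations are checked
against.
"""

from __future__ import annotations

from collections import Counter

import dendropy
import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# Brute-force LZ parse: for each position try every earlier start and extend
# by direct character comparison (self-overlap falls out naturally because
# s[p + m] with p < i may index symbols written during the current step).


def brute_lz_parse(s: str) -> list[str]:
    n = len(s)
    components = []
    i = 0
    while i < n:
        best = 0
        for p in range(i):
            m = 0
            while i + m < n and s[p + m] == s[i + m]:
                m += 1
            best = max(best, m)
        if i + best < n:
            components.append(s[i : i + best + 1])
            i += best + 1
        else:
            components.append(s[i:])
            i = n
    return components


def brute_lz_complexity(s: str) -> int:
    return len(brute_lz_parse(s))


# ---------------------------------------------------------------------------
# Tree helpers via networkx


def _tree_graph(tree: dendropy.Tree) -> tuple[nx.Graph, dict]:
    g = nx.Graph()
    label = {}
    for node in tree.preorder_node_iter():
        g.add_node(id(node))
        if node.is_leaf():
            label[id(node)] = node.taxon.label
        if node.parent_node is not None:
            w = node.edge.length if node.edge.length is not None else 0.0
            g.add_edge(id(node.parent_node), id(node), weight=w)
    return g, label


def nx_bipartitions(tree: dendropy.Tree) -> frozenset:
    """Non-trivial splits by removing each edge and reading off components."""
    g, leaf_label = _tree_graph(tree)
    labels = frozenset(leaf_label.values())
    ref = min(labels)
    n = len(labels)
    out = set()
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        g.add_edge(u, v)
        side = frozenset(leaf_label[x] for x in comp if x in leaf_label)
        if ref in side:
            side = labels - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return frozenset(out)


def nx_rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    return len(nx_bipartitions(t1) ^ nx_bipartitions(t2))


def patristic_matrix(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix via weighted shortest paths."""
    g, leaf_label = _tree_graph(tree)
    node_of = {lab: nid for nid, lab in leaf_label.items()}
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        dist = nx.single_source_dijkstra_path_length(g, node_of[a])
        for j, b in enumerate(labels):
            if i != j:
                D[i, j] = dist[node_of[b]]
    return (D + D.T) / 2  # exact symmetry despite per-source float sums


def brute_consensus_splits(trees, counts: Counter | None = None):
    """Extended-majority-rule split set straight from the definition."""
    if counts is None:
        counts = Counter()
        for t in trees:
            counts.update(nx_bipartitions(t))
    n = len(trees)
    accepted = [s for s in counts if 2 * counts[s] > n]
    rest = sorted(
        (s for s in counts if 2 * counts[s] <= n),
        key=lambda s: (-counts[s], tuple(sorted(s))),
    )
    for s in rest:
        if all(s <= a or a <= s or not (s & a) for a in accepted):
            accepted.append(s)
    return {s: counts[s] for s in accepted}


# ---------------------------------------------------------------------------
# Random trees with known additive distances


def random_binary_tree(
    rng: np.random.Generator,
    labels: list[str],
    length_range: tuple[float, float] = (0.1, 1.0),
) -> dendropy.Tree:
    """Random unrooted binary topology with uniform branch lengths."""
    tns = dendropy.TaxonNamespace(list(labels))
    nodes = [dendropy.Node(taxon=t) for t in tns]
    lo, hi = length_range
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(rng.uniform(lo, hi))
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(rng.uniform(lo, hi))
        nodes[i] = parent
        del nodes[j]
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
        node.edge.length = float(rng.uniform(lo, hi))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def edge_lengths_by_split(tree: dendropy.Tree) -> dict:
    """Total branch length per split, keyed canonically.

    Pendant edges are keyed by the single-leaf side; the two edges of a
    degree-2 root map to the same split and are summed, matching the single
    edge of the unrooted view.
    """
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(labels)
    below = {}
    out: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset((node.taxon.label,))
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        side = below[node]
        if ref in side:
            side = labels - side
        out[side] = out.get(side, 0.0) + (node.edge.length or 0.0)
    return out
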