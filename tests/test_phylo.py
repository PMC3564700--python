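"""Neighbor joining, Robinson-Foulds and consensus against independent oracles."""

import io

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from _oracles import (
    brute_consensus_splits,
    edge_lengths_by_split,
    nx_bipartitions,
    nx_rf_distance,
    patristic_matrix,
    random_binary_tree,
)
from rcmphylo.phylo import (
    bipartitions,
    consensus_mre,
    leaf_labels,
    nj_tree,
    read_tree,
    read_trees,
    rf_distance,
    robustness_curve,
    split_counts,
    write_tree,
)
from rcmphylo.rcm import DistanceMatrix


def _tree(newick: str) -> dendropy.Tree:
    return read_trees(newick)[0]


# ---------------------------------------------------------------------------
# Newick I/O


def test_newick_roundtrip_topology_labels_lengths(rng):
    t = random_binary_tree(rng, [f"L{i}" for i in range(8)])
    text = write_tree(t)
    back = read_tree(text)
    assert leaf_labels(back) == leaf_labels(t)
    assert rf_distance(back, t) == 0
    assert edge_lengths_by_split(back) == pytest.approx(edge_lengths_by_split(t), abs=1e-9)


def test_read_trees_multitree_and_quoted_labels(tmp_path):
    path = tmp_path / "trees.nwk"
    path.write_text("((A:1,B:1):1,(C:1,D:1):1);\n(('tax one':1,B:1):1,(C:1,D:1):1);\n")
    trees = read_trees(path)
    assert len(trees) == 2
    assert "tax one" in leaf_labels(trees[1])


# ---------------------------------------------------------------------------
# Neighbor joining


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        t = nj_tree(dm)
        lengths = edge_lengths_by_split(t)
        assert lengths[frozenset(["B"])] == pytest.approx(1.0)
        assert lengths[frozenset(["C"])] == pytest.approx(3.0)
        # pendant edge of the reference leaf A is keyed by its complement
        assert lengths[frozenset(["B", "C"])] == pytest.approx(1.0)

    def test_four_taxon_additive_recovery(self, rng):
        true = random_binary_tree(rng, ["A", "B", "C", "D"])
        labels = sorted(leaf_labels(true))
        D = patristic_matrix(true, labels)
        # four-point condition sanity check on the generated matrix
        sums = sorted([D[0, 1] + D[2, 3], D[0, 2] + D[1, 3], D[0, 3] + D[1, 2]])
        assert sums[1] == pytest.approx(sums[2])
        est = nj_tree(DistanceMatrix(tuple(labels), D))
        assert rf_distance(est, true) == 0
        assert edge_lengths_by_split(est) == pytest.approx(edge_lengths_by_split(true), abs=1e-9)

    def test_additive_recovery_many_sizes(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 21))
            true = random_binary_tree(rng, [f"L{i:02d}" for i in range(n)])
            labels = sorted(leaf_labels(true))
            dm = DistanceMatrix(tuple(labels), patristic_matrix(true, labels))
            est = nj_tree(dm)
            assert rf_distance(est, true) == 0
            assert edge_lengths_by_split(est) == pytest.approx(
                edge_lengths_by_split(true), abs=1e-9
            )

    def test_matches_scikit_bio_on_noisy_matrix(self, rng):
        import skbio

        true = random_binary_tree(rng, [f"L{i:02d}" for i in range(10)])
        labels = sorted(leaf_labels(true))
        D = patristic_matrix(true, labels)
        noise = rng.uniform(-1e-3, 1e-3, D.shape)
        D = D + noise + noise.T
        np.fill_diagonal(D, 0.0)
        mine = nj_tree(DistanceMatrix(tuple(labels), D))
        sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        buf = io.StringIO()
        sk.write(buf, format="newick")
        theirs = _tree(buf.getvalue())
        assert rf_distance(mine, theirs) == 0

    def test_degenerate_equal_distances_still_builds(self):
        n = 5
        D = np.ones((n, n)) - np.eye(n)
        t = nj_tree(DistanceMatrix(tuple(f"t{i}" for i in range(n)), D))
        assert leaf_labels(t) == frozenset(f"t{i}" for i in range(n))
        # deterministic under the lowest-(i,j) tie-break
        t2 = nj_tree(DistanceMatrix(tuple(f"t{i}" for i in range(n)), D))
        assert write_tree(t) == write_tree(t2)

    def test_negative_lengths_kept_unless_clamped(self):
        # matrix engineered to force a negative NJ branch
        D = np.array(
            [
                [0.0, 0.1, 2.0, 2.0],
                [0.1, 0.0, 1.0, 1.0],
                [2.0, 1.0, 0.0, 0.1],
                [1.98, 1.0, 0.1, 0.0],
            ]
        )
        D = (D + D.T) / 2
        labels = ("a", "b", "c", "d")
        kept = nj_tree(DistanceMatrix(labels, D))
        clamped = nj_tree(DistanceMatrix(labels, D), clamp_negative=True)
        kept_lengths = list(edge_lengths_by_split(kept).values())
        assert min(kept_lengths) < 0
        assert min(edge_lengths_by_split(clamped).values()) >= 0
        # clamping redistributes within the join: totals match
        assert sum(edge_lengths_by_split(clamped).values()) == pytest.approx(
            sum(kept_lengths)
        )

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# Robinson-Foulds


class TestRFDistance:
    def test_identity_and_four_taxon_topologies(self):
        t1 = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = _tree("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_distance(t1, t1) == 0
        assert rf_distance(t1, t2) == 2
        assert rf_distance(t1, t2, normalized=True) == 1.0

    def test_matches_edge_removal_oracle(self, rng):
        labels = [f"L{i}" for i in range(6)]
        for _ in range(30):
            t1 = random_binary_tree(rng, labels)
            t2 = random_binary_tree(rng, labels)
            assert rf_distance(t1, t2) == nx_rf_distance(t1, t2)
            assert bipartitions(t1) == nx_bipartitions(t1)

    def test_matches_dendropy_treecompare(self, rng):
        tns = dendropy.TaxonNamespace()
        for _ in range(15):
            a = random_binary_tree(rng, [f"L{i}" for i in range(8)])
            b = random_binary_tree(rng, [f"L{i}" for i in range(8)])
            da = dendropy.Tree.get(data=write_tree(a), schema="newick", taxon_namespace=tns)
            db = dendropy.Tree.get(data=write_tree(b), schema="newick", taxon_namespace=tns)
            da.encode_bipartitions()
            db.encode_bipartitions()
            assert rf_distance(a, b) == treecompare.symmetric_difference(da, db)

    def test_bound_and_metric_properties(self, rng):
        labels = [f"L{i}" for i in range(9)]
        for _ in range(10):
            a, b, c = (random_binary_tree(rng, labels) for _ in range(3))
            dab, dbc, dac = rf_distance(a, b), rf_distance(b, c), rf_distance(a, c)
            n = len(labels)
            assert 0 <= dab <= 2 * (n - 3) and dab % 2 == 0
            assert dab == rf_distance(b, a)
            assert dac <= dab + dbc  # triangle inequality

    def test_mismatched_leaf_sets_error_names_difference(self):
        t1 = _tree("((A,B),(C,D));")
        t2 = _tree("((A,B),(C,E));")
        with pytest.raises(ValueError, match=r"\['D', 'E'\]"):
            rf_distance(t1, t2)


# ---------------------------------------------------------------------------
# Extended majority rule consensus


def _support_by_split(tree: dendropy.Tree) -> dict:
    labels = leaf_labels(tree)
    ref = min(labels)
    below = {}
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset((node.taxon.label,))
            continue
        s = frozenset().union(*(below[c] for c in node.child_nodes()))
        below[node] = s
        if node.parent_node is None:
            continue
        side = s if ref not in s else labels - s
        if 2 <= len(side) <= len(labels) - 2:
            out[side] = int(node.label)
    return out


class TestConsensusMre:
    def test_unanimous_trees_reproduce_topology_with_full_support(self, rng):
        t = random_binary_tree(rng, [f"L{i}" for i in range(7)])
        cons = consensus_mre([t] * 50)
        assert rf_distance(cons, t) == 0
        assert set(_support_by_split(cons).values()) == {50}

    def test_majority_split_retained_with_count(self):
        trees = [
            _tree("((A,B),(C,D));"),
            _tree("((A,B),(C,D));"),
            _tree("((A,C),(B,D));"),
        ]
        cons = consensus_mre(trees)
        support = _support_by_split(cons)
        assert support == {frozenset(["C", "D"]): 2}

    def test_extended_rule_adds_subminority_compatible_split(self):
        # {D,E,F} appears in 40% of trees yet is compatible with both
        # majority splits; strict majority would drop it, MRe keeps it
        trees = (
            [_tree("(((A,B),C),(D,(E,F)));")] * 4
            + [_tree("(((A,B),D),(C,(E,F)));")] * 3
            + [_tree("(((A,B),(E,F)),(C,D));")] * 3
        )
        support = _support_by_split(consensus_mre(trees))
        assert support[frozenset(["D", "E", "F"])] == 4
        assert support[frozenset(["C", "D", "E", "F"])] == 10
        assert support[frozenset(["E", "F"])] == 10
        # conflicting minority splits were rejected
        assert frozenset(["C", "D"]) not in support
        assert frozenset(["C", "E", "F"]) not in support

    def test_matches_bruteforce_consensus_on_random_sets(self, rng):
        labels = [f"L{i}" for i in range(6)]
        for _ in range(12):
            trees = [random_binary_tree(rng, labels) for _ in range(9)]
            expected = brute_consensus_splits(trees)
            cons = consensus_mre(trees)
            assert _support_by_split(cons) == expected

    def test_counts_and_compat(self, rng):
        labels = [f"L{i}" for i in range(6)]
        trees = [random_binary_tree(rng, labels) for _ in range(5)]
        counts = split_counts(trees)
        assert sum(counts.values()) == sum(len(bipartitions(t)) for t in trees)
        splits = list(bipartitions(consensus_mre(trees)))
        for i, a in enumerate(splits):
            for b in splits[i + 1:]:
                assert a <= b or b <= a or not (a & b)

    def test_errors(self):
        with pytest.raises(ValueError):
            consensus_mre([])
        with pytest.raises(ValueError):
            consensus_mre([_tree("((A,B),(C,D));"), _tree("((A,B),(C,E));")])


# ---------------------------------------------------------------------------
# Robustness curve plumbing


def test_robustness_curve_identical_replicates_give_zero(rng):
    t = random_binary_tree(rng, [f"L{i}" for i in range(6)])
    rates = [0.0, 0.05, 0.10]
    curve = robustness_curve(t, {r: [t] * 5 for r in rates})
    assert list(curve) == rates  # input rate order preserved
    for point in curve.values():
        assert point.rf_consensus == 0
        assert point.replicate_rf == (0,) * 5
        assert point.mean_replicate_rf == 0.0
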