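import numpy as np
import pytest

from auxiaa.errors import InputError, ValidationError
from auxiaa.phylogeny import (
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    bootstrap_support,
    neighbor_joining,
    pdistance_matrix,
    suggest_paralog_pairs,
)
from auxiaa.synthetic_data import default_family_plan, simulate_family_sequences

from oracles import (
    enumerate_unrooted_topologies,
    least_squares_sse,
    random_additive_tree,
)


class TestPDistance:
    def test_identical_rows(self):
        dm = pdistance_matrix([("a", "ACDE"), ("b", "ACDE"), ("c", "ACDE")])
        assert np.allclose(dm.d, 0)

    def test_half_mismatch(self):
        dm = pdistance_matrix([("a", "AAAA"), ("b", "AATT"), ("c", "AAAA")])
        i, j = dm.labels.index("a"), dm.labels.index("b")
        assert dm.d[i, j] == 0.5

    def test_pairwise_deletion(self):
        dm = pdistance_matrix([("a", "A-CD"), ("b", "AACD"), ("c", "AAAA")])
        i, j = dm.labels.index("a"), dm.labels.index("b")
        assert dm.d[i, j] == 0.0  # gapped column excluded

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(InputError, match="a.*b|b.*a"):
            pdistance_matrix([("a", "AC--"), ("b", "--AC"), ("c", "ACAC")])

    def test_matches_per_column_oracle(self, rng):
        for _ in range(50):
            n, L = int(rng.integers(3, 8)), int(rng.integers(5, 40))
            rows = [
                ("t%d" % i, "".join(rng.choice(list("ACDE-"), size=L)))
                for i in range(n)
            ]
            try:
                dm = pdistance_matrix(rows)
            except InputError:
                continue
            for i in range(n):
                for j in range(n):
                    a, b = rows[i][1], rows[j][1]
                    cols = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
                    if not cols:
                        continue
                    expected = sum(x != y for x, y in cols) / len(cols)
                    assert dm.d[i, j] == pytest.approx(expected)

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        tree = neighbor_joining(dm)
        lengths = {c.label: c.length for c in tree.root.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_additive(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> AB|CD with internal branch 1
        labels = ("A", "B", "C", "D")
        M = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 0.0, 0.0],
            ]
        )
        M[3, 2] = M[2, 3] = 7.0
        tree = neighbor_joining(DistanceMatrix(labels, M))
        biparts = tree.bipartitions()
        (key, node), = biparts.items()
        assert key in (frozenset({"C", "D"}), frozenset({"A", "B"}))
        assert node.length == pytest.approx(1.0)
        labs, P = tree.leaf_distances()
        idx = [labs.index(l) for l in labels]
        assert np.allclose(P[np.ix_(idx, idx)], M)

    def test_equal_distances_deterministic(self):
        labels = ("a", "b", "c", "d", "e")
        M = np.ones((5, 5)) - np.eye(5)
        t1 = neighbor_joining(DistanceMatrix(labels, M))
        t2 = neighbor_joining(DistanceMatrix(labels[::-1], M))
        assert t1.newick() == t2.newick()

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(InputError):
            neighbor_joining(DistanceMatrix(("a", "b"), np.array([[0.0, 1], [1, 0.0]])))

    def test_additive_recovery_property(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 13))
            labels, M, true_splits = random_additive_tree(n, rng)
            tree = neighbor_joining(DistanceMatrix(tuple(labels), M))
            labs, P = tree.leaf_distances()
            idx = [labs.index(l) for l in labels]
            assert np.abs(P[np.ix_(idx, idx)] - M).max() < 1e-9
            assert set(tree.bipartitions()) == true_splits

    def test_matches_exhaustive_least_squares_on_small_matrices(self, rng):
        for n in (4, 5, 6):
            topologies = enumerate_unrooted_topologies([f"T{i:02d}" for i in range(n)])
            for _ in range(6):
                labels, M, _ = random_additive_tree(n, rng)
                noise = rng.uniform(-0.05, 0.05, size=M.shape)
                noise = (noise + noise.T) / 2
                np.fill_diagonal(noise, 0.0)
                Mn = M + noise
                tree = neighbor_joining(DistanceMatrix(tuple(labels), Mn))
                nj_splits = frozenset(tree.bipartitions())
                sse = {
                    bip: least_squares_sse(edges, labels, Mn)
                    for bip, edges in topologies.items()
                }
                best = min(sse, key=sse.get)
                assert nj_splits == best

    def test_taxon_order_invariance(self, rng):
        labels, M, _ = random_additive_tree(7, rng)
        dm = DistanceMatrix(tuple(labels), M)
        perm = rng.permutation(len(labels))
        dm2 = DistanceMatrix(
            tuple(labels[i] for i in perm), M[np.ix_(perm, perm)]
        )
        assert neighbor_joining(dm).newick() == neighbor_joining(dm2).newick()

    def test_agrees_with_dendropy_on_random_matrices(self, rng):
        dendropy = pytest.importorskip("dendropy")
        for _ in range(10):
            labels, M, _ = random_additive_tree(int(rng.integers(4, 9)), rng)
            noise = rng.uniform(0, 0.02, size=M.shape)
            Mn = M + (noise + noise.T) / 2
            np.fill_diagonal(Mn, 0.0)
            tree = neighbor_joining(DistanceMatrix(tuple(labels), Mn))
            csv = "," + ",".join(labels) + "\n"
            for i, l in enumerate(labels):
                csv += l + "," + ",".join(f"{Mn[i, j]:.12f}" for j in range(len(labels))) + "\n"
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=__import__("io").StringIO(csv),
                delimiter=",",
            )
            dtree = pdm.nj_tree()
            dtree.encode_bipartitions()
            ref = min(labels)
            full = frozenset(labels)
            dsplits = set()
            for edge in dtree.preorder_edge_iter():
                if edge.head_node.is_leaf() or edge.head_node is dtree.seed_node:
                    continue
                side = frozenset(
                    lf.taxon.label for lf in edge.head_node.leaf_iter()
                )
                if 1 < len(side) < len(labels) - 1:
                    dsplits.add(side if ref not in side else full - side)
            assert set(tree.bipartitions()) == dsplits


def _two_clade_alignment():
    # many diagnostic columns separating {a1,a2,a3} from {b1,b2,b3}
    a = "AAAAAAAAAAAAAAAAAAAA"
    b = "CCCCCCCCCCCCCCCCCCCC"
    return [
        ("a1", a), ("a2", a[:-1] + "D"), ("a3", "D" + a[1:]),
        ("b1", b), ("b2", b[:-1] + "D"), ("b3", "D" + b[1:]),
    ]


class TestBootstrap:
    def test_clear_clades_high_support(self):
        tree = bootstrap_support(_two_clade_alignment(), n_replicates=200, seed=5)
        biparts = tree.bipartitions()
        clade = frozenset({"b1", "b2", "b3"})
        candidates = {k: v for k, v in biparts.items()
                      if k == clade or k == frozenset({"a1", "a2", "a3"})}
        assert candidates
        assert all(v.support >= 95 for v in candidates.values())

    def test_single_replicate_supports_binary(self):
        tree = bootstrap_support(_two_clade_alignment(), n_replicates=1, seed=3)
        supports = [n.support for n in tree.internal_nodes()]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_same_seed_identical(self):
        t1 = bootstrap_support(_two_clade_alignment(), n_replicates=50, seed=11)
        t2 = bootstrap_support(_two_clade_alignment(), n_replicates=50, seed=11)
        assert t1.newick() == t2.newick()

    def test_taxon_order_invariance(self):
        aln = _two_clade_alignment()
        t1 = bootstrap_support(aln, n_replicates=50, seed=11)
        t2 = bootstrap_support(aln[::-1], n_replicates=50, seed=11)
        assert t1.newick() == t2.newick()


class TestSuggestPairs:
    def _toy_tree(self):
        a, b, c, d = (TreeNode(label=l, length=1.0) for l in "abcd")
        ab = TreeNode(children=[a, b], length=1.0, support=95.0)
        cd = TreeNode(children=[c, d], length=1.0, support=40.0)
        e = TreeNode(label="e", length=1.0)
        return PhyloTree(root=TreeNode(children=[ab, cd, e]))

    def test_support_threshold(self):
        assert suggest_paralog_pairs(self._toy_tree(), min_support=50) == [("a", "b")]

    def test_star_tree_no_pairs(self):
        leaves = [TreeNode(label=l, length=1.0) for l in "abcde"]
        star = PhyloTree(root=TreeNode(children=leaves))
        assert suggest_paralog_pairs(star, min_support=0) == []

    def test_seven_planted_duplicate_pairs_recovered(self):
        plans = [p for p in default_family_plan() if p.paralog_partner is not None]
        _, _, alignment, truth = simulate_family_sequences(plans=plans, seed=77)
        tree = bootstrap_support(alignment, n_replicates=100, seed=78)
        pairs = suggest_paralog_pairs(tree, min_support=50.0)
        assert sorted(pairs) == sorted(tuple(p) for p in truth.paralog_pairs)
        assert len(pairs) == 7
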