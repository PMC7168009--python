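"""Neighbor joining, outgroup rooting and bootstrap supports."""

import numpy as np
import pytest

from paphbarcode.distance import DistanceMatrix
from paphbarcode.resolution import is_monophyletic
from paphbarcode.treeinfer import (
    BootstrapConfig,
    bootstrap_support,
    neighbor_joining,
    root_with_outgroup,
    unroot,
)
from paphbarcode.tree import TreeError

from conftest import make_alignment


def random_binary_tree_matrix(n, rng):
    """Additive distances from a random binary tree with positive lengths.

    Returns (labels, matrix, bipartitions of the generating tree).
    """
    labels = [f"t{i}" for i in range(n)]
    # build by sequential attachment: start from 2-leaf tree, attach each new
    # leaf to a random existing edge, subdividing it
    edges = {}  # node -> (parent, length)
    next_id = [n]

    class N:  # tiny mutable node
        def __init__(self, name=None):
            self.name, self.children, self.length = name, [], 0.0

    root = N()
    a, b = N(labels[0]), N(labels[1])
    a.length = rng.uniform(0.1, 1.0)
    b.length = rng.uniform(0.1, 1.0)
    root.children = [a, b]

    def all_nodes(node):
        yield node
        for c in node.children:
            yield from all_nodes(c)

    for k in range(2, n):
        candidates = [x for x in all_nodes(root) if x is not root]
        target = candidates[rng.integers(len(candidates))]
        mid, leaf = N(), N(labels[k])
        leaf.length = rng.uniform(0.1, 1.0)
        split = rng.uniform(0.3, 0.7) * target.length
        mid.length = target.length - split
        target.length = split

        def replace(node):
            node.children = [mid if c is target else c for c in node.children]
            for c in node.children:
                replace(c)

        replace(root)
        mid.children = [target, leaf]

    # path lengths between leaves
    def paths(node, acc, out):
        if not node.children:
            out[node.name] = acc
        for c in node.children:
            paths(c, acc + [(c, c.length)], out)

    leaf_paths = {}
    paths(root, [], leaf_paths)
    d = np.zeros((n, n))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i >= j:
                continue
            px = leaf_paths[x]
            py = leaf_paths[y]
            shared = 0
            for (nx, _), (ny, _) in zip(px, py):
                if nx is ny:
                    shared += 1
                else:
                    break
            dist = sum(l for _, l in px[shared:]) + sum(l for _, l in py[shared:])
            d[i, j] = d[j, i] = dist

    def leafset(node):
        if not node.children:
            return frozenset([node.name])
        return frozenset().union(*map(leafset, node.children))

    anchor = min(labels)
    splits = set()
    for node in all_nodes(root):
        if node is root or not node.children:
            continue
        side = leafset(node)
        if 2 <= len(side) <= n - 2:
            splits.add(side if anchor not in side else frozenset(labels) - side)
    return labels, d, splits


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], float), "p"
        )
        tree = neighbor_joining(dm)
        limbs = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert limbs == {"A": 0.0, "B": 2.0, "C": 4.0}

    def test_four_taxon_additive_recovery(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d, "p"))
        limbs = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert limbs == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        (split,) = tree.bipartitions().keys()
        assert split == frozenset({"C", "D"})
        internal = tree.bipartitions()[split]
        assert internal.length == pytest.approx(1.0)

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.5], [0.5, 0]]), "p")
        tree = neighbor_joining(dm)
        assert tree.to_newick() == "(A:0.500000,B:0.000000);"

    def test_internal_edge_count(self):
        rng = np.random.default_rng(5)
        for n in (4, 5, 6, 7, 8):
            labels, d, _ = random_binary_tree_matrix(n, rng)
            tree = neighbor_joining(DistanceMatrix(labels, d, "p"))
            assert len(tree.bipartitions()) == n - 3
            assert len(tree.leaves()) == n

    @pytest.mark.parametrize("seed", range(12))
    def test_additive_matrices_recover_topology_and_lengths(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        labels, d, true_splits = random_binary_tree_matrix(n, rng)
        tree = neighbor_joining(DistanceMatrix(labels, d, "p"))
        assert set(tree.bipartitions().keys()) == true_splits
        # additivity: tree path lengths reproduce the input distances
        dist = tree_path_distances(tree)
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    assert dist[x, y] == pytest.approx(d[i, j], abs=1e-9)

    def test_matches_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(42)
        labels, d, _ = random_binary_tree_matrix(7, rng)
        ours = set(neighbor_joining(DistanceMatrix(labels, d, "p")).bipartitions())
        sk_tree = sk_nj(SkDM(d, labels))
        anchor = min(labels)
        theirs = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(labels) - 2:
                theirs.add(
                    side if anchor not in side else frozenset(labels) - side
                )
        assert ours == theirs

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]), "p")


def tree_path_distances(tree):
    out = {}
    leaves = tree.leaves()

    def depth(leaf):
        d, node = 0.0, leaf
        while node.parent is not None:
            d += node.length
            node = node.parent
        return d

    def path(leaf):
        nodes, node = [], leaf
        while node is not None:
            nodes.append(node)
            node = node.parent
        return nodes

    for i, x in enumerate(leaves):
        for y in leaves[i + 1 :]:
            px, py = path(x), path(y)
            common = next(n for n in px if n in py)

            def climb(leaf):
                d, node = 0.0, leaf
                while node is not common:
                    d += node.length
                    node = node.parent
                return d

            out[x.name, y.name] = out[y.name, x.name] = climb(x) + climb(y)
    return out


class TestRooting:
    def four_taxon_tree(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        return neighbor_joining(DistanceMatrix(list("ABCD"), d, "p"))

    def test_outgroup_split_at_root(self):
        rooted = root_with_outgroup(self.four_taxon_tree(), ["D"])
        assert rooted.rooted
        sides = [c.leaf_names() for c in rooted.root.children]
        assert frozenset({"D"}) in sides
        assert frozenset({"A", "B", "C"}) in sides

    def test_outgroup_edge_length_split_equally(self):
        rooted = root_with_outgroup(self.four_taxon_tree(), ["D"])
        lengths = sorted(c.length for c in rooted.root.children)
        assert lengths == [2.0, 2.0]  # D's limb was 4

    def test_all_leaves_outgroup_rejected(self):
        with pytest.raises(TreeError, match="ingroup"):
            root_with_outgroup(self.four_taxon_tree(), list("ABCD"))

    def test_rerooting_idempotent(self):
        r1 = root_with_outgroup(self.four_taxon_tree(), ["D"])
        r2 = root_with_outgroup(r1, ["D"])
        assert r1.to_newick() == r2.to_newick()

    def test_non_clade_outgroup_rejected(self):
        with pytest.raises(TreeError, match="monophyletic"):
            root_with_outgroup(self.four_taxon_tree(), ["A", "C"])

    def test_unroot_then_root_preserves_leafset(self):
        rooted = root_with_outgroup(self.four_taxon_tree(), ["D"])
        assert unroot(rooted).leaf_names() == rooted.leaf_names()


class TestBootstrap:
    def constant_pattern_alignment(self, n_cols=60):
        pattern = {"a-1": "A", "a-2": "A", "b-1": "G", "b-2": "G", "b-3": "G"}
        return make_alignment(
            "x", [(v, ch * n_cols) for v, ch in pattern.items()]
        )

    def test_constant_pattern_full_support(self):
        tree, diag = bootstrap_support(
            self.constant_pattern_alignment(), "k2p", BootstrapConfig(50, seed=3)
        )
        supports = [n.support for n in tree.bipartitions().values()]
        assert supports and all(s == 100 for s in supports)
        assert diag.redrawn == 0

    def test_fixed_seed_reproducible(self):
        aln = make_alignment(
            "x",
            [
                ("a-1", "ACGTACGTACGTACGTACGA"),
                ("b-1", "ACGTACGTACGTACGAACGA"),
                ("c-1", "ACGAACGTACGAACGTACGT"),
                ("d-1", "ACGAACGAACGAACGTACGT"),
            ],
        )
        t1, _ = bootstrap_support(aln, "k2p", BootstrapConfig(80, seed=9))
        t2, _ = bootstrap_support(aln, "k2p", BootstrapConfig(80, seed=9))
        assert t1.to_newick() == t2.to_newick()

    def test_supports_within_range_and_leaf_order_invariant(self):
        rows = [
            ("a-1", "ACGTACGTACGTACGTACGA"),
            ("b-1", "ACGTACGTACGTACGAACGA"),
            ("c-1", "ACGAACGTACGAACGTACGT"),
            ("d-1", "ACGAACGAACGAACGTACGT"),
        ]
        t1, _ = bootstrap_support(
            make_alignment("x", rows), "k2p", BootstrapConfig(60, seed=4)
        )
        t2, _ = bootstrap_support(
            make_alignment("x", rows[::-1]), "k2p", BootstrapConfig(60, seed=4)
        )
        s1 = {k: n.support for k, n in t1.bipartitions().items()}
        s2 = {k: n.support for k, n in t2.bipartitions().items()}
        assert set(s1) == set(s2)
        assert all(0 <= v <= 100 for v in s1.values())

    def test_deep_split_high_support(self):
        rng = np.random.default_rng(17)
        L = 500
        base = rng.integers(0, 4, L)
        other = base.copy()
        flip = rng.choice(L, size=40, replace=False)  # ~8% divergence
        other[flip] = (other[flip] + rng.integers(1, 4, 40)) % 4
        bases = np.array(list("ACGT"))

        def noisy(arr, k):
            arr = arr.copy()
            cols = rng.choice(L, size=k, replace=False)
            arr[cols] = (arr[cols] + rng.integers(1, 4, k)) % 4
            return "".join(bases[arr])

        aln = make_alignment(
            "x",
            [
                ("a-1", noisy(base, 2)),
                ("a-2", noisy(base, 2)),
                ("b-1", noisy(other, 2)),
                ("b-2", noisy(other, 2)),
            ],
        )
        tree, _ = bootstrap_support(aln, "k2p", BootstrapConfig(100, seed=5))
        split = frozenset({"b-1", "b-2"})
        support = tree.bipartitions()[split].support
        assert support >= 95

    def test_too_few_records_rejected(self):
        aln = make_alignment("x", [("a-1", "ACGT"), ("b-1", "ACGA")])
        with pytest.raises(TreeError):
            bootstrap_support(aln, "k2p", BootstrapConfig(10, seed=1))


def test_rooted_tree_monophyly_helper():
    d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
    rooted = root_with_outgroup(
        neighbor_joining(DistanceMatrix(list("ABCD"), d, "p")), ["D"]
    )
    assert is_monophyletic(rooted, {"A", "B"})
    assert not is_monophyletic(rooted, {"A", "C"})
    assert is_monophyletic(rooted, {"A"})
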