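"""Neighbor-joining inference, outgroup rooting and nonparametric bootstrap.

Saitou-Nei agglomeration on a distance matrix: repeatedly join the pair
minimising Q(i, j) = (m - 2) d(i, j) - r(i) - r(j).  Ties in the Q minimum
are broken on the lexicographically smallest pair of cluster keys (a
cluster's key is the alphabetically first leaf it contains), so runs are
reproducible.  Negative limb lengths are clamped to zero without
redistribution to the adjacent edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix, NoOverlapError, distances_from_matrix
from .seqio import Alignment
from .tree import Node, Tree, TreeError


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Unrooted NJ tree; n=2 gives a single edge, n=3 the closed-form star."""
    labels = dm.labels
    n = len(labels)
    if n < 2:
        raise TreeError("need at least 2 labels")
    if n == 2:
        root = Node()
        root.add(Node(labels[0], float(dm.d[0, 1])))
        root.add(Node(labels[1], 0.0))
        return Tree(root, rooted=False)

    D = dm.d.astype(float).copy()
    nodes: list[Node] = [Node(name) for name in labels]
    keys: list[str] = list(labels)  # alphabetically first leaf per cluster
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qmin = Q[iu].min()
        ties = [
            (ai, aj)
            for ai, aj in zip(*iu)
            if Q[ai, aj] <= qmin + 1e-12 * max(1.0, abs(qmin))
        ]
        ai, aj = min(ties, key=lambda t: tuple(sorted((keys[active[t[0]]], keys[active[t[1]]]))))
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = Node()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(0.0, li)
        child_j.length = max(0.0, lj)
        parent.add(child_i)
        parent.add(child_j)
        # distances from the new cluster to the remaining ones
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    root = Node()
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, limb in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(0.0, limb)
        root.add(nodes[idx])
    return Tree(root, rooted=False)


def unroot(tree: Tree) -> Tree:
    """Collapse a degree-2 root into the adjacent trifurcation (copy)."""
    t = tree.copy()
    root = t.root
    if len(root.children) != 2:
        t.rooted = False
        return t
    first, second = root.children
    keep, fold = (first, second) if not first.is_leaf else (second, first)
    if keep.is_leaf:  # two-leaf tree: nothing to collapse
        t.rooted = False
        return t
    fold.length += keep.length
    keep.length = 0.0
    keep.parent = None
    keep.support = None
    keep.add(fold)
    return Tree(keep, rooted=False)


def root_with_outgroup(tree: Tree, outgroup_vouchers) -> Tree:
    """Root on the edge separating the outgroup, splitting its length equally."""
    outgroup = frozenset(outgroup_vouchers)
    all_leaves = tree.leaf_names()
    unknown = outgroup - all_leaves
    if unknown:
        raise TreeError(f"outgroup vouchers not in tree: {sorted(unknown)}")
    if outgroup == all_leaves:
        raise TreeError("outgroup covers every leaf; no ingroup remains")
    t = unroot(tree)

    if len(all_leaves) == 2:
        # single edge: total length is split equally across the new root
        (a, b) = t.root.children if t.root.children else (None, None)
        total = a.length + b.length
        ing, out = (a, b) if b.name in outgroup else (b, a)
        new_root = Node()
        new_root.add(Node(ing.name, total / 2.0))
        new_root.add(Node(out.name, total / 2.0))
        return Tree(new_root, rooted=True)

    target = None
    outgroup_is_child_side = True
    for node in t.root.walk():
        if node is t.root:
            continue
        side = node.leaf_names()
        if side == outgroup:
            target, outgroup_is_child_side = node, True
            break
        if side == all_leaves - outgroup:
            target, outgroup_is_child_side = node, False
            break
    if target is None:
        raise TreeError("outgroup not monophyletic")

    parent = target.parent
    parent.children.remove(target)
    target.parent = None
    half = target.length / 2.0
    target.length = half
    edge_support = target.support if not target.is_leaf else None

    # walk the old parent chain up to the old top, then flip every edge so
    # each former parent hangs below its former child
    chain: list[Node] = []
    node = parent
    while node is not None:
        chain.append(node)
        node = node.parent
    original = [(n.length, n.support) for n in chain]
    for k in range(len(chain) - 1):
        chain[k + 1].children.remove(chain[k])
    for n in chain:
        n.parent = None
    pending = (half, edge_support)
    for k, n in enumerate(chain):
        n.length, n.support = pending
        pending = original[k]
        if k + 1 < len(chain):
            n.add(chain[k + 1])
    chain_top = chain[0]
    new_root = Node()

    _suppress_unifurcations(chain_top)
    if outgroup_is_child_side:
        ingroup_side, outgroup_side = chain_top, target
    else:
        ingroup_side, outgroup_side = target, chain_top
    new_root.add(ingroup_side)
    new_root.add(outgroup_side)
    return Tree(new_root, rooted=True)


def _suppress_unifurcations(node: Node) -> None:
    """Merge any chain node left with a single child (edge lengths add)."""
    stack = [node]
    while stack:
        cur = stack.pop()
        while len(cur.children) == 1:
            only = cur.children[0]
            cur.name = only.name
            cur.length += only.length
            cur.support = only.support if only.support is not None else cur.support
            cur.children = only.children
            for ch in cur.children:
                ch.parent = cur
        stack.extend(cur.children)


@dataclass
class BootstrapDiagnostics:
    replicates: int
    redrawn: int = 0
    seed: int = 0


def bootstrap_support(
    aln: Alignment,
    model: str = "k2p",
    cfg: BootstrapConfig = BootstrapConfig(),
    *,
    deletion: str = "pairwise",
) -> tuple[Tree, BootstrapDiagnostics]:
    """NJ tree from the full alignment with supports from column resampling.

    Each replicate resamples columns with replacement, rebuilds the distance
    matrix and NJ tree, and scores the original tree's internal bipartitions.
    Support = round(100 * count / replicates), mapped onto the original tree.
    Replicates in which some pair loses all comparable sites are redrawn and
    counted in the diagnostics.
    """
    if len(aln.records) < 3:
        raise TreeError("bootstrap needs an alignment with >= 3 records")
    from .seqio import MISSING

    mat = aln.matrix()
    if deletion == "complete":
        mat = mat[:, ~np.any(mat == MISSING, axis=0)]
    labels = aln.vouchers
    tree = neighbor_joining(distances_from_matrix(mat, labels, model))
    splits = tree.bipartitions()
    counts = {split: 0 for split in splits}

    rng = np.random.default_rng(cfg.seed)
    diag = BootstrapDiagnostics(cfg.replicates, seed=cfg.seed)
    L = mat.shape[1]
    done = 0
    while done < cfg.replicates:
        cols = rng.integers(0, L, size=L)
        try:
            rep_dm = distances_from_matrix(mat[:, cols], labels, model)
        except NoOverlapError:
            diag.redrawn += 1
            continue
        rep_splits = neighbor_joining(rep_dm).bipartitions().keys()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
        done += 1

    for split, node in splits.items():
        node.support = int(round(100.0 * counts[split] / cfg.replicates))
    return tree, diag
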