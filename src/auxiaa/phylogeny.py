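"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap.

The tree over the family's proteins is built from a supplied multiple
alignment by neighbor joining on uncorrected p-distances (pairwise
deletion of gapped columns).  Internal-edge support comes from
site-resampled bootstrap replicates, and tightly supported cherries are
suggested as candidate whole-genome-duplication paralog pairs.

Reproducibility rules: taxa are ordered lexicographically inside the
algorithm (so results do not depend on input order), Q-matrix ties are
broken by the smallest label pair, and negative branch-length estimates
are clamped to zero with the deficit moved to the sibling branch.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ValidationError

log = logging.getLogger("auxiaa")

GAP = "-"


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("distance matrix contains non-finite entries")
        if np.any(self.d < 0):
            raise ValidationError("distance matrix contains negative entries")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")

    def reordered(self, labels: tuple[str, ...]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.d[np.ix_(idx, idx)])


class TreeNode:
    """Node of an (un)rooted tree; ``length`` is the branch above."""

    __slots__ = ("label", "length", "support", "children")

    def __init__(self, label=None, length=None, support=None, children=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[TreeNode] = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leafset(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        return frozenset().union(*(c.leafset() for c in self.children))


@dataclass
class PhyloTree:
    """Unrooted tree stored with a trifurcating root; bootstrap support
    (percent) lives on internal nodes."""

    root: TreeNode
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = tuple(sorted(self.root.leafset()))

    # -- traversal helpers -------------------------------------------------
    def nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes() if not n.is_leaf and n is not self.root]

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Canonical bipartition (side not holding the reference taxon)
        for every internal edge."""
        ref = min(self.labels)
        full = frozenset(self.labels)
        out = {}
        for n in self.internal_nodes():
            side = n.leafset()
            key = side if ref not in side else full - side
            out[key] = n
        return out

    # -- output ------------------------------------------------------------
    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                sup = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){sup}"
            if node.length is not None:
                body += f":{node.length:.10g}"
            return body

        return fmt(self.root) + ";"

    def leaf_distances(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Patristic (path-length) distances between all leaf pairs."""
        # undirected adjacency over node ids
        adj: dict[int, list[tuple[TreeNode, float]]] = {}
        by_id: dict[int, TreeNode] = {}

        def walk(n: TreeNode) -> None:
            by_id[id(n)] = n
            adj.setdefault(id(n), [])
            for c in n.children:
                adj.setdefault(id(c), [])
                adj[id(n)].append((c, c.length or 0.0))
                adj[id(c)].append((n, c.length or 0.0))
                walk(c)

        walk(self.root)
        leaves = {n.label: n for n in by_id.values() if n.is_leaf}
        labels = tuple(sorted(leaves))
        k = len(labels)
        D = np.zeros((k, k))
        for i, lab in enumerate(labels):
            # DFS from each leaf
            dist = {id(leaves[lab]): 0.0}
            stack = [leaves[lab]]
            while stack:
                n = stack.pop()
                for m, w in adj[id(n)]:
                    if id(m) not in dist:
                        dist[id(m)] = dist[id(n)] + w
                        stack.append(m)
            for j, lab2 in enumerate(labels):
                D[i, j] = dist[id(leaves[lab2])]
        np.fill_diagonal(D, 0.0)
        return labels, D


# ---------------------------------------------------------------------------
# distances

def _alignment_array(records: list[tuple[str, str]]) -> tuple[tuple[str, ...], np.ndarray]:
    if len(records) < 3:
        raise InputError("alignment must contain at least 3 taxa")
    labels = tuple(r[0] for r in records)
    lengths = {len(r[1]) for r in records}
    if len(lengths) != 1:
        raise InputError(f"alignment rows have unequal lengths: {sorted(lengths)}")
    arr = np.array([list(r[1]) for r in records])
    return labels, arr


def pdistance_matrix(records: list[tuple[str, str]]) -> DistanceMatrix:
    """Uncorrected p-distances with pairwise deletion of gapped sites.

    ``d[i][j]`` = mismatches / compared sites over columns where neither
    row has a gap; a pair with zero comparable sites is an error.
    """
    labels, arr = _alignment_array(records)
    return _pdistance_from_array(labels, arr)


def _pdistance_from_array(labels: tuple[str, ...], arr: np.ndarray) -> DistanceMatrix:
    n = arr.shape[0]
    nogap = arr != GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = nogap[i] & nogap[j]
            nsites = int(valid.sum())
            if nsites == 0:
                raise InputError(
                    f"no comparable (gap-free) sites between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = np.mean(arr[i][valid] != arr[j][valid])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    For an additive distance matrix the returned tree reproduces all
    leaf-to-leaf path lengths exactly.  Ties in the Q criterion are
    broken by the lexicographically smallest label pair (each cluster is
    keyed by its smallest member), and negative branch estimates are
    clamped to zero with the deficit shifted to the sibling branch so
    the joined pair's path length is preserved.
    """
    if len(dm.labels) < 3:
        raise InputError("neighbor joining requires at least 3 taxa")
    dm = dm.reordered(tuple(sorted(dm.labels)))
    n = len(dm.labels)
    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = dm.d
    nodes: dict[int, TreeNode] = {i: TreeNode(label=dm.labels[i]) for i in range(n)}
    keys: dict[int, str] = {i: dm.labels[i] for i in range(n)}
    active = list(range(n))
    nxt = n

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    ka, kb = keys[active[a]], keys[active[b]]
                    pair_key = (min(ka, kb), max(ka, kb))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        u = TreeNode(children=[ni, nj] if keys[i] <= keys[j] else [nj, ni])
        nodes[nxt] = u
        keys[nxt] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[nxt, k] = D[k, nxt] = duk
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    # trifurcating root over the last three clusters
    x, y, z = sorted(active, key=lambda k: keys[k])
    dxy, dxz, dyz = D[x, y], D[x, z], D[y, z]
    lx = max(0.0, 0.5 * (dxy + dxz - dyz))
    ly = max(0.0, 0.5 * (dxy + dyz - dxz))
    lz = max(0.0, 0.5 * (dxz + dyz - dxy))
    for k, l in ((x, lx), (y, ly), (z, lz)):
        nodes[k].length = l
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    return PhyloTree(root=root, labels=dm.labels)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(
    alignment: list[tuple[str, str]], n_replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree of the full alignment with bootstrap supports.

    Alignment columns are resampled with replacement ``n_replicates``
    times; each internal edge of the full-data tree is labeled with the
    percentage of replicate trees containing the same bipartition.
    Replicates use one RNG stream seeded by ``seed``, so supports are
    reproducible and independent of taxon order.
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    labels, arr = _alignment_array(alignment)
    order = np.argsort(np.array(labels))
    labels = tuple(str(l) for l in np.array(labels)[order])
    arr = arr[order]
    L = arr.shape[1]
    full = neighbor_joining(_pdistance_from_array(labels, arr))
    biparts = full.bipartitions()
    counts = {key: 0 for key in biparts}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = neighbor_joining(_pdistance_from_array(labels, arr[:, cols]))
        rep_keys = set(rep.bipartitions())
        for key in counts:
            if key in rep_keys:
                counts[key] += 1
    for key, node in biparts.items():
        node.support = 100.0 * counts[key] / n_replicates
    log.info(
        "bootstrap: %d replicates over %d taxa, %d internal edges",
        n_replicates, len(labels), len(biparts),
    )
    return full


def suggest_paralog_pairs(tree: PhyloTree, min_support: float = 50.0) -> list[tuple[str, str]]:
    """Leaf pairs that are mutual sisters across a well-supported edge.

    A cherry (internal node with exactly two leaf children) whose edge
    support meets ``min_support`` suggests a retained duplicate pair.
    Pairs are disjoint by construction.
    """
    pairs = []
    for node in tree.internal_nodes():
        if len(node.children) == 2 and all(c.is_leaf for c in node.children):
            if node.support is not None and node.support >= min_support:
                pairs.append(tuple(sorted(c.label for c in node.children)))
    return sorted(pairs)
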