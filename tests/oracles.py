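"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a result by exhaustive enumeration or direct
arithmetic, independently of the library's search strategy.
"""
from __future__ import annotations

import itertools
import re

import numpy as np


# ---------------------------------------------------------------------------
# motif scanning

def substring_positions(seq: str, motif: str) -> list[int]:
    """All (overlapping) occurrences by per-position string comparison."""
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]


def sliding_window_domains(protein: str, profiles) -> dict:
    """Leftmost full / split / partial domain spans found by trying a
    re.match at every single position (no search shortcuts)."""

    def leftmost(pattern: str, start: int = 0):
        prog = re.compile(pattern)
        for i in range(start, len(protein) + 1):
            m = prog.match(protein, i)
            if m:
                return i, m.end()
        return None

    spans = {}
    for dom, prof in profiles.items():
        hit = leftmost(prof.full)
        if hit:
            spans[dom] = (hit[0], hit[1], True, False)
            continue
        if prof.split_parts is not None:
            a = leftmost(prof.split_parts[0])
            if a:
                b = leftmost(prof.split_parts[1], a[1])
                if b and b[0] - a[1] <= prof.split_max_gap:
                    spans[dom] = (a[0], b[1], True, True)
                    continue
        if prof.partial is not None:
            hit = leftmost(prof.partial)
            if hit:
                spans[dom] = (hit[0], hit[1], False, False)
    return spans


# ---------------------------------------------------------------------------
# phylogeny

def random_additive_tree(n: int, rng: np.random.Generator,
                         lo: float = 0.5, hi: float = 2.0):
    """Random binary unrooted tree; returns (labels, D, bipartitions)
    where D holds exact path lengths and bipartitions the non-trivial
    splits (as frozensets of the side without the first label)."""
    labels = [f"T{i:02d}" for i in range(n)]
    D = {}
    clusters = [({l}, {l: 0.0}) for l in labels]  # (leafset, leaf->dist to cluster root)
    splits = []
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        (sa, da), (sb, db) = clusters[i], clusters[j]
        la, lb = rng.uniform(lo, hi, 2)
        for l1, d1 in da.items():
            for l2, d2 in db.items():
                D[frozenset((l1, l2))] = d1 + la + d2 + lb
        merged = {**{l: d + la for l, d in da.items()},
                  **{l: d + lb for l, d in db.items()}}
        if len(clusters) > 2:
            splits.append(frozenset(sa | sb))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [(sa | sb, merged)]
    full = frozenset(labels)
    ref = min(labels)
    canon = set()
    for s in splits:
        if 1 < len(s) < n - 1:
            canon.add(s if ref not in s else full - s)
    M = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        M[a, b] = M[b, a] = D[frozenset((labels[a], labels[b]))]
    return labels, M, canon


def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies as frozensets of canonical
    bipartitions (3, 15, 105, ... for 4, 5, 6 taxa)."""
    labels = list(labels)
    ref = min(labels)
    full = frozenset(labels)

    def canon(side):
        side = frozenset(side)
        return side if ref not in side else full - side

    # grow by inserting each taxon into every edge of the current tree;
    # trees are edge lists; node ids grow monotonically so sorting the
    # degree-1 nodes recovers the label insertion order
    trees = [[(0, 3), (1, 3), (2, 3)]]  # nodes 0..2 = first three leaves
    for _ in range(3, len(labels)):
        new_trees = []
        for edges in trees:
            n_nodes = max(max(e) for e in edges) + 1
            for k, (u, v) in enumerate(edges):
                mid, leaf = n_nodes, n_nodes + 1
                new = [e for ei, e in enumerate(edges) if ei != k]
                new += [(u, mid), (mid, v), (mid, leaf)]
                new_trees.append(new)
        trees = new_trees
    out = []
    for edges in trees:
        deg = {}
        for u, v in edges:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        leaves = sorted(u for u, d in deg.items() if d == 1)
        leaf_name = dict(zip(leaves, labels))
        adj = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)

        def side_of(u, v):
            # leaves reachable from v without crossing u
            seen_n, stack, found = {u, v}, [v], []
            while stack:
                x = stack.pop()
                if deg[x] == 1:
                    found.append(leaf_name[x])
                for y in adj[x]:
                    if y not in seen_n:
                        seen_n.add(y)
                        stack.append(y)
            return found

        biparts = set()
        for u, v in edges:
            side = side_of(u, v)
            if 1 < len(side) < len(labels) - 1:
                biparts.add(canon(side))
        out.append((edges, frozenset(biparts)))
    # deduplicate by bipartition set
    uniq = {}
    for edges, bip in out:
        uniq[bip] = edges
    return uniq  # {frozenset of bipartitions: edge list}


def least_squares_sse(edges, labels, M):
    """Ordinary least-squares fit of branch lengths to distances for a
    fixed topology; returns the sum of squared residuals."""
    deg = {}
    for u, v in edges:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    leaves = sorted(u for u, d in deg.items() if d == 1)
    leaf_name = dict(zip(leaves, labels))
    name_leaf = {v: k for k, v in leaf_name.items()}
    adj = {}
    for ei, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, ei))
        adj.setdefault(v, []).append((u, ei))

    def path_edges(a, b):
        # DFS path from leaf a to leaf b
        stack = [(a, [])]
        seen = {a}
        while stack:
            x, path = stack.pop()
            if x == b:
                return path
            for y, ei in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append((y, path + [ei]))
        raise AssertionError

    pairs = list(itertools.combinations(range(len(labels)), 2))
    X = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for ei in path_edges(name_leaf[labels[i]], name_leaf[labels[j]]):
            X[r, ei] = 1.0
        y[r] = M[i, j]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


# ---------------------------------------------------------------------------
# simple statistics

def ols_r2(x, y):
    """Coefficient of determination of y on x by direct arithmetic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    return r**2
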