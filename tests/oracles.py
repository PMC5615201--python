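"""Independent brute-force oracles for tree tests.

Unrooted topologies over n leaves are enumerated by sequential leaf
insertion (3, 15, 105, ... trees); each is scored by an ordinary
least-squares fit of branch lengths to the observed distances. On an
additive matrix exactly one topology attains zero residual, so the
minimum-SSE topology plus its fitted lengths is a complete oracle for
neighbor joining.
"""

from __future__ import annotations

import numpy as np


def enumerate_topologies(n: int) -> list[list[tuple[int, int]]]:
    """All unrooted binary topologies on leaves 0..n-1 as edge lists.

    Internal nodes are numbered from n upward.
    """
    if n < 3:
        raise ValueError("need at least 3 leaves")
    trees = [([(0, n), (1, n), (2, n)], n + 1)]
    for leaf in range(3, n):
        nxt_trees = []
        for edges, nxt in trees:
            for k, (u, v) in enumerate(edges):
                new_edges = edges[:k] + edges[k + 1 :]
                new_edges += [(u, nxt), (v, nxt), (leaf, nxt)]
                nxt_trees.append((new_edges, nxt + 1))
        trees = nxt_trees
    return [edges for edges, _ in trees]


def _paths(edges: list[tuple[int, int]], n_leaves: int) -> dict[tuple[int, int], list[int]]:
    """Edge-index path between every leaf pair, by DFS over the adjacency."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    out = {}
    for a in range(n_leaves):
        stack = [(a, -1, [])]
        while stack:
            node, parent, path = stack.pop()
            if node < n_leaves and node > a:
                out[(a, node)] = path
            for nbr, eidx in adj[node]:
                if nbr != parent:
                    stack.append((nbr, node, path + [eidx]))
    return out

def ls_fit(edges: list[tuple[int, int]], D: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares branch lengths and SSE for one topology."""
    n = D.shape[0]
    paths = _paths(edges, n)
    pairs = sorted(paths)
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([D[a, b] for a, b in pairs])
    for row, pair in enumerate(pairs):
        A[row, paths[pair]] = 1.0
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    sse = float(np.sum((A @ lengths - y) ** 2))
    return sse, lengths


def best_ls_tree(D: np.ndarray) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Exhaustive minimum-SSE topology with its fitted branch lengths."""
    best = None
    for edges in enumerate_topologies(D.shape[0]):
        sse, lengths = ls_fit(edges, D)
        if best is None or sse < best[0]:
            best = (sse, edges, lengths)
    return best[1], best[2]


def edge_splits(
    edges: list[tuple[int, int]], lengths: np.ndarray, n_leaves: int, labels
) -> dict[frozenset, float]:
    """Map each edge to (leaf-label set on the side away from leaf 0) -> length."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    def leaves_below(node: int, parent: int) -> set[int]:
        if node < n_leaves:
            return {node}
        out: set[int] = set()
        for nbr, _ in adj[node]:
            if nbr != parent:
                out |= leaves_below(nbr, node)
        return out

    result = {}
    for idx, (u, v) in enumerate(edges):
        side = leaves_below(v, u)
        if 0 in side:
            side = leaves_below(u, v)
        result[frozenset(labels[i] for i in side)] = float(lengths[idx])
    return result


def random_additive_tree(
    n: int, rng: np.random.Generator, lo: float = 0.05, hi: float = 0.5
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Random topology + positive branch lengths + its exact distance matrix."""
    topologies = None
    # Build a random topology by random leaf insertion (uniform over trees).
    edges = [(0, n), (1, n), (2, n)]
    nxt = n + 1
    for leaf in range(3, n):
        k = int(rng.integers(0, len(edges)))
        u, v = edges.pop(k)
        edges += [(u, nxt), (v, nxt), (leaf, nxt)]
        nxt += 1
    lengths = rng.uniform(lo, hi, size=len(edges))
    paths = _paths(edges, n)
    D = np.zeros((n, n))
    for (a, b), path in paths.items():
        D[a, b] = D[b, a] = lengths[path].sum()
    return edges, lengths, D
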