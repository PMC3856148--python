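"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths (and, where possible, the
libraries) they check: hypergeometric probabilities by explicit enumeration
of draws, betweenness by pairwise shortest-path counting from scratch,
coreness by literal recursive deletion, and the walk fixed point by a dense
linear solve.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def hypergeom_pmf_enum(N: int, K: int, n: int) -> np.ndarray:
    """pmf over k = 0..n by enumerating all C(N, n) draws.

    Items 0..K-1 carry the feature; a draw's k is the number of its items
    below K.  Exact rational counts converted to float at the end.
    """
    counts = np.zeros(n + 1, dtype=np.int64)
    for combo in itertools.combinations(range(N), n):
        k = sum(1 for x in combo if x < K)
        counts[k] += 1
    return counts / counts.sum()


def hypergeom_all_k_counts(N: int, n: int) -> np.ndarray:
    """counts[K, k]: draws of size n from N items with k of the first K.

    One enumeration pass serves every K: for a sorted draw, the count of
    elements < K is a bisection.  Returns an integer array of shape
    (N+1, n+1).
    """
    counts = np.zeros((N + 1, n + 1), dtype=np.int64)
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(N), n)),
        dtype=np.int64,
    ).reshape(-1, max(n, 1)) if n > 0 else np.zeros((1, 0), dtype=np.int64)
    for K in range(N + 1):
        k = (combos < K).sum(axis=1) if n > 0 else np.zeros(len(combos), dtype=np.int64)
        np.add.at(counts[K], k, 1)
    return counts


def _bfs_sigma(adj: dict, s) -> tuple[dict, dict]:
    """Distances and shortest-path counts from s by breadth-first search."""
    dist = {s: 0}
    sigma = {s: 1}
    q = deque([s])
    while q:
        v = q.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                sigma[u] = 0
                q.append(u)
            if dist[u] == dist[v] + 1:
                sigma[u] += sigma[v]
    return dist, sigma


def brute_betweenness(graph, normalized: bool = True) -> dict:
    """g(v) = sum over unordered pairs s<t of sigma_st(v)/sigma_st.

    sigma_st(v) = sigma_sv * sigma_vt when v lies on a shortest s-t path
    (d(s,v) + d(v,t) = d(s,t)), else 0.  Pairs in different components
    contribute nothing.  O(n^2) BFS + O(n^3) accumulation.
    """
    nodes = sorted(graph.nodes)
    adj = {v: sorted(graph.neighbors(v)) for v in nodes}
    dist, sigma = {}, {}
    for s in nodes:
        dist[s], sigma[s] = _bfs_sigma(adj, s)
    g = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v == s or v == t:
                    continue
                if (
                    v in dist[s]
                    and v in dist[t]
                    and dist[s][v] + dist[t][v] == d_st
                ):
                    g[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    if normalized:
        n = len(nodes)
        scale = (n - 1) * (n - 2) / 2
        if scale > 0:
            g = {v: val / scale for v, val in g.items()}
    return g


def brute_coreness(graph) -> dict:
    """coreness(v) = max k at which v survives recursive deletion of
    degree-<k nodes, found by re-running the peel at every k."""
    core = {v: 0 for v in graph.nodes}
    max_deg = max((d for _, d in graph.degree()), default=0)
    for k in range(1, max_deg + 1):
        alive = set(graph.nodes)
        changed = True
        while changed:
            changed = False
            for v in sorted(alive):
                deg = sum(1 for u in graph.neighbors(v) if u in alive)
                if deg < k:
                    alive.discard(v)
                    changed = True
        for v in alive:
            core[v] = k
    return core


def rwr_dense_solve(network, x0: np.ndarray, r: float) -> np.ndarray:
    """Fixed point of the restart walk by direct dense inversion:
    (I - (1-r) W) x = r x0 with W the column-normalised weight matrix."""
    n = network.number_of_nodes()
    A = np.zeros((n, n))
    for a, b, w in network.graph.edges(data="weight"):
        ia, ib = network.index[a], network.index[b]
        A[ia, ib] = w
        A[ib, ia] = w
    W = A / A.sum(axis=0, keepdims=True)
    return np.linalg.solve(np.eye(n) - (1 - r) * W, r * x0)
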