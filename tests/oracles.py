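"""Brute-force oracles for network metrics, independent of the implementation.

Everything here works from a raw adjacency matrix with explicit enumeration
(BFS by hand, DFS path counting, power iteration, triple counting) so that
the package's metric functions can be checked against a second route on
small graphs.
"""

import itertools

import numpy as np


def bf_shortest_dists(adj_list, n, src, lengths=None):
    """BFS distances (unweighted)."""
    dist = [None] * n
    dist[src] = 0
    frontier = [src]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj_list[u]:
                if dist[v] is None:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def bf_betweenness(W):
    """Betweenness by explicit enumeration of all shortest paths (binary)."""
    n = W.shape[0]
    A = (W != 0)
    A = A | A.T
    adj = [list(np.where(A[u])[0]) for u in range(n)]
    score = np.zeros(n)
    for s in range(n):
        dist_s = bf_shortest_dists(adj, n, s)
        for t in range(s + 1, n):
            if dist_s[t] is None:
                continue
            d = dist_s[t]
            dist_t = bf_shortest_dists(adj, n, t)
            paths = []

            def extend(path):
                u = path[-1]
                if u == t:
                    paths.append(list(path))
                    return
                for v in adj[u]:
                    if v in path:
                        continue
                    # only stay on shortest-path geodesics
                    if dist_s[v] == len(path) and dist_t[v] == d - len(path):
                        path.append(v)
                        extend(path)
                        path.pop()

            extend([s])
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    score[v] += 1.0 / len(paths)
    return score


def bf_eigenvector(W, iters=5000):
    """Principal eigenvector by shifted power iteration, scaled to max 1.

    The shift W + cI (c > spectral radius) makes the dominant eigenvalue
    unique, so the iteration converges even on bipartite graphs whose
    spectrum is symmetric about zero; the eigenvectors are unchanged.
    """
    n = W.shape[0]
    shift = W.sum(axis=1).max() + 1.0
    M = W + shift * np.eye(n)
    v = np.ones(n)
    for _ in range(iters):
        nv = M @ v
        nrm = np.linalg.norm(nv)
        if nrm == 0:
            return np.zeros(n)
        nv = nv / nrm
        if np.allclose(nv, v, rtol=0, atol=1e-13):
            v = nv
            break
        v = nv
    v = np.abs(v)
    return v / v.max() if v.max() > 0 else v


def bf_pagerank(W, damping=0.85, iters=5000):
    """PageRank by explicit stochastic-matrix iteration."""
    n = W.shape[0]
    out = W.sum(axis=1)
    P = np.zeros((n, n))
    for i in range(n):
        if out[i] > 0:
            P[i] = W[i] / out[i]
        else:
            P[i] = 1.0 / n  # dangling: uniform
    r = np.full(n, 1.0 / n)
    for _ in range(iters):
        nr = (1 - damping) / n + damping * (P.T @ r)
        if np.allclose(nr, r, atol=1e-14):
            return nr
        r = nr
    return r


def bf_transitivity(W):
    """3 * triangles / connected triples by direct combination counting."""
    n = W.shape[0]
    A = (W != 0)
    A = A | A.T
    triangles = sum(
        1 for i, j, k in itertools.combinations(range(n), 3)
        if A[i, j] and A[j, k] and A[i, k]
    )
    triples = sum(
        1 for c in range(n)
        for _ in itertools.combinations(np.where(A[c])[0], 2)
    )
    if triples == 0:
        return None
    return 3.0 * triangles / triples


def bf_reach(W, steps):
    """Fraction of other nodes within <= steps hops, by repeated BFS."""
    n = W.shape[0]
    A = (W != 0)
    A = A | A.T
    adj = [list(np.where(A[u])[0]) for u in range(n)]
    out = np.zeros(n)
    for s in range(n):
        dist = bf_shortest_dists(adj, n, s)
        out[s] = sum(1 for t in range(n)
                     if t != s and dist[t] is not None and dist[t] <= steps)
    return out / (n - 1)


def bf_weighted_assortativity_numeric(W, attr):
    """Weighted Pearson correlation over the directed edge list."""
    i, j = np.nonzero(W)
    w = W[i, j]
    xi, xj = attr[i].astype(float), attr[j].astype(float)
    sw = w.sum()
    mx, my = (w * xi).sum() / sw, (w * xj).sum() / sw
    cov = (w * (xi - mx) * (xj - my)).sum() / sw
    sx = np.sqrt((w * (xi - mx) ** 2).sum() / sw)
    sy = np.sqrt((w * (xj - my) ** 2).sum() / sw)
    return cov / (sx * sy)


def bf_spearman(a, b):
    """Rank correlation with average ranks on ties, from first principles."""

    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        sv = np.asarray(v)[order]
        k = 0
        while k < len(v):
            m = k
            while m + 1 < len(v) and sv[m + 1] == sv[k]:
                m += 1
            ranks[order[k:m + 1]] = (k + m) / 2 + 1
            k = m + 1
        return ranks

    ra, rb = avg_ranks(a), avg_ranks(b)
    return np.corrcoef(ra, rb)[0, 1]
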