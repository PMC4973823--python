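"""Node- and network-level metrics.

Most measures exist in a binary and a weighted flavour.  Degree counts a
node's nonzero edges; strength sums its edge weights (on a 0/1 network the
two coincide).  Weighted shortest-path measures treat stronger edges as
shorter: the distance of an edge of weight w is 1/w (configurable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats as sps

from .core import Network

logger = logging.getLogger("asna")

__all__ = [
    "NodeMetricVector",
    "NetworkSummary",
    "degree_strength",
    "betweenness",
    "spectral_centrality",
    "reach",
    "density",
    "assortativity",
    "transitivity",
    "detect_communities",
    "metric_rank_correlation",
    "node_metric_table",
]


@dataclass
class NodeMetricVector:
    metric_name: str
    values: np.ndarray
    registry: object
    weighted: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.registry):
            raise ValueError("metric vector length does not match registry")

    def as_dict(self) -> dict:
        return dict(zip(self.registry.ids, self.values.tolist()))


@dataclass
class NetworkSummary:
    density: float
    transitivity: float | None
    assortativity: dict
    modularity: float | None
    communities: np.ndarray | None


def degree_strength(net: Network, which: str = "strength", direction: str = "total") -> NodeMetricVector:
    """Binary degree (count of edges) or strength (sum of edge weights).

    ``direction`` in/out applies to directed networks only; ``total`` sums
    both for directed networks.
    """
    if direction not in ("total", "in", "out"):
        raise ValueError("direction must be 'total', 'in' or 'out'")
    if direction != "total" and not net.directed:
        raise ValueError("in/out direction is undefined for undirected networks")
    W = net.weights
    M = W if which == "strength" else (W != 0).astype(float)
    if which not in ("strength", "degree"):
        raise ValueError("which must be 'strength' or 'degree'")
    if direction == "in":
        vals = M.sum(axis=0)
    elif direction == "out":
        vals = M.sum(axis=1)
    else:
        vals = M.sum(axis=1) + (M.sum(axis=0) if net.directed else 0)
    return NodeMetricVector(which, vals, net.registry, weighted=(which == "strength"))


def betweenness(net: Network, use_weights: bool = False,
                distance_transform=lambda w: 1.0 / w) -> NodeMetricVector:
    """Shortest-path betweenness; weighted mode converts weights to distances."""
    if np.any(net.weights < 0):
        raise ValueError("betweenness requires non-negative weights")
    g = net.to_networkx()
    if use_weights:
        for _, _, data in g.edges(data=True):
            data["dist"] = distance_transform(data["weight"])
        vals = nx.betweenness_centrality(g, weight="dist", normalized=False)
    else:
        vals = nx.betweenness_centrality(g, weight=None, normalized=False)
    return NodeMetricVector(
        "betweenness", [vals[i] for i in net.registry.ids], net.registry, weighted=use_weights
    )


def spectral_centrality(net: Network, method: str = "eigenvector",
                        damping: float = 0.85) -> NodeMetricVector:
    """Eigenvector centrality (scaled to max 1) or PageRank (sums to 1).

    Eigenvector centrality is computed per connected component (with a
    warning when the graph is disconnected); PageRank divides passed-on
    centrality by out-degree, taming long degree tails.
    """
    if np.any(net.weights < 0):
        raise ValueError("spectral centralities require non-negative weights")
    if method == "pagerank":
        if not 0 < damping < 1:
            raise ValueError("damping must be in (0, 1)")
        g = net.to_networkx()
        pr = nx.pagerank(g, alpha=damping, weight="weight")
        return NodeMetricVector("pagerank", [pr[i] for i in net.registry.ids], net.registry)
    if method != "eigenvector":
        raise ValueError("method must be 'eigenvector' or 'pagerank'")
    W = net.weights if not net.directed else (net.weights + net.weights.T) / 2
    n = net.n
    comp = _components((W != 0))
    if len(set(comp.tolist())) > 1:
        warnings.warn("disconnected network: eigenvector centrality computed per component",
                      stacklevel=2)
    values = np.zeros(n)
    for c in np.unique(comp):
        idx = np.where(comp == c)[0]
        if len(idx) == 1:
            values[idx] = 0.0
            continue
        sub = W[np.ix_(idx, idx)]
        evals, evecs = np.linalg.eigh(sub)
        v = evecs[:, -1]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        values[idx] = np.clip(v, 0, None)
    m = values.max()
    if m > 0:
        values = values / m
    return NodeMetricVector("eigenvector", values, net.registry)


def _components(adj: np.ndarray) -> np.ndarray:
    """Connected-component labels from a boolean adjacency matrix (BFS)."""
    n = adj.shape[0]
    sym = adj | adj.T
    labels = -np.ones(n, dtype=int)
    current = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = current
        while stack:
            u = stack.pop()
            for v in np.where(sym[u])[0]:
                if labels[v] < 0:
                    labels[v] = current
                    stack.append(v)
        current += 1
    return labels


def reach(net: Network, steps: int = 1) -> NodeMetricVector:
    """Fraction of the other N-1 nodes within ``steps`` binary steps."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    n = net.n
    A = (net.weights != 0)
    if not net.directed:
        A = A | A.T
    reached = A.copy()
    frontier = A.copy()
    for _ in range(steps - 1):
        frontier = (frontier.astype(np.int64) @ A.astype(np.int64)) > 0
        reached |= frontier
    np.fill_diagonal(reached, False)
    return NodeMetricVector("reach", reached.sum(axis=1) / (n - 1), net.registry)


def density(net: Network, weighted: bool = True) -> float:
    """Edge count (binary) or total edge weight (weighted) over possible dyads."""
    n = net.n
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    vals = net.dyad_values()
    total = vals.sum() if weighted else (vals != 0).sum()
    return float(total / len(vals))


def assortativity(net: Network, attribute: np.ndarray) -> float:
    """Edge-weight-weighted assortativity of a node attribute.

    Numeric attributes: weighted Pearson correlation of the attribute values
    at the two ends of each edge.  Categorical attributes: Newman's
    assortativity coefficient on the weighted mixing matrix.  Both lie in
    [-1, 1]; a constant attribute is undefined and raises.
    """
    attribute = np.asarray(attribute)
    if len(attribute) != net.n:
        raise ValueError("attribute length does not match network size")
    W = net.weights if net.directed else net.weights  # symmetric counts both directions below
    i, j = np.nonzero(W)
    if len(i) == 0:
        raise ValueError("assortativity undefined on an empty network")
    w = W[i, j]
    if attribute.dtype.kind in "fiu":
        vals = attribute.astype(float)
        if np.ptp(vals) == 0:
            raise ValueError("assortativity undefined for a constant attribute")
        xi, xj = vals[i], vals[j]
        sw = w.sum()
        mx = (w * xi).sum() / sw
        my = (w * xj).sum() / sw
        cov = (w * (xi - mx) * (xj - my)).sum() / sw
        sx = np.sqrt((w * (xi - mx) ** 2).sum() / sw)
        sy = np.sqrt((w * (xj - my) ** 2).sum() / sw)
        if sx == 0 or sy == 0:
            raise ValueError("assortativity undefined (degenerate attribute spread on edges)")
        return float(cov / (sx * sy))
    cats = np.unique(attribute)
    if len(cats) < 2:
        raise ValueError("assortativity undefined for a constant attribute")
    k = len(cats)
    cat_idx = {c: m for m, c in enumerate(cats)}
    e = np.zeros((k, k))
    for a, b, ww in zip(i, j, w):
        e[cat_idx[attribute[a]], cat_idx[attribute[b]]] += ww
    e /= e.sum()
    a_marg = e.sum(axis=1)
    b_marg = e.sum(axis=0)
    ab = (a_marg * b_marg).sum()
    if ab >= 1.0:
        raise ValueError("assortativity undefined (single mixing class)")
    return float((np.trace(e) - ab) / (1 - ab))


def transitivity(net: Network, literal: bool = False) -> float:
    """Global clustering: 3 * triangles / connected triples, on the binarized view.

    ``literal=True`` instead returns closed triads over open (two-edge)
    triads, an alternative ratio that is not bounded by 1.
    """
    A = ((net.weights != 0) | (net.weights.T != 0)).astype(np.int64)
    np.fill_diagonal(A, 0)
    deg = A.sum(axis=1)
    triangles = np.trace(A @ A @ A) / 6.0
    triples = (deg * (deg - 1) / 2).sum()  # paths of length 2, centre-counted
    if literal:
        open_triads = triples - 3 * triangles
        if open_triads == 0:
            raise ValueError("no open triads: literal ratio undefined")
        return float(triangles / open_triads)
    if triples == 0:
        raise ValueError("no connected triples: transitivity undefined")
    return float(3.0 * triangles / triples)


def detect_communities(net: Network):
    """Leading-eigenvector modularity partition (weighted).

    Returns ``(labels, modularity)`` with labels aligned to the registry.
    The underlying spectral split is deterministic for a given matrix.
    """
    if net.directed:
        raise ValueError("community detection expects an undirected network")
    if not np.any(net.weights):
        raise ValueError("cannot partition an empty network")
    g = net.to_igraph()
    clustering = g.community_leading_eigenvector(weights="weight")
    labels = np.asarray(clustering.membership, dtype=int)
    q = g.modularity(clustering.membership, weights="weight")
    return labels, float(q)


def metric_rank_correlation(v1: NodeMetricVector, v2: NodeMetricVector) -> dict:
    """Spearman rho (average ranks on ties) and OLS R^2 between two node metrics."""
    if v1.registry != v2.registry:
        raise ValueError("metric vectors come from different registries")
    a, b = v1.values, v2.values
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant metric")
    rho = sps.spearmanr(a, b).statistic
    r = np.corrcoef(a, b)[0, 1]
    return {"spearman_rho": float(rho), "r_squared": float(r**2)}


def node_metric_table(net: Network, which=("degree", "strength"), attributes=None):
    """Convenience: several node metrics as a DataFrame in registry order."""
    out = {}
    for name in which:
        if name in ("degree", "strength"):
            out[name] = degree_strength(net, which=name).values
        elif name == "betweenness":
            out[name] = betweenness(net, use_weights=net.edge_kind != "binary").values
        elif name in ("eigenvector", "pagerank"):
            out[name] = spectral_centrality(net, method=name).values
        elif name == "reach":
            out[name] = reach(net, steps=2).values
        else:
            raise ValueError(f"unknown node metric {name!r}")
    return pd.DataFrame(out, index=list(net.registry.ids))
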