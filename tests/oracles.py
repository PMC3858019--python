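"""Independent brute-force oracles used to cross-check the implementation.

Everything here works on plain adjacency matrices with numpy only — no
networkx, no package code — so agreement with the package is a genuine
dual-route check.
"""

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by min-plus dynamic programming."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d


def clustering_coefficients(adj: np.ndarray) -> np.ndarray:
    """Per-node C_i by explicit triangle counting; 0 for degree < 2."""
    a = (adj > 0).astype(int)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = len(nbrs)
        if k < 2:
            continue
        links = a[np.ix_(nbrs, nbrs)].sum() / 2
        out[i] = links / (k * (k - 1) / 2)
    return out


def graph_stats(adj: np.ndarray) -> dict:
    """Diameter, average distance over reachable unordered pairs, mean
    clustering, average degree — all from scratch."""
    d = floyd_warshall(adj)
    iu = np.triu_indices(adj.shape[0], k=1)
    finite = d[iu][np.isfinite(d[iu])]
    degrees = (adj > 0).sum(axis=1)
    return {
        "diameter": int(finite.max()),
        "average_distance": float(finite.mean()),
        "average_clustering": float(clustering_coefficients(adj).mean()),
        "average_degree": float(degrees.mean()),
        "path_matrix": d,
    }


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Symmetric Erdős–Rényi adjacency with no self-loops."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return (adj | adj.T).astype(int)


def pairwise_distances_loop(points: np.ndarray) -> np.ndarray:
    """Square Euclidean distance matrix by an explicit double loop."""
    n = len(points)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = float(np.sqrt(((points[i] - points[j]) ** 2).sum()))
    return out
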