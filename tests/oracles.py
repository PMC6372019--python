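"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths (and libraries) used by the
implementation: distances and shortest-path counts come from adjacency
matrix powers, clustering from a triple loop, correlations from textbook
formulas.
"""

from __future__ import annotations

import numpy as np


def bfs_distances(A: np.ndarray) -> np.ndarray:
    """Hop-count distance matrix via adjacency matrix powers:
    d(i,j) = min k with (A^k)[i,j] > 0."""
    A = (np.asarray(A) > 0).astype(np.int64)
    n = A.shape[0]
    D = np.full((n, n), -1, dtype=int)
    np.fill_diagonal(D, 0)
    P = np.eye(n, dtype=np.int64)
    for k in range(1, n):
        P = P @ A
        newly = (P > 0) & (D < 0)
        D[newly] = k
    return D


def shortest_path_counts(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(distances, number of shortest paths) for all pairs.

    A walk of minimal length cannot revisit a vertex, so the number of
    shortest i-j paths equals (A^d(i,j))[i, j].
    """
    A = (np.asarray(A) > 0).astype(object)  # object dtype: exact big ints
    n = A.shape[0]
    D = bfs_distances(A.astype(np.int64))
    powers = [np.eye(n, dtype=object)]
    for _ in range(n):
        powers.append(powers[-1] @ A)
    sigma = np.zeros((n, n), dtype=object)
    for i in range(n):
        for j in range(n):
            if D[i, j] >= 0:
                sigma[i, j] = powers[D[i, j]][i, j]
    return D, sigma


def betweenness_exact(A: np.ndarray) -> np.ndarray:
    """Betweenness by explicit enumeration over ordered (s, t) pairs,
    normalized by (n-1)(n-2)."""
    D, sigma = shortest_path_counts(A)
    n = A.shape[0]
    out = np.zeros(n)
    for v in range(n):
        acc = 0.0
        for s in range(n):
            for t in range(n):
                if s == t or s == v or t == v:
                    continue
                if D[s, v] >= 0 and D[v, t] >= 0 and D[s, v] + D[v, t] == D[s, t]:
                    acc += (sigma[s, v] * sigma[v, t]) / sigma[s, t]
        out[v] = acc / ((n - 1) * (n - 2))
    return out


def clustering_exact(A: np.ndarray) -> np.ndarray:
    A = (np.asarray(A) > 0).astype(int)
    n = A.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.nonzero(A[v])[0]
        k = len(nbrs)
        if k < 2:
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                links += A[nbrs[a], nbrs[b]]
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def mean_path_length_exact(A: np.ndarray) -> np.ndarray:
    D = bfs_distances(A)
    n = A.shape[0]
    if np.any(D < 0):
        raise ValueError("graph is disconnected")
    return (D.sum(axis=1)) / (n - 1)


def pearson_formula(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def random_connected_graph(n: int, p: float, rng) -> np.ndarray:
    """Rejection-sample a connected Erdos-Renyi adjacency matrix."""
    while True:
        A = (rng.random((n, n)) < p).astype(int)
        A = np.triu(A, 1)
        A = A + A.T
        if np.all(bfs_distances(A) >= 0):
            return A
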