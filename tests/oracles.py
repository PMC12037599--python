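"""Independent brute-force oracles for graph metrics and statistics.

Deliberately naive implementations (Floyd-Warshall, triple enumeration,
exhaustive partition search, textbook formulas) used only to check the
package's production code paths on small inputs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall(A) -> np.ndarray:
    A = np.asarray(A, bool)
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    D[A] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def path_length_oracle(A) -> float:
    D = floyd_warshall(A)
    n = D.shape[0]
    vals = [D[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(D[i, j])]
    return float(np.mean(vals))


def global_efficiency_oracle(A) -> float:
    D = floyd_warshall(A)
    n = D.shape[0]
    if n < 2:
        return 0.0
    total = sum(1.0 / D[i, j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(D[i, j]))
    return total / (n * (n - 1))


def nodal_efficiency_oracle(A) -> np.ndarray:
    D = floyd_warshall(A)
    n = D.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(1.0 / D[i, j] for j in range(n)
                     if j != i and np.isfinite(D[i, j])) / (n - 1)
    return out


def clustering_oracle(A) -> np.ndarray:
    """Per-node clustering via explicit triangle enumeration over triples."""
    A = np.asarray(A, bool)
    n = A.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if A[v, u]]
        k = len(nb)
        if k < 2:
            continue
        t = sum(1 for a, b in itertools.combinations(nb, 2) if A[a, b])
        out[v] = 2 * t / (k * (k - 1))
    return out


def local_efficiency_oracle(A) -> float:
    A = np.asarray(A, bool)
    n = A.shape[0]
    vals = []
    for v in range(n):
        nb = [u for u in range(n) if A[v, u]]
        if len(nb) < 2:
            vals.append(0.0)
            continue
        sub = A[np.ix_(nb, nb)]
        vals.append(global_efficiency_oracle(sub))
    return float(np.mean(vals))


def betweenness_oracle(A) -> np.ndarray:
    """Betweenness by shortest-path counting from the distance matrix.

    sigma[s, t] (number of shortest s-t paths) follows the recursion over
    predecessors on the BFS DAG; the through-v count uses
    sigma[s, v] * sigma[v, t] when d(s, v) + d(v, t) = d(s, t).
    Unordered pairs, endpoints excluded, no normalization.
    """
    A = np.asarray(A, bool)
    n = A.shape[0]
    D = floyd_warshall(A)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = sorted((d, t) for t, d in enumerate(D[s]) if np.isfinite(d))
        for d, t in order:
            if t == s:
                continue
            sigma[s, t] = sum(sigma[s, u] for u in range(n)
                              if A[u, t] and D[s, u] == d - 1)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(D[s, t]) or sigma[s, t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if D[s, v] + D[v, t] == D[s, t]:
                bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def _set_partitions(items):
    """All set partitions (Bell number growth; fine for n <= 8)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def modularity_value(A, partition) -> float:
    """Newman Q of a given partition: intra-edge fraction minus degree model."""
    A = np.asarray(A, bool)
    deg = A.sum(axis=1)
    m2 = deg.sum()  # = 2m
    q = 0.0
    for block in partition:
        idx = np.array(sorted(block))
        e_in = A[np.ix_(idx, idx)].sum() / 2
        d_c = deg[idx].sum()
        q += e_in / (m2 / 2) - (d_c / m2) ** 2
    return q


def modularity_oracle(A) -> float:
    """Max Q over all set partitions; exhaustive, so only for n <= 8."""
    n = np.asarray(A).shape[0]
    assert n <= 8, "exhaustive partition search is only feasible for n <= 8"
    return max(modularity_value(A, p) for p in _set_partitions(range(n)))


def pearson_oracle(x, y) -> float:
    """Textbook Pearson formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = math.sqrt(n * (x**2).sum() - x.sum() ** 2) * math.sqrt(
        n * (y**2).sum() - y.sum() ** 2
    )
    return num / den


def ols_residual_oracle(X, y) -> np.ndarray:
    """Residuals via the normal equations, independent of lstsq."""
    X, y = np.asarray(X, float), np.asarray(y, float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


def partial_r_oracle(x, y, Z) -> float:
    """Partial correlation from the inverse of the full correlation matrix."""
    M = np.column_stack([x, y, Z])
    P = np.linalg.inv(np.corrcoef(M, rowvar=False))
    return -P[0, 1] / math.sqrt(P[0, 0] * P[1, 1])
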