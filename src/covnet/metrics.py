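"""Topological metrics on binary brain graphs.

All metrics use the binary, undirected conventions standard for
sparsity-thresholded covariance networks:

* clustering coefficient Cp (Watts-Strogatz): mean over nodes of
  2*triangles / (k*(k-1)), with 0 for degree < 2;
* characteristic path length Lp: mean shortest-path distance over node
  pairs, averaging finite distances only when the graph is disconnected;
* global / local / nodal efficiency (Latora-Marchiori): means of inverse
  distances, with 1/inf = 0, so disconnection is handled natively;
* betweenness centrality: unnormalized, each unordered pair counted once,
  endpoints excluded (a 5-node star's hub scores C(4,2) = 6);
* modularity Q (Newman): best Louvain partition over seeded restarts;
* gamma = Cp/<Cp_rand>, lambda = Lp/<Lp_rand> and the small-world index
  sigma = gamma/lambda, normalized against an ensemble of degree-preserving
  (Maslov-Sneppen double-edge-swap) random graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .networks import BinaryGraph, CovarianceNetwork, graded_graphs

log = logging.getLogger(__name__)

GLOBAL_METRICS = ("Cp", "Lp", "gamma", "lambda", "sigma", "Eglob", "Eloc", "Q")
NODAL_METRICS = ("degree", "nodal_efficiency", "betweenness")

#: global metrics whose value depends on the random-graph null ensemble
NORMALIZED_METRICS = frozenset({"gamma", "lambda", "sigma"})


def _adj(g) -> np.ndarray:
    A = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g)
    return A.astype(bool)


def distances(g) -> np.ndarray:
    """All-pairs shortest-path lengths (unit edges); ``inf`` if unreachable."""
    A = _adj(g)
    n = A.shape[0]
    D = np.where(A, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    reach = A | np.eye(n, dtype=bool)
    A8 = A.astype(np.uint8)
    k = 1
    while True:
        wider = (reach.astype(np.uint8) @ A8) > 0
        wider |= reach
        newly = wider & ~reach
        if not newly.any():
            return D
        k += 1
        D[newly] = k
        reach = wider


def degree(g) -> np.ndarray:
    return _adj(g).sum(axis=1).astype(int)


def local_clustering(g) -> np.ndarray:
    """Per-node clustering coefficient; 0 for nodes with degree < 2."""
    A = _adj(g).astype(np.uint8)
    k = A.sum(axis=1).astype(float)
    closed = ((A @ A) * A).sum(axis=1).astype(float)  # = 2 * triangles per node
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, closed / denom, 0.0)
    return c


def clustering_coefficient(g) -> float:
    """Mean clustering coefficient Cp over all nodes."""
    return float(local_clustering(g).mean())


def characteristic_path_length(g) -> float:
    """Mean shortest-path length over node pairs with a finite path."""
    D = distances(g)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    if not finite.any():
        raise ValidationError("graph has no finite pairwise path")
    if finite.sum() < off.sum():
        log.debug("disconnected graph: Lp averages %d/%d finite pairs",
                  int(finite.sum()), int(off.sum()))
    return float(D[finite].mean())


def _inverse_distances(A: np.ndarray) -> np.ndarray:
    D = distances(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(g) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    A = _adj(g)
    n = A.shape[0]
    if n < 2:
        return 0.0
    return float(_inverse_distances(A).sum() / (n * (n - 1)))


def nodal_efficiency(g) -> np.ndarray:
    """Per node, mean of inverse distances to every other node."""
    A = _adj(g)
    n = A.shape[0]
    return _inverse_distances(A).sum(axis=1) / (n - 1)


def local_efficiency(g) -> float:
    """Mean over nodes of the global efficiency of the neighbor-induced subgraph."""
    A = _adj(g)
    n = A.shape[0]
    vals = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(A[v])
        if nb.size >= 2:
            vals[v] = global_efficiency(A[np.ix_(nb, nb)])
    return float(vals.mean())


def betweenness(g) -> np.ndarray:
    """Unnormalized betweenness centrality (Brandes), unordered-pair convention."""
    A = _adj(g)
    G = nx.from_numpy_array(A)
    bc = nx.betweenness_centrality(G, normalized=False)
    return np.array([bc[i] for i in range(A.shape[0])])


def modularity(g, seed: int = 0, n_restarts: int = 10) -> float:
    """Newman modularity Q of the best Louvain partition over seeded restarts."""
    A = _adj(g)
    if A.sum() == 0:
        raise ValidationError("modularity is undefined for an edgeless graph")
    G = nx.from_numpy_array(A)
    best = -np.inf
    for t in range(n_restarts):
        parts = nx.community.louvain_communities(G, seed=int(seed) + t)
        q = nx.community.modularity(G, parts)
        best = max(best, q)
    return float(best)


def rewire_preserving_degree(g, swaps_per_edge: int = 10, seed: int = 0,
                             rng: np.random.Generator | None = None):
    """Degree-preserving randomization by Maslov-Sneppen double-edge swaps.

    Repeatedly picks two edges (a,b), (c,d) and rewires them to (a,d),
    (c,b), rejecting proposals that would create a self-loop or a duplicate
    edge.  The degree sequence and edge count are preserved exactly; output
    is deterministic given the seed.  Returns the same type as the input.
    """
    A = _adj(g)
    if rng is None:
        rng = np.random.default_rng(seed)
    out = _rewired_adjacency(A, swaps_per_edge, rng)
    if isinstance(g, BinaryGraph):
        return BinaryGraph(adjacency=out, sparsity=g.sparsity, regions=g.regions)
    return out


def _apply_swap_proposals(ei, ej, adj, ps, qs, flips, target, swaps, tries,
                          max_tries):
    """Apply a batch of double-edge-swap proposals in place.

    Pure-Python reference; a numba-compiled twin (identical semantics, same
    proposal stream) is used when available.  Returns updated counters.
    """
    nprop = ps.shape[0]
    k = 0
    while swaps < target and tries < max_tries and k < nprop:
        p, q, f = ps[k], qs[k], flips[k]
        k += 1
        tries += 1
        if p == q:
            continue
        a, b = ei[p], ej[p]
        c, d = ei[q], ej[q]
        if f == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = adj[c, b] = adj[b, c] = True
        if a < d:
            ei[p], ej[p] = a, d
        else:
            ei[p], ej[p] = d, a
        if c < b:
            ei[q], ej[q] = c, b
        else:
            ei[q], ej[q] = b, c
        swaps += 1
    return swaps, tries


try:  # compiled hot loop; permutation tests rewire ~1e5 graphs
    from numba import njit as _njit

    _apply_swap_proposals_fast = _njit(cache=True)(_apply_swap_proposals)
except ImportError:  # pragma: no cover
    _apply_swap_proposals_fast = _apply_swap_proposals


def _rewired_adjacency(A: np.ndarray, swaps_per_edge: int,
                       rng: np.random.Generator) -> np.ndarray:
    n = A.shape[0]
    iu, ju = np.nonzero(np.triu(A, 1))
    m = iu.size
    if m < 2:
        return A.copy()
    ei = iu.astype(np.int64)
    ej = ju.astype(np.int64)
    adj = A.astype(np.bool_).copy()
    target = swaps_per_edge * m
    max_tries = 100 * target
    swaps = tries = 0
    while swaps < target and tries < max_tries:
        batch = min(4 * (target - swaps) + 64, 65536)
        ps = rng.integers(0, m, size=batch)
        qs = rng.integers(0, m, size=batch)
        flips = rng.integers(0, 2, size=batch)
        swaps, tries = _apply_swap_proposals_fast(
            ei, ej, adj, ps, qs, flips, target, swaps, tries, max_tries)
    if swaps < target:
        log.debug("rewiring saturated after %d/%d swaps (%d tries)", swaps, target, tries)
    return adj


@dataclass
class NullEnsemble:
    """Degree-preserving random-graph ensemble configuration."""

    n_random: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def sample(self, g):
        """Yield ``n_random`` rewired adjacency matrices (one shared rng stream)."""
        A = _adj(g)
        rng = np.random.default_rng(self.seed)
        for _ in range(self.n_random):
            yield _rewired_adjacency(A, self.swaps_per_edge, rng)


@dataclass
class GlobalMetrics:
    """Bundle of global metrics for one graph; ``sigma = gamma / lam`` exactly."""

    cp: float
    lp: float
    gamma: float
    lam: float
    sigma: float
    eglob: float
    eloc: float
    q: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Cp": self.cp, "Lp": self.lp, "gamma": self.gamma,
            "lambda": self.lam, "sigma": self.sigma,
            "Eglob": self.eglob, "Eloc": self.eloc, "Q": self.q,
        }


def normalized_global_metrics(g, ensemble: NullEnsemble | None = None,
                              null_graphs=None, n_restarts: int = 10) -> GlobalMetrics:
    """All global metrics for one graph, normalized against its null ensemble.

    ``null_graphs`` may supply explicit null adjacencies (overriding
    ``ensemble``), e.g. for self-normalization checks.
    """
    A = _adj(g)
    cp = clustering_coefficient(A)
    lp = characteristic_path_length(A)
    if null_graphs is None:
        ensemble = ensemble or NullEnsemble()
        null_graphs = ensemble.sample(A)
    cps, lps = [], []
    for R in null_graphs:
        cps.append(clustering_coefficient(R))
        lps.append(characteristic_path_length(R))
    if not cps:
        raise ValidationError("null ensemble is empty")
    cp_rand, lp_rand = float(np.mean(cps)), float(np.mean(lps))
    gamma = cp / cp_rand if cp_rand > 0 else np.inf
    lam = lp / lp_rand
    return GlobalMetrics(
        cp=cp, lp=lp, gamma=gamma, lam=lam, sigma=gamma / lam,
        eglob=global_efficiency(A), eloc=local_efficiency(A),
        q=modularity(A, seed=(ensemble.seed if ensemble else 0), n_restarts=n_restarts),
    )


@dataclass
class MetricCurve:
    """One metric evaluated on each sparsity of a grid, with its AUC."""

    name: str
    grid: np.ndarray
    values: np.ndarray

    @property
    def auc(self) -> float:
        from .inference import auc
        return auc(self.values, self.grid)


def nodal_metric_values(g, metric: str) -> np.ndarray:
    if metric == "degree":
        return degree(g).astype(float)
    if metric == "nodal_efficiency":
        return nodal_efficiency(g)
    if metric == "betweenness":
        return betweenness(g)
    raise ValidationError(f"unknown nodal metric {metric!r}")


def global_metric_values(matrix, grid, metrics=GLOBAL_METRICS, n_random: int = 100,
                         swaps_per_edge: int = 10, seed: int = 0,
                         n_restarts: int = 10) -> dict[str, np.ndarray]:
    """Evaluate the requested global metrics at every sparsity of the grid.

    Null ensembles (for gamma/lambda/sigma) are drawn from a single rng
    stream seeded by ``seed``, so the full curve set is deterministic.
    Only the primitives the requested metrics need are computed.
    """
    metrics = tuple(metrics)
    unknown = set(metrics) - set(GLOBAL_METRICS)
    if unknown:
        raise ValidationError(f"unknown global metric(s): {sorted(unknown)}")
    need_null = bool(set(metrics) & NORMALIZED_METRICS)
    need_cp = need_null or "Cp" in metrics
    need_lp = need_null or "Lp" in metrics
    if need_null and n_random < 1:
        raise ValidationError("normalized metrics require n_random >= 1")
    rng = np.random.default_rng(seed) if need_null else None
    out = {m: [] for m in metrics}
    for i, (s, A) in enumerate(graded_graphs(matrix, np.asarray(grid, float))):
        cp = clustering_coefficient(A) if need_cp else None
        lp = characteristic_path_length(A) if need_lp else None
        if need_null:
            cps, lps = [], []
            for _ in range(n_random):
                R = _rewired_adjacency(A, swaps_per_edge, rng)
                cps.append(clustering_coefficient(R))
                lps.append(characteristic_path_length(R))
            gamma = cp / np.mean(cps)
            lam = lp / np.mean(lps)
        for m in metrics:
            if m == "Cp":
                v = cp
            elif m == "Lp":
                v = lp
            elif m == "gamma":
                v = gamma
            elif m == "lambda":
                v = lam
            elif m == "sigma":
                v = gamma / lam
            elif m == "Eglob":
                v = global_efficiency(A)
            elif m == "Eloc":
                v = local_efficiency(A)
            elif m == "Q":
                v = modularity(A, seed=seed + 1000 + i, n_restarts=n_restarts)
            out[m].append(float(v))
    return {m: np.asarray(v) for m, v in out.items()}


def metrics_over_sparsities(net: CovarianceNetwork, grid,
                            global_metrics=GLOBAL_METRICS,
                            nodal_metrics=(), n_random: int = 100,
                            swaps_per_edge: int = 10, seed: int = 0,
                            n_restarts: int = 10):
    """Metric curves for one covariance network over a sparsity grid.

    Returns ``(global_curves, nodal_tables)``: a dict of
    :class:`MetricCurve` keyed by metric name, and a dict of DataFrames
    (sparsity x region) for each requested nodal metric.
    """
    grid = np.asarray(grid, float)
    gvals = global_metric_values(net.matrix, grid, metrics=global_metrics,
                                 n_random=n_random, swaps_per_edge=swaps_per_edge,
                                 seed=seed, n_restarts=n_restarts)
    curves = {m: MetricCurve(m, grid, v) for m, v in gvals.items()}
    nodal: dict[str, pd.DataFrame] = {}
    for metric in nodal_metrics:
        rows = [nodal_metric_values(A, metric) for _, A in graded_graphs(net.matrix, grid)]
        labels = net.regions.labels if net.regions else range(net.matrix.shape[0])
        nodal[metric] = pd.DataFrame(rows, index=grid, columns=list(labels))
    return curves, nodal
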