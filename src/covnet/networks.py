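"""Group-level covariance networks and sparsity thresholding.

A structural covariance network for one group is the regions x regions
matrix of absolute Pearson correlations of corrected morphometric values
across that group's subjects (diagonal fixed at 0).  Weighted matrices are
converted to binary undirected graphs by keeping, at sparsity ``s``, the
``k = round(s * R(R-1)/2)`` strongest edges — so any two groups thresholded
at the same sparsity have exactly the same node and edge counts, and edge
sets are nested along an increasing sparsity grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import MorphometricCohort
from .regions import RegionSet


@dataclass
class CovarianceNetwork:
    """Absolute-Pearson covariance matrix for one group."""

    group: object
    matrix: np.ndarray  # (R, R), symmetric, diag 0, entries in [0, 1]
    n_subjects: int
    regions: RegionSet | None = None

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("covariance matrix must be square")
        if not np.allclose(m, m.T):
            raise ValidationError("covariance matrix must be symmetric")
        if np.diag(m).any():
            raise ValidationError("covariance matrix diagonal must be zero")
        if (m < 0).any() or (m > 1).any():
            raise ValidationError("absolute correlations must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        labels = self.regions.labels if self.regions else range(self.n_regions)
        return pd.DataFrame(self.matrix, index=list(labels), columns=list(labels))


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph at a fixed sparsity; nodes are regions."""

    adjacency: np.ndarray  # (R, R) bool, symmetric, zero diagonal
    sparsity: float
    regions: RegionSet | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(i.tolist(), j.tolist()))


def sparsity_grid(start: float = 0.10, stop: float = 0.40, step: float = 0.01) -> np.ndarray:
    """Inclusive sparsity grid; defaults cover 0.10-0.40 in steps of 0.01."""
    if not (0 < start <= stop <= 1) or step <= 0:
        raise ValidationError("require 0 < start <= stop <= 1 and step > 0")
    n = int(round((stop - start) / step))
    if not math.isclose(start + n * step, stop, rel_tol=0, abs_tol=1e-9):
        raise ValidationError("step does not evenly divide the sparsity range")
    return np.round(start + step * np.arange(n + 1), 10)


def edge_count(n_regions: int, sparsity: float) -> int:
    """Edge budget at a sparsity: round-half-up of ``s * R(R-1)/2``."""
    if not 0 < sparsity <= 1:
        raise ValidationError(f"sparsity must be in (0, 1], got {sparsity}")
    npairs = n_regions * (n_regions - 1) // 2
    k = math.floor(sparsity * npairs + 0.5)
    if k == 0:
        raise ValidationError(
            f"sparsity {sparsity} keeps zero edges on {n_regions} regions"
        )
    return min(k, npairs)


def correlation_matrix(cohort: MorphometricCohort, group) -> CovarianceNetwork:
    """|Pearson r| between all region pairs across one group's subjects."""
    X = cohort.group_values(group)
    n = X.shape[0]
    if n < 4:
        raise ValidationError(f"group {group!r} has {n} subjects; at least 4 required")
    sd = X.std(axis=0)
    if (sd == 0).any():
        names = np.asarray(cohort.regions.labels)[sd == 0]
        raise ValidationError(f"zero-variance region(s) in group {group!r}: {list(names)}")
    r = np.abs(np.corrcoef(X, rowvar=False))
    np.clip(r, 0.0, 1.0, out=r)
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2
    return CovarianceNetwork(group=group, matrix=r, n_subjects=n, regions=cohort.regions)


def _ranked_pairs(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered by descending weight, ties by (i, j)."""
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    w = matrix[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def binarize_at_sparsity(net, sparsity: float, regions: RegionSet | None = None) -> BinaryGraph:
    """Keep the ``k`` strongest edges at the given sparsity.

    Ties in weight are broken by lexicographic node-index order, making the
    result deterministic and edge sets nested across increasing sparsity.
    Accepts a :class:`CovarianceNetwork` or a raw symmetric matrix.
    """
    if isinstance(net, CovarianceNetwork):
        matrix, regions = net.matrix, net.regions
    else:
        matrix = np.asarray(net, float)
    R = matrix.shape[0]
    k = edge_count(R, sparsity)
    ri, rj = _ranked_pairs(matrix)
    A = np.zeros((R, R), dtype=bool)
    A[ri[:k], rj[:k]] = True
    A |= A.T
    return BinaryGraph(adjacency=A, sparsity=float(sparsity), regions=regions)


def graded_graphs(net, grid: np.ndarray):
    """Yield ``(sparsity, adjacency)`` along a grid, adding edges incrementally.

    The ranking is computed once, so the yielded edge sets are nested by
    construction and identical to repeated :func:`binarize_at_sparsity`
    calls.  The adjacency buffer is reused between yields; callers must
    consume each graph before advancing.
    """
    matrix = net.matrix if isinstance(net, CovarianceNetwork) else np.asarray(net, float)
    R = matrix.shape[0]
    ri, rj = _ranked_pairs(matrix)
    A = np.zeros((R, R), dtype=bool)
    prev = 0
    for s in grid:
        k = edge_count(R, float(s))
        if k < prev:
            raise ValidationError("sparsity grid must be non-decreasing")
        A[ri[prev:k], rj[prev:k]] = True
        A[rj[prev:k], ri[prev:k]] = True
        prev = k
        yield float(s), A


def export_matrix(net: CovarianceNetwork, path) -> None:
    """Write the covariance matrix as TSV with region labels as header."""
    net.to_frame().to_csv(path, sep="\t")


def export_edge_list(graph: BinaryGraph, weights: np.ndarray | None, path) -> None:
    """Write an edge list TSV: region_a, region_b, weight (1.0 if unweighted)."""
    labels = list(graph.regions.labels) if graph.regions else list(range(graph.n_nodes))
    rows = []
    for i, j in graph.edge_list():
        w = float(weights[i, j]) if weights is not None else 1.0
        rows.append((labels[i], labels[j], w))
    pd.DataFrame(rows, columns=["region_a", "region_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )
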