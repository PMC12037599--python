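"""Two-group permutation inference on network metrics.

Group differences are summarized across the sparsity grid by the
trapezoidal area under the metric curve (AUC), and tested against a null
distribution obtained by randomly reassigning subjects to two new groups of
the original sizes and re-running the full pipeline (correlation ->
thresholding -> metrics -> AUC) for every relabeling.  P-values use the
add-one estimator ``p = (1 + #{|null| >= |observed|}) / (reps + 1)``
(two-tailed), so they are never exactly zero.  Nodal metrics are compared
at a single sparsity, with Benjamini-Hochberg FDR correction across
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import MorphometricCohort
from .metrics import (
    GLOBAL_METRICS,
    NODAL_METRICS,
    NORMALIZED_METRICS,
    global_metric_values,
    nodal_metric_values,
)
from .networks import binarize_at_sparsity, sparsity_grid

DEFAULT_REPETITIONS = 2000


def auc(values, grid) -> float:
    """Trapezoidal area under a metric curve sampled on a sparsity grid."""
    values = np.asarray(values, float)
    grid = np.asarray(grid, float)
    if values.shape != grid.shape or grid.ndim != 1 or grid.size < 2:
        raise ValidationError("curve and grid must be equal-length 1-d arrays (>= 2 points)")
    if not (np.diff(grid) > 0).all():
        raise ValidationError("sparsity grid must be strictly increasing")
    return float(np.trapezoid(values, grid))


def permute_groups(labels, rng: np.random.Generator) -> np.ndarray:
    """Random reassignment of subjects to groups, preserving group sizes."""
    labels = np.asarray(labels)
    return labels[rng.permutation(labels.size)]


@dataclass
class PermutationResult:
    """Observed AUC difference (group A - group B) with its permutation null."""

    metric: str
    observed: float
    auc_a: float
    auc_b: float
    null: np.ndarray
    p: float
    band: tuple[float, float]

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _permutation_p(observed: float, null: np.ndarray) -> float:
    b = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    return (1 + b) / (null.size + 1)


def _group_masks(groups: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    return (groups == labels[0]), (groups == labels[1])


def _abs_corr(X: np.ndarray) -> np.ndarray:
    r = np.abs(np.corrcoef(X, rowvar=False))
    np.clip(r, 0.0, 1.0, out=r)
    np.fill_diagonal(r, 0.0)
    return r


def global_permutation_test(
    cohort: MorphometricCohort,
    metric: str,
    grid=None,
    repetitions: int = DEFAULT_REPETITIONS,
    seed: int = 0,
    n_random: int = 100,
    null_per_perm: int = 20,
    swaps_per_edge: int = 10,
    n_restarts: int = 10,
) -> PermutationResult:
    """Permutation test of the AUC group difference for one global metric.

    ``n_random`` sets the rewired-null ensemble size for the observed
    statistic and ``null_per_perm`` the (smaller) size used inside each
    permutation; both only matter for the normalized metrics
    gamma/lambda/sigma.
    """
    if metric not in GLOBAL_METRICS:
        raise ValidationError(f"unknown global metric {metric!r}")
    if repetitions < 100:
        raise ValidationError("at least 100 permutation repetitions are required")
    import warnings

    if repetitions < 1000:
        warnings.warn(f"only {repetitions} permutations; p-value resolution is coarse",
                      stacklevel=2)
    grid = sparsity_grid() if grid is None else np.asarray(grid, float)

    X = cohort.values.to_numpy(float)
    groups = cohort.meta["group"].to_numpy()
    labels = cohort.group_labels
    ens = n_random if metric in NORMALIZED_METRICS else 0

    def statistic(g: np.ndarray, n_rand: int, stat_seed: int) -> tuple[float, float]:
        ma, mb = _group_masks(g, labels)
        res = []
        for k, mask in enumerate((ma, mb)):
            vals = global_metric_values(
                _abs_corr(X[mask]), grid, metrics=(metric,), n_random=n_rand,
                swaps_per_edge=swaps_per_edge, seed=stat_seed + k,
                n_restarts=n_restarts,
            )[metric]
            res.append(auc(vals, grid))
        return res[0], res[1]

    auc_a, auc_b = statistic(groups, ens, seed)
    observed = auc_a - auc_b

    perm_ens = null_per_perm if metric in NORMALIZED_METRICS else 0
    rng = np.random.default_rng(seed)
    null = np.empty(repetitions)
    for r in range(repetitions):
        perm = permute_groups(groups, rng)
        na, nb = statistic(perm, perm_ens, seed + 7919 * (r + 1))
        null[r] = na - nb

    return PermutationResult(
        metric=metric, observed=observed, auc_a=auc_a, auc_b=auc_b, null=null,
        p=_permutation_p(observed, null),
        band=(float(np.percentile(null, 2.5)), float(np.percentile(null, 97.5))),
    )


def nodal_permutation_test_fdr(
    cohort: MorphometricCohort,
    metric: str,
    sparsity: float = 0.10,
    repetitions: int = DEFAULT_REPETITIONS,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region permutation test of a nodal metric at one sparsity, BH-corrected.

    Returns a DataFrame indexed by region with columns ``observed`` (A - B),
    ``p_raw``, ``p_bh`` and ``significant`` (``p_bh < alpha``).
    """
    if metric not in NODAL_METRICS:
        raise ValidationError(f"unknown nodal metric {metric!r}")
    X = cohort.values.to_numpy(float)
    groups = cohort.meta["group"].to_numpy()
    labels = cohort.group_labels

    def statistic(g: np.ndarray) -> np.ndarray:
        ma, mb = _group_masks(g, labels)
        vals = []
        for mask in (ma, mb):
            A = binarize_at_sparsity(_abs_corr(X[mask]), sparsity).adjacency
            vals.append(nodal_metric_values(A, metric))
        return vals[0] - vals[1]

    observed = statistic(groups)
    rng = np.random.default_rng(seed)
    null = np.empty((repetitions, observed.size))
    for r in range(repetitions):
        null[r] = statistic(permute_groups(groups, rng))

    exceed = (np.abs(null) >= np.abs(observed)[None, :] - 1e-12).sum(axis=0)
    p_raw = (1 + exceed) / (repetitions + 1)
    p_bh = bh_fdr(p_raw)
    return pd.DataFrame(
        {"observed": observed, "p_raw": p_raw, "p_bh": p_bh,
         "significant": p_bh < alpha},
        index=list(cohort.regions.labels),
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p-values must form a non-empty 1-d array")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
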