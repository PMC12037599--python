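"""Demographic and clinical group statistics.

Group comparisons of clinical variables follow a normality-gated scheme:
Shapiro-Wilk is run per group at alpha = 0.05; when both groups look
normal the variable is compared with a pooled-variance unpaired two-tailed
t-test, otherwise with a two-tailed Mann-Whitney U test (normal
approximation with tie correction for larger samples).  A summary-level
t-test reproduces p-values from printed mean +/- SD tables.  Associations
between regional morphometrics and clinical scores use partial correlation
with age and sex regressed out of both variables, tested via the t
transform on ``df = n - 2 - k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .preprocess import design_matrix


@dataclass
class GroupComparison:
    variable: str
    test: str  # "t_test" | "mann_whitney"
    statistic: float
    p: float
    summary_a: str
    summary_b: str


def _summaries(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.3f} ± {np.std(x, ddof=1):.3f}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}–{q3:.2f})"


def gated_group_test(values, groups, variable: str = "", force: str | None = None,
                     alpha: float = 0.05) -> GroupComparison:
    """Compare one variable between two groups with Shapiro-Wilk gating.

    ``force`` overrides the gate with ``"t_test"`` or ``"mann_whitney"``.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = sorted(np.unique(groups).tolist())
    if len(labels) != 2:
        raise ValidationError(f"expected two groups, got {labels}")
    xa = values[groups == labels[0]]
    xb = values[groups == labels[1]]
    if min(xa.size, xb.size) < 3:
        raise ValidationError("each group needs at least 3 observations")

    if force is None:
        normal = all(
            np.ptp(x) > 0 and stats.shapiro(x).pvalue > alpha for x in (xa, xb)
        )
        test = "t_test" if normal else "mann_whitney"
    elif force in ("t_test", "mann_whitney"):
        test = force
    else:
        raise ValidationError(f"unknown test {force!r}")

    if test == "t_test":
        res = stats.ttest_ind(xa, xb, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        method = "exact" if max(xa.size, xb.size) <= 20 else "asymptotic"
        try:
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        except ValueError:  # exact method refuses ties
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)

    normalish = test == "t_test"
    return GroupComparison(
        variable=variable, test=test, statistic=stat, p=min(p, 1.0) if p > 0 else p,
        summary_a=_summaries(xa, normalish), summary_b=_summaries(xb, normalish),
    )


def summary_t_test(mean1: float, sd1: float, n1: int,
                   mean2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Pooled-variance two-tailed t-test from printed summary statistics.

    Exactly equivalent to the data-level pooled t-test on any dataset with
    these group means, SDs and sizes; ``df = n1 + n2 - 2``.
    """
    if min(n1, n2) < 2:
        raise ValidationError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    t = (mean1 - mean2) / se
    return float(t), float(2 * stats.t.sf(abs(t), df))


@dataclass
class PartialCorrelation:
    x: str
    y: str
    covariates: tuple[str, ...]
    r: float
    p: float
    df: int
    n: int


def partial_r_to_p(r: float, n: int, k: int) -> float:
    """Two-tailed p for a partial correlation via the t transform, df = n - 2 - k."""
    df = n - 2 - k
    if df < 1:
        raise ValidationError(f"df = {df} < 1")
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt(df / (1 - r**2))
    return float(2 * stats.t.sf(abs(t), df))


def partial_correlation(x, y, covariates: np.ndarray | None = None,
                        x_name: str = "x", y_name: str = "y",
                        covariate_names=()) -> PartialCorrelation:
    """Partial Pearson correlation of ``x`` and ``y`` given covariate columns.

    Both variables are residualized on an intercept plus the covariates by
    OLS; r is the Pearson correlation of the residuals and p comes from the
    t transform on ``df = n - 2 - k``.  With no covariates this reduces to
    the plain Pearson correlation and its p-value.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if y.size != n:
        raise ValidationError("x and y differ in length")
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        Z = np.ones((n, 1))
        k = 0
    else:
        Z = np.asarray(covariates, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise ValidationError("covariate rows do not match observations")
        k = Z.shape[1]
        Z = np.column_stack([np.ones(n), Z])
    df = n - 2 - k
    if df < 1:
        raise ValidationError(f"df = {df} < 1")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValidationError("singular covariate design")
    beta_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rx = x - Z @ beta_x
    ry = y - Z @ beta_y
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        raise ValidationError("a variable is fully explained by the covariates")
    r = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    return PartialCorrelation(
        x=x_name, y=y_name, covariates=tuple(covariate_names), r=r,
        p=partial_r_to_p(r, n, k), df=df, n=n,
    )


def clinical_table(cohort, columns=None) -> "pd.DataFrame":
    """Gated group comparison for each clinical/demographic column present."""
    import pandas as pd

    from .io import CLINICAL_COLUMNS

    meta = cohort.meta
    groups = meta["group"].to_numpy()
    cols = columns if columns is not None else ("age", *CLINICAL_COLUMNS)
    rows = []
    for col in cols:
        if col not in meta.columns:
            continue
        vals = pd.to_numeric(meta[col], errors="coerce")
        ok = vals.notna().to_numpy()
        if ok.sum() < 6:
            continue
        cmp = gated_group_test(vals.to_numpy()[ok], groups[ok], variable=col)
        rows.append(
            (col, cmp.test, cmp.summary_a, cmp.summary_b, cmp.statistic, cmp.p)
        )
    return pd.DataFrame(
        rows, columns=["variable", "test", "group_a", "group_b", "statistic", "p"]
    )


def morphometry_clinical_correlations(cohort, region_labels, clinical_columns,
                                      covariates=("age", "sex")) -> "pd.DataFrame":
    """Partial correlations between regional values and clinical scores, per group.

    Reported uncorrected, as exploratory associations.
    """
    import pandas as pd

    rows = []
    for g in cohort.group_labels:
        mask = (cohort.meta["group"] == g).to_numpy()
        meta_g = cohort.meta[mask]
        Z = design_matrix(meta_g, covariates)[:, 1:]  # drop intercept; added back inside
        for region in region_labels:
            x = cohort.values.loc[mask, region].to_numpy(float)
            for col in clinical_columns:
                if col not in meta_g.columns:
                    continue
                y = pd.to_numeric(meta_g[col], errors="coerce").to_numpy(float)
                ok = ~np.isnan(y)
                if ok.sum() - 2 - Z.shape[1] < 1:
                    continue
                pc = partial_correlation(
                    x[ok], y[ok], Z[ok], x_name=region, y_name=col,
                    covariate_names=covariates,
                )
                rows.append((g, region, col, pc.r, pc.p, pc.n, pc.df))
    return pd.DataFrame(
        rows, columns=["group", "region", "clinical", "r", "p", "n", "df"]
    )
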