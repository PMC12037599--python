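"""Nuisance-covariate correction of morphometric values.

Covariance networks are built from *corrected* values: per-region ordinary
least-squares residuals after regressing out nuisance covariates (by
default age and sex) with an intercept.  Fitting is pooled across both
groups by default so that group-specific centering cannot itself create or
destroy covariance structure; per-group fitting is available via
``pooled=False``.  Residuals are not re-standardized — Pearson correlation
is scale-invariant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import MorphometricCohort

DEFAULT_COVARIATES = ("age", "sex")


def design_matrix(meta: pd.DataFrame, covariates) -> np.ndarray:
    """Intercept + covariate columns; ``sex`` is encoded as a 0/1 indicator (M=1)."""
    cols = [np.ones(len(meta))]
    for cov in covariates:
        if cov not in meta.columns:
            raise ValidationError(f"covariate {cov!r} missing from metadata")
        col = meta[cov]
        if cov == "sex" or col.dtype == object:
            levels = sorted(col.astype(str).unique())
            if len(levels) == 1:
                raise ValidationError(f"covariate {cov!r} is constant (singular design)")
            if len(levels) != 2:
                raise ValidationError(
                    f"covariate {cov!r} has levels {levels}; only binary "
                    "categorical covariates are supported"
                )
            x = (col.astype(str) == levels[-1]).to_numpy(float)
        else:
            x = col.to_numpy(float)
            if np.ptp(x) == 0:
                raise ValidationError(f"covariate {cov!r} is constant (singular design)")
        if np.isnan(x).any():
            raise ValidationError(f"covariate {cov!r} has missing values")
        cols.append(x)
    return np.column_stack(cols)


def residualize(
    cohort: MorphometricCohort,
    covariates=DEFAULT_COVARIATES,
    pooled: bool = True,
) -> MorphometricCohort:
    """Replace each region's values by OLS residuals against the covariates.

    Parameters
    ----------
    cohort
        Validated raw cohort.
    covariates
        Metadata column names to remove.  An empty list removes only the
        per-region mean (intercept-only model).
    pooled
        Fit one model per region over all subjects (default); with
        ``False``, fit separately within each group.

    Returns
    -------
    MorphometricCohort
        Cohort flagged ``corrected=True``; ``adjustment`` holds the fitted
        coefficients (regions x design columns).
    """
    Y = cohort.values.to_numpy(float)
    out = np.empty_like(Y)

    def _fit(meta_part: pd.DataFrame, y_part: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = design_matrix(meta_part, covariates)
        n, p = X.shape
        if n <= p:
            raise ValidationError(
                f"{n} subjects cannot identify {p} regression parameters"
            )
        beta, _, rank, _ = np.linalg.lstsq(X, y_part, rcond=None)
        if rank < p:
            raise ValidationError("singular covariate design")
        return y_part - X @ beta, beta

    coef_names = ["intercept", *covariates]
    if pooled:
        out, beta = _fit(cohort.meta, Y)
        adjustment = pd.DataFrame(beta.T, index=cohort.values.columns, columns=coef_names)
    else:
        betas = []
        for g in cohort.group_labels:
            mask = (cohort.meta["group"] == g).to_numpy()
            out[mask], beta = _fit(cohort.meta[mask], Y[mask])
            part = pd.DataFrame(beta.T, index=cohort.values.columns, columns=coef_names)
            part.insert(0, "group", g)
            betas.append(part)
        adjustment = pd.concat(betas)

    return cohort.with_values(out, corrected=True, adjustment=adjustment)
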