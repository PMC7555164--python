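"""Cross-task composite scores, reliability, and descriptive analyses.

Per-participant composites are means of z-standardized task-level values
(drift rate, boundary separation, non-decision time, mean log RT), computed
over all 18 tasks and separately per content domain.  Reliability is
Cronbach's alpha; a correlation-matrix PCA supplies general-factor scores
and a general/domain-specific decomposition; cubic polynomials describe the
age trend of a measure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "zscore_by_task",
    "composite_mean",
    "cronbach_alpha",
    "GeneralFactorPCA",
    "pca_general_factor",
    "general_specific_decomposition",
    "cubic_age_trend",
    "correlation_table",
]


def zscore_by_task(values: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-standardization (sample SD, n-1); NaN entries propagate.

    Each column is one task; standardization uses the observed subset of
    that column, so missing entries neither shift the scale nor get filled.
    """
    values = pd.DataFrame(values)
    out = {}
    for col in values.columns:
        x = values[col].astype(float)
        obs = x.dropna()
        if obs.nunique() < 2:
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        out[col] = (x - obs.mean()) / obs.std(ddof=1)
    return pd.DataFrame(out, index=values.index)


def composite_mean(zmatrix: pd.DataFrame, task_subset=None) -> pd.Series:
    """Row mean of z-scores over the given task subset.

    Rows missing some subset tasks average the available ones; rows missing
    all of them come back NaN.
    """
    zmatrix = pd.DataFrame(zmatrix)
    if task_subset is None:
        task_subset = list(zmatrix.columns)
    task_subset = [c for c in task_subset]
    if len(task_subset) == 0:
        raise ValueError("task subset must be non-empty")
    missing = set(task_subset) - set(zmatrix.columns)
    if missing:
        raise KeyError(f"tasks not in matrix: {sorted(missing)}")
    return zmatrix[task_subset].mean(axis=1, skipna=True)


def cronbach_alpha(items) -> float:
    """Internal-consistency reliability k/(k-1) * (1 - sum(var_i)/var(total)).

    Listwise deletion; needs >= 2 items and >= 3 complete rows.
    """
    X = pd.DataFrame(items).dropna().to_numpy(dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    if n < 3:
        raise ValueError("need at least 3 complete rows")
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


class GeneralFactorPCA(BaseEstimator, TransformerMixin):
    """First principal component of the correlation matrix.

    ``fit`` on a complete participant x indicator matrix; ``transform``
    returns standardized (SD 1) first-component scores with the sign fixed
    so the mean loading is positive.  Fitted attributes: ``loadings_``
    (correlation-scale), ``explained_variance_ratio_``, ``scores_``.
    """

    def fit(self, X, y=None):
        X = np.asarray(pd.DataFrame(X).to_numpy(), dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("need a 2-D matrix with >= 2 columns")
        if not np.isfinite(X).all():
            raise ValueError("PCA requires complete rows (listwise-delete first)")
        sd = X.std(axis=0, ddof=1)
        if (sd <= 0).any():
            raise ValueError("constant column in PCA input")
        Z = (X - X.mean(axis=0)) / sd
        R = np.corrcoef(Z, rowvar=False)
        eigval, eigvec = np.linalg.eigh(R)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        w = eigvec[:, 0]
        if w.mean() < 0:
            w = -w
        raw = Z @ w
        self._score_sd = raw.std(ddof=1)
        scores = raw / self._score_sd
        self.loadings_ = w * np.sqrt(eigval[0])
        self.explained_variance_ratio_ = float(eigval[0] / eigval.sum())
        self.eigenvalues_ = eigval
        self._weights = w
        self._mean = X.mean(axis=0)
        self._sd = sd
        self.scores_ = scores
        return self

    def transform(self, X):
        Z = (np.asarray(pd.DataFrame(X).to_numpy(), dtype=float) - self._mean) / self._sd
        return (Z @ self._weights) / self._score_sd


def pca_general_factor(measure_matrix):
    """Functional wrapper: (standardized first-PC scores, loadings)."""
    est = GeneralFactorPCA().fit(measure_matrix)
    return est.scores_, est.loadings_


def general_specific_decomposition(domain_scores):
    """Split domain composites into a general factor and specific residuals.

    General score = standardized first principal component; each domain's
    specific part is its residual after regressing out the general score
    (orthogonal to it by least-squares construction).

    Returns ``(general, residuals)`` with residuals as a DataFrame matching
    the input columns.
    """
    df = pd.DataFrame(domain_scores)
    general, _ = pca_general_factor(df)
    resid = {}
    g = np.asarray(general, dtype=float)
    gc = g - g.mean()
    for col in df.columns:
        y = df[col].to_numpy(dtype=float)
        beta = np.dot(gc, y - y.mean()) / np.dot(gc, gc)
        resid[col] = y - y.mean() - beta * gc
    return pd.Series(g, index=df.index, name="general"), pd.DataFrame(
        resid, index=df.index
    )


def cubic_age_trend(age, y):
    """Degree-3 polynomial least-squares fit of a measure on age.

    Age is centered before fitting for numerical conditioning; returned
    coefficients are on the centered scale, with the center reported.
    Returns a dict with coefficients, their standard errors and 95% CIs,
    fitted values, and real turning points of the cubic inside the observed
    age range.
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if age.size < 5:
        raise ValueError("need n >= 5")
    center = age.mean()
    x = age - center
    X = np.column_stack([np.ones_like(x), x, x**2, x**3])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("degenerate design (collinear age powers)")
    model = sm.OLS(y, X).fit()
    b = model.params
    # turning points: roots of 3 b3 x^2 + 2 b2 x + b1
    tps = []
    disc = 4 * b[2] ** 2 - 12 * b[3] * b[1]
    if abs(b[3]) > 1e-12 and disc >= 0:
        for sgn in (-1.0, 1.0):
            root = (-2 * b[2] + sgn * np.sqrt(disc)) / (6 * b[3])
            tps.append(root + center)
    elif abs(b[3]) <= 1e-12 and abs(b[2]) > 1e-12:
        tps.append(-b[1] / (2 * b[2]) + center)
    tps = [t for t in tps if age.min() <= t <= age.max()]
    ci = model.conf_int(alpha=0.05)
    return {
        "coefficients": np.asarray(b),
        "bse": np.asarray(model.bse),
        "conf_int": np.asarray(ci),
        "center": float(center),
        "fitted": np.asarray(model.fittedvalues),
        "turning_points": sorted(tps),
        "r_squared": float(model.rsquared),
    }


def correlation_table(
    table: pd.DataFrame, against: str, alpha: float = 0.005, alpha2: float = 0.001
) -> pd.DataFrame:
    """Pearson correlations of every numeric column with one anchor column.

    Pairwise-complete observations (floor n >= 10); two-sided p from the
    exact t transform; star flags at the strict (alpha) and stricter
    (alpha2) levels, mirroring the battery's reporting convention.
    """
    anchor = table[against].astype(float)
    rows = []
    for col in table.columns:
        if col == against:
            continue
        x = table[col]
        if not pd.api.types.is_numeric_dtype(x):
            continue
        mask = anchor.notna() & x.notna()
        n = int(mask.sum())
        if n < 10:
            raise ValueError(f"fewer than 10 pairwise-complete cases for {col!r}")
        r, p = stats.pearsonr(anchor[mask], x[mask].astype(float))
        rows.append(
            {
                "variable": col,
                "r": float(r),
                "p": float(p),
                "n": n,
                "sig": "**" if p < alpha2 else ("*" if p < alpha else ""),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
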