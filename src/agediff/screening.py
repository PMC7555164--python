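"""Outlier-exclusion cascade for the RT battery.

The screen runs in the fixed order: per-trial minimum-RT floor, per-block
(participant x task) IQR trial filter, model-fit adequacy exclusion,
task-level mean-RT/accuracy exclusion, and finally a multivariate
(Mahalanobis) participant screen against a chi-squared critical value.
Every removal is attributed to exactly one stage in a ScreenReport.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ScreenReport",
    "filter_min_rt",
    "trial_iqr_filter",
    "task_level_exclusion",
    "chi_square_critical",
    "mahalanobis_exclusion",
    "MahalanobisScreen",
]


@dataclass
class ScreenReport:
    """Book-keeping for the exclusion cascade.

    ``stages`` maps stage label -> number of units removed (trials for the
    trial-level stages, participant x task cells or participants for the
    later ones); ``thresholds`` records the cut-offs in force and ``flags``
    any per-unit detail worth keeping.
    """

    stages: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def record(self, stage: str, n_removed: int, threshold=None, flags=None):
        self.stages[stage] = self.stages.get(stage, 0) + int(n_removed)
        if threshold is not None:
            self.thresholds[stage] = threshold
        if flags is not None:
            self.flags.setdefault(stage, []).extend(flags)

    @property
    def total_removed(self) -> int:
        return int(sum(self.stages.values()))

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "stages": self.stages,
                "thresholds": self.thresholds,
                "flags": {k: list(map(str, v)) for k, v in self.flags.items()},
                "total_removed": self.total_removed,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def filter_min_rt(rt_s: np.ndarray, floor_ms: float = 300.0) -> np.ndarray:
    """Boolean keep-mask: trials strictly faster than the floor are dropped.

    ``rt_s`` is in seconds; the floor is given in milliseconds.  Ties at the
    floor are kept ("faster than" read strictly).
    """
    if floor_ms < 0:
        raise ValueError("floor must be non-negative")
    rt_s = np.asarray(rt_s, dtype=float)
    return rt_s >= floor_ms / 1000.0


def _iqr_bounds(values: np.ndarray, k: float):
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear-interpolation quantiles
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def trial_iqr_filter(rt_s: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Keep-mask for the single-pass intra-individual IQR filter.

    Bounds are Q1 - k*IQR and Q3 + k*IQR computed once on the input; values
    strictly outside are dropped.  Below 4 trials the filter passes
    everything through with a warning.
    """
    rt_s = np.asarray(rt_s, dtype=float)
    if rt_s.size < 4:
        warnings.warn("fewer than 4 trials; IQR filter passed through")
        return np.ones(rt_s.size, dtype=bool)
    lo, hi = _iqr_bounds(rt_s, k)
    return (rt_s >= lo) & (rt_s <= hi)


def task_level_exclusion(
    mean_rt: np.ndarray, accuracy: np.ndarray, k: float = 3.0
) -> np.ndarray:
    """Flag participant x task cells whose mean RT *or* accuracy is more than
    k IQRs outside [Q1, Q3] for that task (union rule).  Returns a boolean
    exclusion flag per participant."""
    mean_rt = np.asarray(mean_rt, dtype=float)
    accuracy = np.asarray(accuracy, dtype=float)
    if mean_rt.size < 4:
        raise ValueError("need at least 4 participants per task")
    flags = np.zeros(mean_rt.size, dtype=bool)
    for values in (mean_rt, accuracy):
        lo, hi = _iqr_bounds(values, k)
        flags |= (values < lo) | (values > hi)
    return flags


def chi_square_critical(df: int, p: float) -> float:
    """Upper-tail chi-squared critical value: the (1 - p) quantile."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    return float(stats.chi2.ppf(1.0 - p, df))


def mahalanobis_exclusion(
    features, p: float = 0.001, pseudo_inverse: bool = False
):
    """Squared Mahalanobis distances to the sample mean and exclusion flags.

    Uses the classical sample covariance; rows with any missing value are
    skipped (returned unflagged, distance NaN) with a warning.  A singular
    covariance raises unless ``pseudo_inverse=True`` is passed explicitly --
    with p features and barely more rows than features the classical
    covariance is near-singular and the pseudo-inverse changes the
    distances, so the fallback must be a conscious choice.

    Returns ``(flags, d2, critical)``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    complete = np.isfinite(X).all(axis=1)
    if not complete.all():
        warnings.warn(
            f"{int((~complete).sum())} incomplete rows skipped in Mahalanobis screen"
        )
    Xc = X[complete]
    if Xc.shape[0] <= 1:
        raise ValueError("need at least 2 complete rows")
    mu = Xc.mean(axis=0)
    cov = np.cov(Xc, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if pseudo_inverse:
        prec = np.linalg.pinv(cov)
    else:
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0 or not np.isfinite(logdet) or np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError(
                "sample covariance is singular or near-singular; re-run with "
                "pseudo_inverse=True to opt into the pseudo-inverse metric"
            )
        prec = np.linalg.inv(cov)
    diff = Xc - mu
    d2_complete = np.einsum("ij,jk,ik->i", diff, prec, diff)
    d2 = np.full(X.shape[0], np.nan)
    d2[complete] = d2_complete
    critical = chi_square_critical(X.shape[1], p)
    flags = np.zeros(X.shape[0], dtype=bool)
    flags[complete] = d2_complete > critical
    return flags, d2, critical


class MahalanobisScreen(BaseEstimator):
    """Multivariate participant screen, estimator-style.

    ``fit(X)`` computes mean/covariance on complete rows; ``predict(X)``
    returns boolean exclusion flags.  Fitted attributes: ``distances_``,
    ``critical_``, ``flags_``.
    """

    def __init__(self, p: float = 0.001, pseudo_inverse: bool = False):
        self.p = p
        self.pseudo_inverse = pseudo_inverse

    def fit(self, X, y=None):
        flags, d2, crit = mahalanobis_exclusion(
            X, p=self.p, pseudo_inverse=self.pseudo_inverse
        )
        self.flags_ = flags
        self.distances_ = d2
        self.critical_ = crit
        return self

    def predict(self, X=None):
        return self.flags_


def screen_trials(
    trials: pd.DataFrame,
    floor_ms: float = 300.0,
    k: float = 3.0,
    report: ScreenReport | None = None,
) -> pd.DataFrame:
    """Apply the two trial-level filters per participant x task block.

    Expects columns participant_id, task_id, rt (seconds), correct.
    """
    report = report if report is not None else ScreenReport()
    keep_floor = filter_min_rt(trials["rt"].to_numpy(), floor_ms)
    report.record("min_rt", int((~keep_floor).sum()), threshold=floor_ms)
    out = trials.loc[keep_floor]

    keep = pd.Series(True, index=out.index)
    for _, block in out.groupby(["participant_id", "task_id"], sort=False):
        keep.loc[block.index] = trial_iqr_filter(block["rt"].to_numpy(), k)
    report.record("trial_iqr", int((~keep).sum()), threshold=k)
    out = out.loc[keep]
    out.attrs["screen_report"] = report
    return out
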