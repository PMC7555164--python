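"""Multiple-mediator models with case-resampling bootstrap intervals.

All variables are standardized to unit variance on the complete-case sample
before estimation, so every path is a standardized coefficient.  For
predictor x, mediators M = (m_1..m_k) and outcome y:

    alpha_i : OLS slope of m_i on x
    beta_i  : coefficient of m_i in the OLS of y on (x, M)
    c       : total effect, slope of y on x alone
    c'      : direct effect, coefficient of x in y ~ x + M

Least-squares algebra guarantees c = c' + sum_i alpha_i beta_i exactly.
Indirect-effect uncertainty comes from a case-resampling bootstrap with
percentile intervals (default 99.5% to match a strict alpha of 0.005).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "MediationResult",
    "MediationModel",
    "fit_paths",
    "bootstrap_indirect",
    "proportion_mediated",
    "run_model_suite",
    "correlation_power",
    "MODEL_SPECS",
]


@dataclass
class MediationResult:
    mediators: list
    alpha: np.ndarray          # x -> m_i, standardized
    beta: np.ndarray           # m_i -> y | x and other mediators, standardized
    total_effect: float        # c
    direct_effect: float       # c'
    indirect_effects: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    conf: float | None = None
    n: int = 0
    n_boot: int = 0
    seed: int | None = None
    suppression: bool = False
    model_name: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def proportion_mediated(self) -> float:
        return proportion_mediated(self)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": self.model_name,
                "path": "total (c)",
                "estimate": self.total_effect,
            },
            {
                "model": self.model_name,
                "path": "direct (c')",
                "estimate": self.direct_effect,
            },
        ]
        for i, m in enumerate(self.mediators):
            row = {
                "model": self.model_name,
                "path": f"indirect via {m}",
                "estimate": self.indirect_effects[i],
            }
            if self.ci_low is not None:
                row["ci_low"] = self.ci_low[i]
                row["ci_high"] = self.ci_high[i]
                row["excludes_zero"] = bool(
                    self.ci_low[i] > 0 or self.ci_high[i] < 0
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _standardize(A: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise ValueError("constant variable in mediation input")
    return (A - A.mean(axis=0)) / sd


def _complete_cases(x, M, y):
    x = np.asarray(x, dtype=float).ravel()
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    y = np.asarray(y, dtype=float).ravel()
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(M).all(axis=1)
    return x[mask], M[mask], y[mask]


def _point_estimates(x, M, y):
    """Paths on already-complete raw data; standardizes internally."""
    n, k = M.shape
    Z = _standardize(np.column_stack([x, M, y]))
    xs, Ms, ys = Z[:, 0], Z[:, 1 : 1 + k], Z[:, -1]
    alpha = Ms.T @ xs / (xs @ xs)
    X_full = np.column_stack([np.ones(n), xs, Ms])
    coef, *_ = np.linalg.lstsq(X_full, ys, rcond=None)
    c_prime, beta = coef[1], coef[2:]
    c = float(xs @ ys / (xs @ xs))
    return alpha, beta, float(c_prime), c


def fit_paths(x, M, y, mediator_names=None, model_name="") -> MediationResult:
    """Point estimates of the standardized mediation decomposition."""
    x, M, y = _complete_cases(x, M, y)
    n, k = M.shape
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    if k > 1:
        R = np.corrcoef(M, rowvar=False)
        iu = np.triu_indices(k, 1)
        worst = np.argmax(np.abs(R[iu]))
        if np.abs(R[iu])[worst] > 0.999:
            i, j = iu[0][worst], iu[1][worst]
            names = mediator_names or [f"m{t+1}" for t in range(k)]
            raise ValueError(
                f"mediators {names[i]!r} and {names[j]!r} are collinear (|r| > 0.999)"
            )
    alpha, beta, c_prime, c = _point_estimates(x, M, y)
    indirect = alpha * beta
    return MediationResult(
        mediators=list(mediator_names or [f"m{t+1}" for t in range(k)]),
        alpha=alpha,
        beta=beta,
        total_effect=c,
        direct_effect=c_prime,
        indirect_effects=indirect,
        n=n,
        suppression=bool(c * c_prime < 0),
        model_name=model_name,
    )


def bootstrap_indirect(
    x, M, y, n_boot: int = 5000, conf: float = 0.995, seed=0,
    mediator_names=None, model_name="",
) -> MediationResult:
    """Case-resampling bootstrap percentile CIs for the indirect effects.

    The full estimation (including re-standardization) is repeated on each
    resample; resamples with a degenerate (constant) variable are redrawn
    and logged.  Deterministic given (data, seed, n_boot).
    """
    result = fit_paths(x, M, y, mediator_names=mediator_names, model_name=model_name)
    x, M, y = _complete_cases(x, M, y)
    n, k = M.shape
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, k))
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        xb, Mb, yb = x[idx], M[idx], y[idx]
        try:
            alpha, beta, _, _ = _point_estimates(xb, Mb, yb)
        except ValueError:
            redraws += 1
            if redraws > 100 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        boots[b] = alpha * beta
        b += 1
    if redraws:
        warnings.warn(f"{redraws} degenerate bootstrap resamples redrawn")
    tail = (1.0 - conf) / 2.0
    result.ci_low = np.quantile(boots, tail, axis=0)
    result.ci_high = np.quantile(boots, 1.0 - tail, axis=0)
    result.conf = conf
    result.n_boot = n_boot
    result.seed = seed
    return result


def proportion_mediated(result: MediationResult, tol: float = 1e-8) -> float:
    """Percentage of the total effect carried by the mediators: 100 (1 - c'/c).

    Undefined (NaN, with a warning) when |c| is below tolerance; values above
    100% arise under suppression (direct effect of opposite sign) and are
    flagged on the result.
    """
    c, cp = result.total_effect, result.direct_effect
    if abs(c) < tol:
        warnings.warn("total effect is ~0; proportion mediated undefined")
        return float("nan")
    return 100.0 * (1.0 - cp / c)


class MediationModel(BaseEstimator):
    """Estimator interface: ``fit(X, y)`` with X = [predictor, mediators...].

    Parameters: ``n_boot``, ``conf``, ``seed``.  Fitted attributes mirror
    MediationResult (``alpha_``, ``beta_``, ``total_effect_``,
    ``direct_effect_``, ``indirect_effects_``, ``ci_``,
    ``proportion_mediated_``, ``result_``).
    """

    def __init__(self, n_boot: int = 5000, conf: float = 0.995, seed: int = 0):
        self.n_boot = n_boot
        self.conf = conf
        self.seed = seed

    def fit(self, X, y, mediator_names=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be 2-D: [predictor, mediator(s)]")
        res = bootstrap_indirect(
            X[:, 0], X[:, 1:], y,
            n_boot=self.n_boot, conf=self.conf, seed=self.seed,
            mediator_names=mediator_names,
        )
        self.result_ = res
        self.alpha_ = res.alpha
        self.beta_ = res.beta
        self.total_effect_ = res.total_effect
        self.direct_effect_ = res.direct_effect
        self.indirect_effects_ = res.indirect_effects
        self.ci_ = np.column_stack([res.ci_low, res.ci_high])
        self.proportion_mediated_ = res.proportion_mediated
        return self


# The eight-model suite: (outcome column, mediator columns)
MODEL_SPECS = {
    "Model 1": ("g", ["comp_logrt"]),
    "Model 2": ("g", ["comp_v", "comp_a", "comp_t0"]),
    "Model 3": ("processing_capacity", ["comp_v", "comp_a", "comp_t0"]),
    "Model 4": ("psychometric_speed", ["comp_v", "comp_a", "comp_t0"]),
    "Model 5": ("memory", ["comp_v", "comp_a", "comp_t0"]),
    "Model 6": ("figural", ["comp_v_figural", "comp_a_figural", "comp_t0_figural"]),
    "Model 7": ("numeric", ["comp_v_numeric", "comp_a_numeric", "comp_t0_numeric"]),
    "Model 8": ("verbal", ["comp_v_verbal", "comp_a_verbal", "comp_t0_verbal"]),
}


def run_model_suite(
    composites: pd.DataFrame,
    n_boot: int = 5000,
    conf: float = 0.995,
    seed: int = 0,
) -> dict[str, MediationResult]:
    """The eight mediation models: age predicting intelligence scores through
    mean log RT (Model 1), overall diffusion composites (Models 2-5), and
    domain-matched composites (Models 6-8).  Listwise deletion per model."""
    results = {}
    rng = np.random.default_rng(seed)
    for name, (outcome, mediators) in MODEL_SPECS.items():
        needed = ["age", outcome, *mediators]
        missing = [c for c in needed if c not in composites.columns]
        if missing:
            raise KeyError(f"{name}: missing required column(s) {missing}")
        sub = composites[needed]
        results[name] = bootstrap_indirect(
            sub["age"], sub[mediators], sub[outcome],
            n_boot=n_boot, conf=conf, seed=int(rng.integers(2**31 - 1)),
            mediator_names=mediators, model_name=name,
        )
    return results


def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided zero-correlation test, Fisher-z approximation.

    Phi(atanh(r) sqrt(n-3) - z_{1-alpha/2}) plus the (negligible) lower tail.
    """
    if not 0 < r < 1:
        raise ValueError("r must lie in (0, 1)")
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    shift = np.arctanh(r) * np.sqrt(n - 3)
    return float(stats.norm.cdf(shift - z_crit) + stats.norm.cdf(-shift - z_crit))


def correlation_power_simulated(
    r: float, n: int, alpha: float = 0.05, n_rep: int = 20000, seed: int = 0
) -> float:
    """Monte-Carlo cross-check of :func:`correlation_power` (bivariate normal)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_rep, n))
    y = r * x + np.sqrt(1 - r * r) * rng.standard_normal((n_rep, n))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    rhat = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    t = rhat * np.sqrt((n - 2) / (1 - rhat**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return float((p < alpha).mean())
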