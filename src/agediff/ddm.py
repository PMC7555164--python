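"""Two-boundary Wiener diffusion model: densities, simulation, ML fitting.

The model describes a binary-choice trial as noisy evidence accumulation with
drift ``v`` between absorbing boundaries 0 and ``a`` (accuracy coding: the
upper boundary is the correct response).  Observed response time is the
boundary-hitting time plus a non-decision component drawn uniformly from
``[t0 - st0/2, t0 + st0/2]``.  The relative starting point ``z_r`` is fixed at
0.5 (no response bias) and the within-trial scaling constant is ``s = 1``;
other parameters (``sv``, ``szr``) are fixed to zero and not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from . import _wfpt

__all__ = [
    "DiffusionParams",
    "TrialSet",
    "FitResult",
    "WienerDDM",
    "choice_probability",
    "fpt_density",
    "fpt_cdf",
    "log_likelihood",
    "fit_ml",
    "simulate_trials",
    "fit_quality_check",
]

DENSITY_FLOOR = 1e-10  # likelihood floor keeping stray trials finite


@dataclass(frozen=True)
class DiffusionParams:
    """Parameter vector of one participant x task fit.

    v : drift rate (evidence units / s)
    a : boundary separation (> 0)
    t0 : mean non-decision time (s, >= st0/2)
    st0 : width of the uniform non-decision-time distribution (s, >= 0)
    z_r : relative starting point in (0, 1); 0.5 = unbiased
    s : diffusion scaling convention (1.0 throughout; stored, never free)
    """

    v: float
    a: float
    t0: float = 0.0
    st0: float = 0.0
    z_r: float = 0.5
    s: float = 1.0

    def __post_init__(self):
        if not np.isfinite([self.v, self.a, self.t0, self.st0]).all():
            raise ValueError("diffusion parameters must be finite")
        if self.a <= 0:
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if self.st0 < 0:
            raise ValueError(f"st0 must be non-negative, got {self.st0}")
        if self.t0 - self.st0 / 2 < -1e-12:
            raise ValueError("t0 - st0/2 must be non-negative")
        if not 0 < self.z_r < 1:
            raise ValueError(f"z_r must lie in (0, 1), got {self.z_r}")
        if self.s <= 0:
            raise ValueError("scaling constant s must be positive")

    def in_unit_scaling(self) -> "DiffusionParams":
        """Rescale to the s = 1 convention (v and a divide by s)."""
        if self.s == 1.0:
            return self
        return replace(self, v=self.v / self.s, a=self.a / self.s, s=1.0)


@dataclass
class TrialSet:
    """One participant x task block of trials (rt in seconds)."""

    rt: np.ndarray
    correct: np.ndarray
    participant_id: str = ""
    task_id: str = ""

    def __post_init__(self):
        self.rt = np.asarray(self.rt, dtype=float)
        self.correct = np.asarray(self.correct, dtype=np.int64)
        if self.rt.size == 0:
            raise ValueError("TrialSet needs at least one trial")
        if self.rt.shape != self.correct.shape:
            raise ValueError("rt and correct must have matching shapes")
        if not np.isfinite(self.rt).all() or (self.rt <= 0).any():
            raise ValueError("all response times must be finite and positive")
        if not np.isin(self.correct, (0, 1)).all():
            raise ValueError("correct must be coded 0/1")

    @property
    def n_trials(self) -> int:
        return self.rt.size

    @property
    def accuracy(self) -> float:
        return float(self.correct.mean())


@dataclass
class FitResult:
    params: DiffusionParams
    loglik: float
    converged: bool
    n_trials_used: int
    fit_ok: bool | None = None
    discrepancy: float | None = None
    message: str = ""
    start_values: dict = field(default_factory=dict)


def choice_probability(params: DiffusionParams) -> float:
    """Probability of absorption at the upper (correct) boundary.

    With z_r = 0.5 and s = 1 this is the logistic of ``a * v``; t0 and st0
    play no role.
    """
    p = params.in_unit_scaling()
    return 1.0 - _wfpt.prob_lower(p.v, p.a, p.z_r)


def fpt_density(t, boundary: str, params: DiffusionParams):
    """Defective density of the observed RT at the given boundary.

    ``boundary`` is ``"upper"`` or ``"lower"``.  Zero for any
    ``t <= t0 - st0/2``.  Scalar or array ``t``.
    """
    upper = _check_boundary(boundary)
    p = params.in_unit_scaling()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = _wfpt.dens_obs_vec(t_arr.ravel(), upper, p.v, p.a, p.z_r, p.t0, p.st0)
    out = out.reshape(t_arr.shape)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def fpt_cdf(t, boundary: str, params: DiffusionParams):
    """Defective cumulative probability of the observed RT at the boundary."""
    upper = _check_boundary(boundary)
    p = params.in_unit_scaling()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = _wfpt.cdf_obs_vec(t_arr.ravel(), upper, p.v, p.a, p.z_r, p.t0, p.st0)
    out = out.reshape(t_arr.shape)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def _check_boundary(boundary: str) -> bool:
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    return boundary == "upper"


def log_likelihood(trials: TrialSet, params: DiffusionParams) -> float:
    """Sum of log defective densities over trials (accuracy coding).

    Densities below ``DENSITY_FLOOR`` are floored so that stray trials keep
    the objective finite.
    """
    p = params.in_unit_scaling()
    return _wfpt.loglik(
        trials.rt, trials.correct, p.v, p.a, p.z_r, p.t0, p.st0, DENSITY_FLOOR
    )


def simulate_trials(
    params: DiffusionParams, n: int, seed, participant_id="", task_id=""
) -> TrialSet:
    """Draw ``n`` (rt, correct) pairs by exact inverse-CDF sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = params.in_unit_scaling()
    rng = np.random.default_rng(seed)
    u = rng.random((3, n))
    rt, correct = _wfpt.sample_trials(u[0], u[1], u[2], p.v, p.a, p.z_r, p.t0, p.st0)
    return TrialSet(rt=rt, correct=correct, participant_id=participant_id, task_id=task_id)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


def ez_start(rt: np.ndarray, correct: np.ndarray) -> tuple[float, float, float]:
    """Moment-based (EZ-style) starting values (v, a, t0) in s = 1 scaling."""
    n = rt.size
    pc = float(correct.mean())
    # edge correction keeps the logit finite
    pc = min(max(pc, 0.5 / n), 1.0 - 0.5 / n)
    if abs(pc - 0.5) < 1e-4:
        pc = 0.5 + 1e-4
    rt_c = rt[correct == 1]
    if rt_c.size < 5:
        rt_c = rt
    mrt = float(rt_c.mean())
    vrt = float(rt_c.var(ddof=1)) if rt_c.size > 1 else 0.0
    vrt = max(vrt, 1e-6)
    L = math_log_odds(pc)
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vrt
    v = float(np.sign(pc - 0.5) * abs(x) ** 0.25)
    v = float(np.clip(v, -8.0, 8.0))
    if abs(v) < 0.05:
        v = 0.05 if v >= 0 else -0.05
    a = float(np.clip(L / v, 0.2, 8.0))
    y = v * a
    mdt = (a / (2 * v)) * (1 - np.exp(-y)) / (1 + np.exp(-y))
    t0 = mrt - mdt
    min_rt = float(rt.min())
    t0 = float(np.clip(t0, 0.3 * min_rt, 0.95 * min_rt))
    return v, a, t0


def math_log_odds(p: float) -> float:
    return float(np.log(p / (1 - p)))


_ST0_MIN, _ST0_MAX = 1e-4, 5.0


def _pack(v, a, edge, st0, min_rt):
    """(v, a, lower window edge t0 - st0/2, st0) -> unconstrained theta.

    Only the lower edge of the non-decision window is bounded by the fastest
    trial; the window may extend past min(rt), in which case fast trials
    simply sit low in the uniform average.
    """
    th3 = logit(np.clip(edge / min_rt, 1e-4, 1 - 1e-4))
    th4 = np.log(np.clip(st0, _ST0_MIN, _ST0_MAX))
    return np.array([v, np.log(a), th3, th4])


def _unpack(theta, min_rt):
    v = float(np.clip(theta[0], -40.0, 40.0))
    a = float(np.exp(np.clip(theta[1], np.log(0.05), np.log(20.0))))
    edge = min_rt * float(expit(theta[2]))
    st0 = float(np.exp(np.clip(theta[3], np.log(_ST0_MIN), np.log(_ST0_MAX))))
    t0 = edge + 0.5 * st0
    return v, a, t0, st0


def fit_ml(
    trials: TrialSet,
    n_starts: int = 5,
    seed: int = 0,
    z_r: float = 0.5,
    maxiter: int = 600,
    adaptive_starts: bool = False,
) -> FitResult:
    """Maximum-likelihood fit of (v, a, t0, st0) with z_r fixed.

    Nelder-Mead on a transformed space (raw v, log a, logit-scaled t0 within
    (0, min rt), st0 bounded so the whole non-decision window stays inside
    (0, min rt)).  ``n_starts`` multistarts: the first from EZ-style moment
    equations, the rest jittered.  With ``adaptive_starts`` the extra starts
    run only when the first solution fails to converge or sits on the edge of
    the feasible region; deterministic given (trials, seed).
    """
    rt, correct = trials.rt, trials.correct
    n = rt.size
    if n < 40:
        warnings.warn(f"only {n} trials; fits below ~40 trials are unreliable")
    if trials.accuracy in (0.0, 1.0):
        warnings.warn("all responses in one category; drift is weakly identified")
    if np.ptp(rt) < 1e-9:
        return FitResult(
            params=DiffusionParams(v=0.0, a=1.0, t0=float(rt.min()) * 0.9, z_r=z_r),
            loglik=np.nan,
            converged=False,
            n_trials_used=n,
            message="degenerate input: all response times identical",
        )

    min_rt = float(rt.min())
    v0, a0, t00 = ez_start(rt, correct)

    def objective(theta):
        v, a, t0, st0 = _unpack(theta, min_rt)
        return -_wfpt.loglik(rt, correct, v, a, z_r, t0, st0, DENSITY_FLOOR)

    rng = np.random.default_rng(seed)
    st0_0 = max(0.15 * t00, 2e-3)
    edge0 = min(t00 - 0.5 * st0_0, 0.95 * min_rt)
    starts = [_pack(v0, a0, edge0, st0_0, min_rt)]
    for _ in range(max(n_starts - 1, 0)):
        jv = v0 * rng.lognormal(0.0, 0.3) if abs(v0) > 0.1 else v0 + rng.normal(0, 0.5)
        ja = a0 * rng.lognormal(0.0, 0.3)
        je = float(np.clip(edge0 * rng.lognormal(0.0, 0.15), 0.05 * min_rt, 0.95 * min_rt))
        js = st0_0 * rng.lognormal(0.0, 0.5)
        starts.append(_pack(jv, np.clip(ja, 0.1, 15.0), je, js, min_rt))

    best = None
    max_adaptive_extra = 2  # restarts actually run when the first looks poor
    for i, x0 in enumerate(starts):
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 5e-3},
        )
        if best is None or res.fun < best.fun:
            best = res
        if adaptive_starts and (
            _solution_acceptable(best, min_rt) or i >= max_adaptive_extra
        ):
            break

    v, a, t0, st0 = _unpack(best.x, min_rt)
    params = DiffusionParams(v=v, a=a, t0=t0, st0=st0, z_r=z_r, s=1.0)
    return FitResult(
        params=params,
        loglik=-best.fun,
        converged=bool(best.success),
        n_trials_used=n,
        message=best.message,
        start_values={"v": v0, "a": a0, "t0": t00},
    )


def _solution_acceptable(res, min_rt) -> bool:
    if not res.success:
        return False
    v, a, t0, st0 = _unpack(res.x, min_rt)
    edge = t0 - 0.5 * st0
    if abs(v) > 30.0 or a <= 0.06 or a >= 18.0:
        return False
    if edge < 0.02 * min_rt or st0 > 0.9 * _ST0_MAX:
        return False
    return True


# ---------------------------------------------------------------------------
# Parametric-bootstrap adequacy check
# ---------------------------------------------------------------------------

_QPROBS = np.arange(0.1, 0.95, 0.1)


def _discrepancy(rt, correct, model_q_upper, model_q_lower, p_correct_model):
    """Frequency-weighted squared quantile differences + squared accuracy gap."""
    return float(
        _wfpt.discrepancy(
            np.ascontiguousarray(rt, dtype=float),
            np.ascontiguousarray(correct, dtype=np.int64),
            model_q_upper,
            model_q_lower,
            p_correct_model,
            _QPROBS,
        )
    )


def fit_quality_check(
    trials: TrialSet,
    fit: FitResult,
    n_sim: int = 200,
    seed: int = 0,
    q: float = 0.05,
) -> FitResult:
    """Parametric-bootstrap adequacy verdict for a converged fit.

    Simulates ``n_sim`` datasets of the observed size at the fitted
    parameters; the discrepancy (decile RT quantiles per response category,
    weighted by category frequency, plus squared accuracy difference, all
    against model-implied values) of the observed data must not exceed the
    ``1 - q`` quantile of the simulated discrepancies.
    """
    if not fit.converged:
        raise ValueError("fit_quality_check requires a converged fit")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    p = fit.params.in_unit_scaling()
    args = (p.v, p.a, p.z_r, p.t0, p.st0)
    model_q_upper = _wfpt.observed_quantiles(_QPROBS, True, *args, 96)
    model_q_lower = _wfpt.observed_quantiles(_QPROBS, False, *args, 96)
    p_correct = choice_probability(p)

    d_obs = _discrepancy(trials.rt, trials.correct, model_q_upper, model_q_lower, p_correct)
    rng = np.random.default_rng(seed)
    d_sim = np.empty(n_sim)
    n = trials.n_trials
    if n_sim * n > 2000:
        # amortize: conditional quantile grid per boundary, interp sampling
        grid_up = _wfpt.cond_quantile_grid(True, *args[:3], 96)
        grid_lo = _wfpt.cond_quantile_grid(False, *args[:3], 96)
        u = rng.random((n_sim, 3, n))
        d_sim = _wfpt.sim_discrepancies(
            u, *args, grid_up, grid_lo, model_q_upper, model_q_lower, p_correct, _QPROBS
        )
    else:
        for i in range(n_sim):
            sim = simulate_trials(p, n, rng.integers(2**31 - 1))
            d_sim[i] = _discrepancy(sim.rt, sim.correct, model_q_upper, model_q_lower, p_correct)
    crit = float(np.quantile(d_sim, 1.0 - q))
    fit.fit_ok = bool(d_obs <= crit)
    fit.discrepancy = d_obs
    return fit


# ---------------------------------------------------------------------------
# scikit-learn style estimator
# ---------------------------------------------------------------------------


class WienerDDM(BaseEstimator):
    """Wiener diffusion model estimator for one block of binary-choice trials.

    Parameters
    ----------
    n_starts : multistart count for the Nelder-Mead search.
    seed : seed for start-value jitter (fits are deterministic given data+seed).
    z_r : relative starting point, fixed during estimation.
    adaptive_starts : run extra starts only when the first looks poor.

    Attributes (after ``fit``)
    --------------------------
    v_, a_, t0_, st0_ : fitted parameters (s = 1 scaling).
    loglik_ : maximized log-likelihood.
    converged_ : optimizer status.
    fit_ok_ : parametric-bootstrap verdict (after ``check_fit``).
    """

    def __init__(self, n_starts=5, seed=0, z_r=0.5, maxiter=600, adaptive_starts=False):
        self.n_starts = n_starts
        self.seed = seed
        self.z_r = z_r
        self.maxiter = maxiter
        self.adaptive_starts = adaptive_starts

    def fit(self, rt, correct=None):
        trials = rt if isinstance(rt, TrialSet) else TrialSet(rt=rt, correct=correct)
        result = fit_ml(
            trials,
            n_starts=self.n_starts,
            seed=self.seed,
            z_r=self.z_r,
            maxiter=self.maxiter,
            adaptive_starts=self.adaptive_starts,
        )
        self.result_ = result
        self.params_ = result.params
        self.v_ = result.params.v
        self.a_ = result.params.a
        self.t0_ = result.params.t0
        self.st0_ = result.params.st0
        self.loglik_ = result.loglik
        self.converged_ = result.converged
        self.n_trials_ = result.n_trials_used
        return self

    def score(self, rt, correct=None):
        """Mean log-likelihood per trial under the fitted parameters."""
        trials = rt if isinstance(rt, TrialSet) else TrialSet(rt=rt, correct=correct)
        return log_likelihood(trials, self.params_) / trials.n_trials

    def sample(self, n, seed=0):
        return simulate_trials(self.params_, n, seed)

    def check_fit(self, rt, correct=None, n_sim=200, seed=0, q=0.05):
        trials = rt if isinstance(rt, TrialSet) else TrialSet(rt=rt, correct=correct)
        result = fit_quality_check(trials, self.result_, n_sim=n_sim, seed=seed, q=q)
        self.fit_ok_ = result.fit_ok
        self.discrepancy_ = result.discrepancy
        return self
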