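"""Numerical kernels for the two-boundary Wiener first-passage-time model.

Everything here works in the s = 1 diffusion-scaling convention on *decision
time* (no non-decision shift); the public layer in :mod:`agediff.ddm` handles
t0/st0 and parameter validation.  All densities/CDFs refer to the *lower*
boundary of a process starting at ``z = a * w``; upper-boundary quantities are
obtained through the reflection ``(v, w) -> (-v, 1 - w)``.

Density: alternating small-time image series and eigenfunction large-time
series, with term counts chosen per evaluation from the standard truncation
bounds so the truncation error stays below ~1e-7.  CDF: exact image sum of
inverse-Gaussian terms for small normalized time, eigenfunction series
otherwise.
"""

from __future__ import annotations

import math

import numba as nb
import numpy as np

_SQRT2PI = math.sqrt(2.0 * math.pi)
_EPS_DENS = 1e-7      # truncation target for the normalized density
_TAU_CDF_SWITCH = 0.2  # normalized-time crossover for the CDF branches


@nb.njit(cache=True, inline="always")
def _phi(x):
    """Standard normal CDF."""
    return 0.5 * math.erfc(-x * 0.7071067811865476)


@nb.njit(cache=True)
def _log_phi(x):
    """log of the standard normal CDF, stable far into the lower tail."""
    if x > -8.0:
        return math.log(0.5 * math.erfc(-x * 0.7071067811865476))
    # asymptotic expansion of the Mills ratio
    x2 = x * x
    series = 1.0 - 1.0 / x2 + 3.0 / (x2 * x2) - 15.0 / (x2 * x2 * x2)
    return -0.5 * x2 - 0.5 * math.log(2.0 * math.pi) - math.log(-x) + math.log(series)


@nb.njit(cache=True)
def prob_lower(v, a, w):
    """Probability of absorption at the lower boundary (gambler's ruin)."""
    if abs(v) < 1e-10:
        return 1.0 - w
    # P(upper) = (1 - exp(-2 v z)) / (1 - exp(-2 v a)), z = a w
    vv = 2.0 * v * a
    if vv > 0.0:
        p_up = math.expm1(-vv * w) / math.expm1(-vv)
    else:
        # multiply through by exp(vv) for stability when v < 0
        p_up = math.expm1(-vv * w) / math.expm1(-vv)
    return 1.0 - p_up


@nb.njit(cache=True)
def _dens_norm(tau, w):
    """Normalized (a=1, v=0) lower-boundary density f(tau | w)."""
    if tau <= 0.0:
        return 0.0
    # number of terms for each representation (truncation-error bounds)
    arg = 2.0 * _EPS_DENS * math.sqrt(2.0 * math.pi * tau)
    if arg < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tau * math.log(arg))
        sq = math.sqrt(tau) + 1.0
        if sq > ks:
            ks = sq
    else:
        ks = 2.0
    argl = math.pi * tau * _EPS_DENS
    if argl < 1.0:
        kl = math.sqrt(-2.0 * math.log(argl) / (math.pi * math.pi * tau))
        inv = 1.0 / (math.pi * math.sqrt(tau))
        if inv > kl:
            kl = inv
    else:
        kl = 1.0 / (math.pi * math.sqrt(tau))

    if ks < kl:
        # small-time image series
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        s = 0.0
        for k in range(lo, hi + 1):
            c = w + 2.0 * k
            s += c * math.exp(-c * c / (2.0 * tau))
        return s / math.sqrt(2.0 * math.pi * tau * tau * tau)
    # large-time eigenfunction series
    K = int(math.ceil(kl))
    s = 0.0
    for k in range(1, K + 1):
        s += k * math.exp(-k * k * math.pi * math.pi * tau / 2.0) * math.sin(
            k * math.pi * w
        )
    return math.pi * s


@nb.njit(cache=True)
def dens_lower(t, v, a, w):
    """Defective FPT density at the lower boundary, decision time t."""
    if t <= 0.0:
        return 0.0
    tau = t / (a * a)
    expo = -v * a * w - v * v * t / 2.0
    if expo < -700.0:
        return 0.0
    return math.exp(expo) / (a * a) * _dens_norm(tau, w)


@nb.njit(cache=True)
def _cdf_lower_largetime(t, v, a, w):
    p0 = prob_lower(v, a, w)
    pref_log = -v * a * w
    s = 0.0
    pi2 = math.pi * math.pi
    a2 = a * a
    for k in range(1, 1001):
        lam = 0.5 * (v * v + k * k * pi2 / a2)
        bound = k / lam * math.exp(-lam * t + pref_log)
        if bound * math.pi / a2 < 1e-12 and k > 2:
            break
        s += k * math.sin(k * math.pi * w) / lam * math.exp(-lam * t)
    tail = math.pi / a2 * math.exp(pref_log) * s
    out = p0 - tail
    if out < 0.0:
        out = 0.0
    elif out > 1.0:
        out = 1.0
    return out


@nb.njit(cache=True)
def _ig_pair(c, v, z, t, sqt):
    """Integral over (0, t] of one image term of the small-time density.

    c is the signed image location; z = a*w the start point.  Closed form via
    inverse-Gaussian first-passage CDFs, evaluated in log space so the
    exp(-2 v c) factors cannot overflow.
    """
    if c > 0.0:
        sgn = 1.0
        ac = c
        vc = v
    else:
        sgn = -1.0
        ac = -c
        vc = -v
    base = v * (c - z)
    t1 = math.exp(base + _log_phi(-(ac + vc * t) / sqt))
    t2 = math.exp(base - 2.0 * vc * ac + _log_phi((vc * t - ac) / sqt))
    return sgn * (t1 + t2)


@nb.njit(cache=True)
def _cdf_lower_smalltime(t, v, a, w):
    z = a * w
    sqt = math.sqrt(t)
    total = _ig_pair(z, v, z, t, sqt)
    for k in range(1, 51):
        inc = _ig_pair(z + 2.0 * k * a, v, z, t, sqt) + _ig_pair(
            z - 2.0 * k * a, v, z, t, sqt
        )
        total += inc
        if abs(inc) < 1e-12:
            break
    if total < 0.0:
        total = 0.0
    elif total > 1.0:
        total = 1.0
    return total


@nb.njit(cache=True)
def cdf_lower(t, v, a, w):
    """Defective FPT CDF at the lower boundary, decision time t."""
    if t <= 0.0:
        return 0.0
    tau = t / (a * a)
    if tau < _TAU_CDF_SWITCH:
        return _cdf_lower_smalltime(t, v, a, w)
    return _cdf_lower_largetime(t, v, a, w)


@nb.njit(cache=True, inline="always")
def _flip(boundary_upper, v, w):
    """Map an upper-boundary query to the canonical lower-boundary form."""
    if boundary_upper:
        return -v, 1.0 - w
    return v, w


# 11-node Gauss-Legendre on [-1, 1] for the observed-CDF uniform average
_GL_X = np.array(
    [
        -0.9782286581460570,
        -0.8870625997680953,
        -0.7301520055740494,
        -0.5190961292068118,
        -0.2695431559523450,
        0.0,
        0.2695431559523450,
        0.5190961292068118,
        0.7301520055740494,
        0.8870625997680953,
        0.9782286581460570,
    ]
)
_GL_W = np.array(
    [
        0.0556685671161737,
        0.1255803694649046,
        0.1862902109277343,
        0.2331937645919905,
        0.2628045445102467,
        0.2729250867779006,
        0.2628045445102467,
        0.2331937645919905,
        0.1862902109277343,
        0.1255803694649046,
        0.0556685671161737,
    ]
)


@nb.njit(cache=True)
def dens_obs(t, boundary_upper, v, a, w, t0, st0):
    """Observed-RT defective density: decision density shifted by t0 and
    averaged uniformly over the st0 window (exact CDF-difference form)."""
    vv, ww = _flip(boundary_upper, v, w)
    if st0 > 1e-6:
        h = 0.5 * st0
        return (cdf_lower(t - t0 + h, vv, a, ww) - cdf_lower(t - t0 - h, vv, a, ww)) / st0
    return dens_lower(t - t0, vv, a, ww)


@nb.njit(cache=True)
def cdf_obs(t, boundary_upper, v, a, w, t0, st0):
    """Observed-RT defective CDF (uniform st0 average by Gauss-Legendre)."""
    vv, ww = _flip(boundary_upper, v, w)
    if st0 <= 1e-6:
        return cdf_lower(t - t0, vv, a, ww)
    h = 0.5 * st0
    s = 0.0
    for i in range(11):
        u = t0 + h * _GL_X[i]
        s += _GL_W[i] * cdf_lower(t - u, vv, a, ww)
    return 0.5 * s


@nb.njit(cache=True)
def loglik(rt, correct, v, a, w, t0, st0, floor):
    """Sum of log defective densities under accuracy coding (upper=correct)."""
    ll = 0.0
    for i in range(rt.size):
        d = dens_obs(rt[i], correct[i] == 1, v, a, w, t0, st0)
        if d < floor:
            d = floor
        ll += math.log(d)
    return ll


@nb.njit(cache=True)
def _invert_conditional(u_time, boundary_upper, v, a, w, n_iter):
    """Bisection inverse of the conditional decision-time CDF at u_time
    (u_time already scaled into (0, P_boundary))."""
    vv, ww = _flip(boundary_upper, v, w)
    hi = a * a  # expand until the CDF exceeds the target
    for _ in range(200):
        if cdf_lower(hi, vv, a, ww) >= u_time:
            break
        hi *= 2.0
    lo = 0.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if cdf_lower(mid, vv, a, ww) < u_time:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@nb.njit(cache=True)
def sample_trials(u_boundary, u_time, u_t0, v, a, w, t0, st0):
    """Exact inverse-CDF sampler.  The three uniform streams decide boundary,
    conditional decision time, and the uniform non-decision draw."""
    n = u_boundary.size
    rt = np.empty(n)
    correct = np.empty(n, dtype=np.int64)
    p_up = 1.0 - prob_lower(v, a, w)
    for i in range(n):
        upper = u_boundary[i] < p_up
        p_b = p_up if upper else 1.0 - p_up
        target = u_time[i] * p_b
        dt = _invert_conditional(target, upper, v, a, w, 42)
        nd = t0 + st0 * (u_t0[i] - 0.5)
        rt[i] = dt + nd
        correct[i] = 1 if upper else 0
    return rt, correct


@nb.njit(cache=True)
def cond_quantile_grid(boundary_upper, v, a, w, K):
    """Conditional decision-time quantiles at i/K, i = 1..K-1, one boundary."""
    vv, ww = _flip(boundary_upper, v, w)
    p_b = prob_lower(vv, a, ww)
    grid = np.empty(K - 1)
    for i in range(1, K):
        grid[i - 1] = _invert_conditional(p_b * i / K, boundary_upper, v, a, w, 42)
    return grid


@nb.njit(cache=True)
def sample_trials_grid(u_boundary, u_time, u_t0, v, a, w, t0, st0, grid_up, grid_lo):
    """Inverse-CDF sampler interpolating a precomputed conditional quantile
    grid; draws falling in the outer grid cells use exact bisection."""
    n = u_boundary.size
    K = grid_up.size + 1
    rt = np.empty(n)
    correct = np.empty(n, dtype=np.int64)
    p_up = 1.0 - prob_lower(v, a, w)
    for i in range(n):
        upper = u_boundary[i] < p_up
        grid = grid_up if upper else grid_lo
        u = u_time[i]
        pos = u * K
        j = int(pos)
        if j < 1 or j >= K - 1:
            p_b = p_up if upper else 1.0 - p_up
            dt = _invert_conditional(u * p_b, upper, v, a, w, 42)
        else:
            frac = pos - j
            dt = grid[j - 1] + frac * (grid[j] - grid[j - 1])
        rt[i] = dt + t0 + st0 * (u_t0[i] - 0.5)
        correct[i] = 1 if upper else 0
    return rt, correct


@nb.njit(cache=True)
def quantile_obs(p, boundary_upper, v, a, w, t0, st0):
    """Invert the *conditional* observed-RT CDF at probability p in (0,1)."""
    vv, ww = _flip(boundary_upper, v, w)
    p_b = prob_lower(vv, a, ww)
    if p_b < 1e-12:
        return t0 - 0.5 * st0
    target = p * p_b
    lo = t0 - 0.5 * st0
    hi = lo + a * a + 1.0
    for _ in range(200):
        if cdf_obs(hi, boundary_upper, v, a, w, t0, st0) >= target:
            break
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if cdf_obs(mid, boundary_upper, v, a, w, t0, st0) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@nb.njit(cache=True)
def _quantile_linear(x_sorted, p):
    """Linear-interpolation sample quantile (matches numpy's default)."""
    m = x_sorted.size
    if m == 1:
        return x_sorted[0]
    h = (m - 1) * p
    lo = int(math.floor(h))
    if lo >= m - 1:
        return x_sorted[m - 1]
    frac = h - lo
    return x_sorted[lo] + frac * (x_sorted[lo + 1] - x_sorted[lo])


@nb.njit(cache=True)
def _category_term(rts, model_q, qprobs):
    if rts.size == 0:
        return 0.0
    xs = np.sort(rts)
    d = 0.0
    for i in range(qprobs.size):
        diff = _quantile_linear(xs, qprobs[i]) - model_q[i]
        d += diff * diff
    return rts.size * d


@nb.njit(cache=True)
def discrepancy(rt, correct, model_q_upper, model_q_lower, p_correct, qprobs):
    """Category-frequency-weighted squared decile gaps + squared accuracy gap."""
    n = rt.size
    acc = 0.0
    for i in range(n):
        acc += correct[i]
    acc /= n
    d = (acc - p_correct) ** 2
    d += _category_term(rt[correct == 1], model_q_upper, qprobs) / n
    d += _category_term(rt[correct == 0], model_q_lower, qprobs) / n
    return d


@nb.njit(cache=True)
def sim_discrepancies(
    u, v, a, w, t0, st0, grid_up, grid_lo, model_q_upper, model_q_lower, p_correct, qprobs
):
    """Discrepancy statistic for each of u.shape[0] simulated datasets."""
    n_sim = u.shape[0]
    out = np.empty(n_sim)
    for s in range(n_sim):
        rt, corr = sample_trials_grid(
            u[s, 0], u[s, 1], u[s, 2], v, a, w, t0, st0, grid_up, grid_lo
        )
        out[s] = discrepancy(rt, corr, model_q_upper, model_q_lower, p_correct, qprobs)
    return out


@nb.njit(cache=True)
def observed_quantiles(qprobs, boundary_upper, v, a, w, t0, st0, n_grid):
    """Conditional observed-RT quantiles via interpolation of a CDF grid.

    Builds an n_grid-point time grid from the lower edge of the non-decision
    window to the conditional 99.9th percentile and inverts by linear
    interpolation; accurate to the grid resolution, which is ample for the
    decile-discrepancy statistic.
    """
    vv, ww = _flip(boundary_upper, v, w)
    p_b = prob_lower(vv, a, ww)
    t_lo = t0 - 0.5 * st0
    if p_b < 1e-12:
        # boundary essentially never reached; quantiles are immaterial
        return np.full(qprobs.size, t_lo)
    # upper end: expand until conditional CDF >= 0.999
    t_hi = t_lo + a * a + t0 + 1.0
    for _ in range(60):
        if cdf_obs(t_hi, boundary_upper, v, a, w, t0, st0) >= 0.999 * p_b:
            break
        t_hi *= 1.5
    ts = np.empty(n_grid)
    Fs = np.empty(n_grid)
    for i in range(n_grid):
        ts[i] = t_lo + (t_hi - t_lo) * i / (n_grid - 1)
        Fs[i] = cdf_obs(ts[i], boundary_upper, v, a, w, t0, st0) / p_b
    out = np.empty(qprobs.size)
    j = 0
    for k in range(qprobs.size):
        p = qprobs[k]
        while j < n_grid - 1 and Fs[j + 1] < p:
            j += 1
        if j >= n_grid - 1:
            out[k] = ts[n_grid - 1]
        else:
            span = Fs[j + 1] - Fs[j]
            frac = (p - Fs[j]) / span if span > 0 else 0.0
            out[k] = ts[j] + frac * (ts[j + 1] - ts[j])
    return out


@nb.njit(cache=True)
def dens_obs_vec(t, boundary_upper, v, a, w, t0, st0):
    out = np.empty(t.size)
    for i in range(t.size):
        out[i] = dens_obs(t[i], boundary_upper, v, a, w, t0, st0)
    return out


@nb.njit(cache=True)
def cdf_obs_vec(t, boundary_upper, v, a, w, t0, st0):
    out = np.empty(t.size)
    for i in range(t.size):
        out[i] = cdf_obs(t[i], boundary_upper, v, a, w, t0, st0)
    return out
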