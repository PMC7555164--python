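"""Synthetic cohort generator for the full pipeline.

Emulates a cross-sectional adult sample (ages 18-62) completing a battery of
18 binary-choice RT tasks (3 content domains x 2 complexity levels x 3
tasks, ~100 trials each) plus a 12-subtest intelligence battery.  The
generative structure follows the empirical sign pattern the analyses target:
non-decision time and boundary separation increase with age, drift rate is
age-flat, and intelligence loads positively on latent drift and negatively
on latent non-decision time -- so the non-decision-time mediation of the
age-intelligence relation is recoverable by construction.

Per-task true parameters come from a published-battery-like table of task
means and SDs; participant latents enter through a moment-matched lognormal
map, which keeps every parameter positive even for slow tasks whose t0
spread is comparable to its mean.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .ddm import DiffusionParams, simulate_trials

__all__ = [
    "TASK_TABLE",
    "CohortConfig",
    "SyntheticCohort",
    "generate_participants",
    "generate_trials",
    "generate_intelligence",
    "generate_cohort",
]

# Task grid: id, domain, complexity, and per-task mean/SD of the diffusion
# parameters across participants (v in 1/s, a in evidence units, t0 in s).
_TASK_ROWS = [
    # id,   domain,    speed,  Mv,   SDv,  Ma,   SDa,  Mt0,  SDt0
    ("FF1", "figural", "fast", 3.16, 0.73, 0.91, 0.21, 0.42, 0.07),
    ("FF2", "figural", "fast", 3.26, 1.02, 1.53, 0.53, 0.36, 0.07),
    ("FF3", "figural", "fast", 4.27, 0.96, 1.16, 0.61, 0.41, 0.06),
    ("FN1", "numeric", "fast", 4.97, 1.82, 1.47, 1.31, 0.39, 0.07),
    ("FN2", "numeric", "fast", 3.95, 0.97, 1.20, 0.51, 0.43, 0.06),
    ("FN3", "numeric", "fast", 3.97, 1.39, 1.36, 1.03, 0.50, 0.10),
    ("FV1", "verbal", "fast", 2.81, 0.88, 1.52, 0.73, 0.51, 0.08),
    ("FV2", "verbal", "fast", 2.68, 0.78, 1.33, 0.44, 0.53, 0.07),
    ("FV3", "verbal", "fast", 3.21, 0.89, 1.35, 0.55, 0.52, 0.07),
    ("SF1", "figural", "slow", 0.94, 0.20, 3.75, 1.44, 1.29, 0.49),
    ("SF2", "figural", "slow", 0.58, 0.17, 3.71, 1.37, 1.48, 0.92),
    ("SF3", "figural", "slow", 0.50, 0.18, 3.06, 0.81, 0.91, 0.40),
    ("SN1", "numeric", "slow", 0.70, 0.22, 4.00, 1.53, 1.63, 1.21),
    ("SN2", "numeric", "slow", 0.80, 0.25, 3.25, 0.92, 0.84, 0.31),
    ("SN3", "numeric", "slow", 1.08, 0.33, 2.85, 0.92, 1.50, 0.42),
    ("SV1", "verbal", "slow", 1.17, 0.20, 3.08, 0.84, 1.09, 0.35),
    ("SV2", "verbal", "slow", 1.03, 0.29, 3.19, 0.87, 1.45, 0.42),
    ("SV3", "verbal", "slow", 0.90, 0.23, 3.69, 1.23, 1.64, 0.41),
]

TASK_TABLE = pd.DataFrame(
    _TASK_ROWS,
    columns=["task_id", "domain", "complexity", "m_v", "sd_v", "m_a", "sd_a", "m_t0", "sd_t0"],
)

# subtest layout: (scale, domain) -- 6 processing capacity (2/domain),
# 3 psychometric speed, 3 memory (1/domain each) => 4 subtests per domain
_SUBTESTS = [
    ("processing_capacity", "figural"), ("processing_capacity", "figural"),
    ("processing_capacity", "numeric"), ("processing_capacity", "numeric"),
    ("processing_capacity", "verbal"), ("processing_capacity", "verbal"),
    ("psychometric_speed", "figural"), ("psychometric_speed", "numeric"),
    ("psychometric_speed", "verbal"),
    ("memory", "figural"), ("memory", "numeric"), ("memory", "verbal"),
]


@dataclass
class CohortConfig:
    """Study-design and latent-structure settings for the synthetic cohort.

    Loadings are standardized path coefficients; the subtest loading pairs
    (lambda_v, lambda_t0) give psychometric-speed subtests a larger
    non-decision-time share than processing-capacity subtests.
    """

    n_participants: int = 123
    age_min: float = 18.0
    age_max: float = 62.0
    trials_per_task: int = 100
    age_t0_loading: float = 0.55
    age_a_loading: float = 0.45
    age_v_loading: float = 0.0
    cubic_drift_age: bool = False     # optional: drift peaks near age 30
    t0_a_residual_r: float = 0.3
    cross_task_r: float = 0.5         # correlation of a parameter's true
                                      # values across any two tasks
    spread_scale: float = 1.0         # scales the between-person SD of the
                                      # per-task true parameters (0 => none)
    noise_scale: float = 1.0          # scales subtest unique noise (0 => g is
                                      # an exact function of the latents)
    st0_fraction: float = 0.15        # st0 = fraction * t0
    contaminant_fraction: float = 0.005
    contaminant_range: tuple = (0.15, 0.30)
    # subtest loadings: scale -> (lambda_v, lambda_t0)
    subtest_loadings: dict = field(
        default_factory=lambda: {
            "processing_capacity": (0.50, 0.35),
            "psychometric_speed": (0.25, 0.60),
            "memory": (0.40, 0.40),
        }
    )
    domain_loading: float = 0.25
    master_seed: int = 0

    def __post_init__(self):
        for name in ("age_t0_loading", "age_a_loading", "age_v_loading"):
            if abs(getattr(self, name)) > 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if abs(self.t0_a_residual_r) > 1.0:
            raise ValueError("t0_a_residual_r must lie in [-1, 1]")
        if not 0 < self.cross_task_r <= 1.0:
            raise ValueError("cross_task_r must lie in (0, 1]")
        for scale, (lv, lt) in self.subtest_loadings.items():
            if lv**2 + lt**2 + self.domain_loading**2 >= 1.0:
                raise ValueError(
                    f"subtest loadings for {scale} imply negative unique variance"
                )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame    # id, age, latents, subtests, scale scores
    trials: pd.DataFrame          # participant_id, task_id, trial, rt, correct
    true_params: pd.DataFrame     # participant_id, task_id, v, a, t0, st0
    config: CohortConfig


def _seed_for(config: CohortConfig, label: str, seed=None) -> np.random.Generator:
    master = config.master_seed if seed is None else seed
    sub = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big") % 2**31
    return np.random.default_rng(np.random.SeedSequence([int(master), sub]))


def generate_participants(config: CohortConfig, seed=None) -> pd.DataFrame:
    """Ages plus standardized latent traits (t0*, a*, v*) with the configured
    age loadings and a residual t0*-a* correlation; v* is age-independent by
    default, or hump-shaped in age (peak ~30) in cubic mode."""
    rng = _seed_for(config, "participants", seed)
    n = config.n_participants
    age = rng.uniform(config.age_min, config.age_max, n)
    age_z = (age - age.mean()) / age.std(ddof=1)

    l_t0, l_a, l_v = config.age_t0_loading, config.age_a_loading, config.age_v_loading
    r_res = config.t0_a_residual_r
    u1, u2, u3 = rng.standard_normal((3, n))
    t0_lat = l_t0 * age_z + np.sqrt(1 - l_t0**2) * u1
    a_res = r_res * u1 + np.sqrt(1 - r_res**2) * u2
    a_lat = l_a * age_z + np.sqrt(1 - l_a**2) * a_res
    if config.cubic_drift_age:
        # rises to a peak near age 30, declines after; standardized afterwards
        shape = -((age - 30.0) / 25.0) ** 2 + 0.15 * ((age - 30.0) / 25.0) ** 3
        shape = (shape - shape.mean()) / shape.std(ddof=1)
        v_lat = 0.5 * shape + np.sqrt(1 - 0.25) * u3
    else:
        v_lat = l_v * age_z + np.sqrt(1 - l_v**2) * u3

    return pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(n)],
            "age": age,
            "lat_t0": t0_lat,
            "lat_a": a_lat,
            "lat_v": v_lat,
        }
    )


def _lognormal_map(mu: float, sd: float, latent: np.ndarray) -> np.ndarray:
    """Map standardized latents to positive values with mean mu and SD sd."""
    s = np.sqrt(np.log1p((sd / mu) ** 2))
    return mu * np.exp(s * latent - 0.5 * s * s)


def true_parameter_table(
    participants: pd.DataFrame, config: CohortConfig, seed=None
) -> pd.DataFrame:
    """Per participant x task true parameters.

    Each task's latent is a mixture of the participant's general trait and a
    task-unique component, so any two tasks share correlation
    ``cross_task_r`` in their true values before the lognormal map.
    """
    rng = _seed_for(config, "task_uniqueness", seed)
    lam = np.sqrt(config.cross_task_r)
    uniq = np.sqrt(1.0 - config.cross_task_r)
    n = len(participants)
    rows = []
    for _, task in TASK_TABLE.iterrows():
        lat_v = lam * participants["lat_v"].to_numpy() + uniq * rng.standard_normal(n)
        lat_a = lam * participants["lat_a"].to_numpy() + uniq * rng.standard_normal(n)
        lat_t0 = lam * participants["lat_t0"].to_numpy() + uniq * rng.standard_normal(n)
        ss = config.spread_scale
        v = _lognormal_map(task.m_v, ss * task.sd_v, lat_v)
        a = _lognormal_map(task.m_a, ss * task.sd_a, lat_a)
        t0 = _lognormal_map(task.m_t0, ss * task.sd_t0, lat_t0)
        # safety clip; essentially unreachable under the lognormal map
        v = np.clip(v, 0.02, 40.0)
        a = np.clip(a, 0.2, 15.0)
        t0 = np.clip(t0, 0.08, 8.0)
        st0 = config.st0_fraction * t0
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": participants["participant_id"],
                    "task_id": task.task_id,
                    "domain": task.domain,
                    "complexity": task.complexity,
                    "v": v,
                    "a": a,
                    "t0": t0,
                    "st0": st0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_trials(
    participants: pd.DataFrame, config: CohortConfig, seed=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every participant x task block from its true parameters.

    A small configurable fraction of trials is replaced by fast contaminants
    (uniform on ``contaminant_range`` seconds, random response) so the
    minimum-RT screen has something to remove.

    Returns ``(trials, true_params)``.
    """
    true_params = true_parameter_table(participants, config, seed)
    rng = _seed_for(config, "trials", seed)
    n_tr = config.trials_per_task
    frames = []
    for row in true_params.itertuples():
        params = DiffusionParams(v=row.v, a=row.a, t0=row.t0, st0=row.st0)
        ts = simulate_trials(params, n_tr, seed=rng.integers(2**31 - 1))
        rt, correct = ts.rt, ts.correct.astype(np.int64)
        if config.contaminant_fraction > 0:
            m = rng.random(n_tr) < config.contaminant_fraction
            rt = rt.copy()
            rt[m] = rng.uniform(*config.contaminant_range, m.sum())
            correct = correct.copy()
            correct[m] = rng.integers(0, 2, m.sum())
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": row.participant_id,
                    "task_id": row.task_id,
                    "trial": np.arange(n_tr),
                    "rt": rt,
                    "correct": correct,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), true_params


def generate_intelligence(
    participants: pd.DataFrame, config: CohortConfig, seed=None
) -> pd.DataFrame:
    """Subtest and scale scores from the latent traits.

    subtest = lambda_v * v* - lambda_t0 * t0* + lambda_dom * domain + noise,
    with unit total variance.  Scale scores are means of their subtests;
    g is the mean of all 12; content-domain scores are the 4 subtests
    sharing a domain.
    """
    rng = _seed_for(config, "intelligence", seed)
    n = len(participants)
    dom_factors = {d: rng.standard_normal(n) for d in ("figural", "numeric", "verbal")}
    lat_v = participants["lat_v"].to_numpy()
    lat_t0 = participants["lat_t0"].to_numpy()

    out = participants.copy()
    subtest_cols = []
    for j, (scale, domain) in enumerate(_SUBTESTS):
        lv, lt = config.subtest_loadings[scale]
        ld = config.domain_loading
        noise_sd = config.noise_scale * np.sqrt(max(1.0 - lv**2 - lt**2 - ld**2, 0.0))
        score = lv * lat_v - lt * lat_t0 + ld * dom_factors[domain] + noise_sd * rng.standard_normal(n)
        col = f"subtest_{j:02d}_{scale[:4]}_{domain[:3]}"
        out[col] = score
        subtest_cols.append((col, scale, domain))

    for scale in ("processing_capacity", "psychometric_speed", "memory"):
        cols = [c for c, s, _ in subtest_cols if s == scale]
        out[scale] = out[cols].mean(axis=1)
    for domain in ("figural", "numeric", "verbal"):
        cols = [c for c, _, d in subtest_cols if d == domain]
        out[domain] = out[cols].mean(axis=1)
    out["g"] = out[[c for c, _, _ in subtest_cols]].mean(axis=1)
    return out


def generate_cohort(config: CohortConfig | None = None, seed=None) -> SyntheticCohort:
    """Full cohort: participants with intelligence scores, trials, truths."""
    config = config if config is not None else CohortConfig()
    participants = generate_participants(config, seed)
    participants = generate_intelligence(participants, config, seed)
    trials, true_params = generate_trials(participants, config, seed)
    return SyntheticCohort(
        participants=participants, trials=trials, true_params=true_params, config=config
    )
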