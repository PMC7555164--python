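"""End-to-end workflow: simulate/ingest -> screen -> fit -> composites ->
mediation, with a machine-readable results bundle and run manifest.

Stage order follows the exclusion cascade: minimum-RT floor, per-block IQR
trial filter, per-block ML fits, fit-adequacy exclusion, task-level
mean-RT/accuracy exclusion, multivariate participant screen; composites and
all downstream analyses use the post-exclusion sample.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composites as comp
from . import mediation as med
from . import screening as scr
from .cohort import TASK_TABLE, CohortConfig, generate_cohort
from .ddm import TrialSet, fit_ml, fit_quality_check

__all__ = ["PipelineConfig", "RunManifest", "fit_blocks", "build_composites", "run_pipeline"]

DOMAINS = ("figural", "numeric", "verbal")


@dataclass
class PipelineConfig:
    """Analysis settings; cohort settings ride along for `simulate`."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    min_rt_ms: float = 300.0
    iqr_k: float = 3.0
    fit_check_n_sim: int = 100
    fit_check_q: float = 0.05
    mahalanobis_p: float = 0.001
    # With ~93 features and ~123 participants minus incomplete rows, the
    # classical covariance is singular; the pseudo-inverse metric is an
    # explicit, documented opt-in.
    mahalanobis_pseudo_inverse: bool = True
    n_boot: int = 5000
    conf: float = 0.995
    alpha: float = 0.005
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = CohortConfig(**d.pop("cohort", {}))
        return cls(cohort=cohort, **d)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_timings: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    exclusion_counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    completed_stages: list = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]


def fit_blocks(
    trials: pd.DataFrame,
    config: PipelineConfig,
    progress: bool = False,
) -> pd.DataFrame:
    """ML fit + adequacy check per participant x task block.

    Returns one row per block: mean RT, mean log RT, accuracy, n trials,
    fitted parameters, convergence, and the parametric-bootstrap verdict.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for (pid, tid), block in trials.groupby(["participant_id", "task_id"], sort=True):
        rt = block["rt"].to_numpy()
        correct = block["correct"].to_numpy()
        row = {
            "participant_id": pid,
            "task_id": tid,
            "n_trials": len(block),
            "mean_rt": float(rt.mean()),
            "mean_log_rt": float(np.log(rt).mean()),
            "accuracy": float(correct.mean()),
        }
        fit_seed = int(rng.integers(2**31 - 1))
        check_seed = int(rng.integers(2**31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_ml(
                TrialSet(rt=rt, correct=correct, participant_id=str(pid), task_id=str(tid)),
                seed=fit_seed,
                adaptive_starts=True,
            )
            if fit.converged:
                fit = fit_quality_check(
                    TrialSet(rt=rt, correct=correct),
                    fit,
                    n_sim=config.fit_check_n_sim,
                    seed=check_seed,
                    q=config.fit_check_q,
                )
        row.update(
            v=fit.params.v, a=fit.params.a, t0=fit.params.t0, st0=fit.params.st0,
            loglik=fit.loglik, converged=fit.converged,
            fit_ok=bool(fit.fit_ok) if fit.fit_ok is not None else False,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _apply_cell_exclusions(summaries: pd.DataFrame, config: PipelineConfig, report):
    """Fit-based and task-level cell exclusions (masked, not dropped)."""
    s = summaries.copy()
    s["excluded_fit"] = ~(s["converged"] & s["fit_ok"])
    report.record("fit_inadequate", int(s["excluded_fit"].sum()), threshold=config.fit_check_q)

    s["excluded_task_level"] = False
    for tid, grp in s.groupby("task_id"):
        flags = scr.task_level_exclusion(
            grp["mean_rt"].to_numpy(), grp["accuracy"].to_numpy(), k=config.iqr_k
        )
        s.loc[grp.index[flags], "excluded_task_level"] = True
    report.record("task_level", int(s["excluded_task_level"].sum()), threshold=config.iqr_k)
    s["excluded_cell"] = s["excluded_fit"] | s["excluded_task_level"]
    return s


def _mahalanobis_features(summaries: pd.DataFrame, participants: pd.DataFrame):
    """93-feature matrix: v, a, t0, st0 and mean RT per task (x18) plus the
    three intelligence content-domain scores."""
    s = summaries.copy()
    s.loc[s["excluded_cell"], ["v", "a", "t0", "st0", "mean_rt"]] = np.nan
    wide = s.pivot(index="participant_id", columns="task_id",
                   values=["v", "a", "t0", "st0", "mean_rt"])
    wide.columns = [f"{m}_{t}" for m, t in wide.columns]
    feats = wide.join(participants.set_index("participant_id")[list(DOMAINS)])
    return feats


def screen_participants(summaries, participants, config, report):
    feats = _mahalanobis_features(summaries, participants)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        flags, d2, crit = scr.mahalanobis_exclusion(
            feats.to_numpy(), p=config.mahalanobis_p,
            pseudo_inverse=config.mahalanobis_pseudo_inverse,
        )
    excluded = feats.index[flags]
    report.record("mahalanobis", int(flags.sum()), threshold=crit, flags=list(excluded))
    return set(excluded)


def build_composites(
    summaries: pd.DataFrame,
    participants: pd.DataFrame,
    excluded_participants=(),
) -> pd.DataFrame:
    """Per-participant z-composites of v, a, t0 and mean log RT, overall and
    per content domain, merged with age and intelligence scores."""
    s = summaries[~summaries["participant_id"].isin(set(excluded_participants))].copy()
    s.loc[s["excluded_cell"], ["v", "a", "t0", "st0", "mean_log_rt", "mean_rt"]] = np.nan
    task_domain = TASK_TABLE.set_index("task_id")["domain"]

    out = participants[
        ["participant_id", "age", "g", "processing_capacity", "psychometric_speed",
         "memory", *DOMAINS]
    ].copy()
    out = out[~out["participant_id"].isin(set(excluded_participants))]
    out = out.set_index("participant_id")

    for measure, label in (
        ("v", "comp_v"), ("a", "comp_a"), ("t0", "comp_t0"), ("mean_log_rt", "comp_logrt")
    ):
        wide = s.pivot(index="participant_id", columns="task_id", values=measure)
        z = comp.zscore_by_task(wide)
        out[label] = comp.composite_mean(z)
        for domain in DOMAINS:
            cols = [t for t in z.columns if task_domain.get(t) == domain]
            out[f"{label}_{domain}"] = comp.composite_mean(z, cols)
    return out.reset_index()


def _alpha_table(summaries: pd.DataFrame) -> dict:
    alphas = {}
    s = summaries.copy()
    s.loc[s["excluded_cell"], ["v", "a", "t0", "mean_log_rt"]] = np.nan
    for measure in ("v", "a", "t0", "mean_log_rt"):
        wide = s.pivot(index="participant_id", columns="task_id", values=measure)
        try:
            alphas[measure] = comp.cronbach_alpha(comp.zscore_by_task(wide))
        except ValueError:
            alphas[measure] = float("nan")
    return alphas


def run_pipeline(
    config: PipelineConfig | None = None,
    trials: pd.DataFrame | None = None,
    participants: pd.DataFrame | None = None,
    out_dir=None,
    stages=("simulate", "screen", "fit", "analyze"),
) -> dict:
    """Run the workflow and return the results bundle as a dict.

    With no input tables, a synthetic cohort is generated from
    ``config.cohort``.  If ``out_dir`` is given, the bundle is written out as
    CSV/JSON files plus a run manifest.
    """
    config = config if config is not None else PipelineConfig()
    manifest = RunManifest(config=asdict(config), seed=config.seed)
    report = scr.ScreenReport()
    bundle: dict = {"screen_report": report, "manifest": manifest}
    t_start = time.time()

    def tick(stage):
        manifest.stage_timings[stage] = round(time.time() - t_start, 3)
        manifest.completed_stages.append(stage)

    true_params = None
    if trials is None:
        if "simulate" not in stages:
            raise ValueError("no input trials and simulate stage not requested")
        cohort = generate_cohort(config.cohort, seed=config.seed)
        trials, participants = cohort.trials, cohort.participants
        true_params = cohort.true_params
        bundle["true_params"] = true_params
        tick("simulate")
    manifest.input_hashes["trials"] = _hash_frame(trials)

    n_before = len(trials)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screened = scr.screen_trials(
            trials, floor_ms=config.min_rt_ms, k=config.iqr_k, report=report
        )
    manifest.exclusion_counts["trials_removed"] = n_before - len(screened)
    tick("screen")

    summaries = fit_blocks(screened, config)
    summaries = _apply_cell_exclusions(summaries, config, report)
    bundle["summaries"] = summaries
    tick("fit")

    excluded = screen_participants(summaries, participants, config, report)
    manifest.exclusion_counts.update(report.stages)

    composites_table = build_composites(summaries, participants, excluded)
    bundle["composites"] = composites_table
    bundle["alphas"] = _alpha_table(
        summaries[~summaries["participant_id"].isin(excluded)]
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle["correlations_age"] = comp.correlation_table(
            composites_table.drop(columns=["participant_id"]), "age", config.alpha
        )
        bundle["correlations_g"] = comp.correlation_table(
            composites_table.drop(columns=["participant_id"]), "g", config.alpha
        )
        bundle["mediation"] = med.run_model_suite(
            composites_table, n_boot=config.n_boot, conf=config.conf, seed=config.seed
        )
        cc = composites_table.dropna(subset=["age", "comp_v"])
        bundle["cubic_v_age"] = comp.cubic_age_trend(cc["age"], cc["comp_v"])
    tick("analyze")

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), manifest, report)
    return bundle


def _write_bundle(bundle, out_dir: Path, manifest: RunManifest, report) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    def save(name, obj):
        path = out_dir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=isinstance(obj.index, pd.MultiIndex) or obj.index.name is not None)
        else:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, default=str)
        manifest.outputs.append(name)

    save("summaries.csv", bundle["summaries"])
    save("composites.csv", bundle["composites"])
    save("correlations_age.csv", bundle["correlations_age"])
    save("correlations_g.csv", bundle["correlations_g"])
    save("alphas.json", bundle["alphas"])
    med_frame = pd.concat([r.to_frame() for r in bundle["mediation"].values()])
    save("mediation.csv", med_frame)
    med_json = {
        name: {
            "total_effect": r.total_effect,
            "direct_effect": r.direct_effect,
            "proportion_mediated_pct": r.proportion_mediated,
            "indirect": {
                m: {"estimate": float(r.indirect_effects[i]),
                    "ci_low": float(r.ci_low[i]), "ci_high": float(r.ci_high[i]),
                    "excludes_zero": bool(r.ci_low[i] > 0 or r.ci_high[i] < 0)}
                for i, m in enumerate(r.mediators)
            },
            "suppression": r.suppression,
        }
        for name, r in bundle["mediation"].items()
    }
    save("mediation.json", med_json)
    cubic = dict(bundle["cubic_v_age"])
    cubic = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in cubic.items()}
    cubic.pop("fitted", None)
    save("cubic_v_age.json", cubic)
    with open(out_dir / "screen_report.json", "w") as fh:
        fh.write(report.to_json())
    manifest.outputs.append("screen_report.json")
    manifest.save(out_dir / "manifest.json")


def render_report(bundle: dict) -> str:
    """Human-readable markdown summary of a results bundle."""
    lines = ["# agediff results", ""]
    warnings_block = []
    alphas = bundle.get("alphas")
    if alphas:
        lines.append("## Composite reliability (Cronbach's alpha)")
        for k, v in alphas.items():
            lines.append(f"- {k}: {v:.2f}")
        lines.append("")
    corr = bundle.get("correlations_age")
    if corr is not None:
        lines.append("## Age correlations of composites (* p<0.005, ** p<0.001)")
        for var in ("comp_v", "comp_a", "comp_t0", "comp_logrt", "g"):
            if var in corr.index:
                row = corr.loc[var]
                lines.append(f"- {var}: r = {row['r']:.2f}{row['sig']}")
        lines.append("")
    mediation = bundle.get("mediation", {})
    lines.append("## Mediation models (standardized paths, 99.5% bootstrap CIs)")
    for name in med.MODEL_SPECS:
        if name not in mediation:
            lines.append(f"### {name}: absent")
            warnings_block.append(f"{name} missing from bundle")
            continue
        r = mediation[name]
        lines.append(f"### {name} (outcome {med.MODEL_SPECS[name][0]}, n={r.n})")
        lines.append(f"- total effect c = {r.total_effect:.2f}, direct c' = {r.direct_effect:.2f}")
        pm = r.proportion_mediated
        supp = " (suppression: direct effect of opposite sign)" if r.suppression else ""
        lines.append(f"- proportion of total effect mediated: {pm:.0f}%{supp}")
        for i, m in enumerate(r.mediators):
            star = "*" if (r.ci_low[i] > 0 or r.ci_high[i] < 0) else ""
            lines.append(
                f"- indirect via {m}: {r.indirect_effects[i]:.3f} "
                f"[{r.ci_low[i]:.3f}, {r.ci_high[i]:.3f}]{star}"
            )
        lines.append("")
    if warnings_block:
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in warnings_block)
    return "\n".join(lines)
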