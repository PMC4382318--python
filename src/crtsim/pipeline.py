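"""Orchestration of the full simulation study.

The study proceeds in five steps: expand the design grid into calibrated
parameter sets; estimate fixed-size power over a range of actual cluster
counts; estimate variable-size power at each coefficient-of-variation
level; interpolate each power curve at the 80% target to get required
cluster counts; and summarize how much cluster-size variability inflates
the requirement relative to the closed-form calibration.

Results are persisted as plain tab-separated text with a schema-version
header. Runs are deterministic given the master seed and invariant to the
worker count: every (scenario, cluster count, cv) job derives its own seed
from the master seed and its grid coordinates, and each replicate inside a
job gets its own substream.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .interpolate import PowerCurve, interpolate_required, percent_change
from .params import ParameterSet
from .power import PowerEstimate, estimate_power_fixed, estimate_power_variable
from .simulate import assign_arms, simulate_trial
from .sizes import draw_cluster_sizes, fixed_cluster_sizes
from .inference import test_treatment_effect

logger = logging.getLogger(__name__)

SCHEMA_HEADER = "# crtsim results schema v1"

__all__ = [
    "ExperimentConfig",
    "ComparisonSummary",
    "expand_parameter_sets",
    "c_actual_for",
    "expand_grid",
    "run_study",
    "summarize",
    "replay_trial",
]

# Table-style defaults for the full study grid
_TABLE_DEFAULTS = dict(
    alpha=0.05,
    beta=0.2,
    mu_values=(20, 50, 75, 100, 125),
    icc_values=(0.001, 0.002, 0.006, 0.01, 0.03, 0.08, 0.2),
    bcv_values=(0.01, 0.1, 1.0),
    c80_values=(10, 20, 40, 60),
    c_actual_values=(5, 10, 15, 20, 40, 60, 80, 100, 120),
    cv_values=(0.5, 1.0, 1.5),
    n_sims_fixed=5000,
    n_sims_variable=2000,
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Study configuration: grids, replicate counts, seed, execution options.

    The defaults are the full study grid. ``profile="reduced"`` swaps in
    small replicate counts (500 fixed / 200 variable) for quick runs unless
    counts are given explicitly.
    """

    alpha: float = _TABLE_DEFAULTS["alpha"]
    beta: float = _TABLE_DEFAULTS["beta"]
    mu_values: tuple[float, ...] = _TABLE_DEFAULTS["mu_values"]
    icc_values: tuple[float, ...] = _TABLE_DEFAULTS["icc_values"]
    bcv_values: tuple[float, ...] = _TABLE_DEFAULTS["bcv_values"]
    c80_values: tuple[int, ...] = _TABLE_DEFAULTS["c80_values"]
    c_actual_values: tuple[int, ...] = _TABLE_DEFAULTS["c_actual_values"]
    cv_values: tuple[float, ...] = _TABLE_DEFAULTS["cv_values"]
    n_sims_fixed: int = _TABLE_DEFAULTS["n_sims_fixed"]
    n_sims_variable: int = _TABLE_DEFAULTS["n_sims_variable"]
    master_seed: int = 0
    n_workers: int = 1
    output_dir: str = "crtsim_results"
    method: str = "mixed"  # or "cluster-means"
    profile: str = "full"  # or "reduced"
    target_power: float = 0.8

    def __post_init__(self) -> None:
        if self.profile not in ("full", "reduced"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if not self.mu_values or not self.icc_values or not self.bcv_values \
                or not self.c80_values or not self.c_actual_values:
            raise ValueError("empty parameter grid")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("mu_values", "icc_values", "bcv_values", "c80_values",
                    "c_actual_values", "cv_values"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if cfg.profile == "reduced":
            if "n_sims_fixed" not in raw:
                cfg = dataclasses.replace(cfg, n_sims_fixed=500)
            if "n_sims_variable" not in raw:
                cfg = dataclasses.replace(cfg, n_sims_variable=200)
        return cfg

    def reduced(self, **overrides) -> "ExperimentConfig":
        base = dict(profile="reduced", n_sims_fixed=500, n_sims_variable=200)
        base.update(overrides)
        return dataclasses.replace(self, **base)


def expand_parameter_sets(config: ExperimentConfig) -> list[ParameterSet]:
    """Cartesian expansion of the scenario grid into calibrated parameter sets."""
    sets = [
        ParameterSet(alpha=config.alpha, beta=config.beta, mu=mu, icc=icc, bcv=bcv, c80=c80)
        for mu, icc, bcv, c80 in itertools.product(
            config.mu_values, config.icc_values, config.bcv_values, config.c80_values
        )
    ]
    if not sets:
        raise ValueError("empty parameter grid")
    return sets


def c_actual_for(config: ExperimentConfig, c80: int) -> list[int]:
    """Actual-cluster-count ladder for one scenario.

    Large counts are only simulated where the scenario needs them to reach
    power 1: 80 clusters only when c80 > 10, and 100/120 only when c80 > 20.
    """
    out = []
    for c in config.c_actual_values:
        if c == 80 and c80 <= 10:
            continue
        if c in (100, 120) and c80 <= 20:
            continue
        out.append(c)
    return out


def expand_grid(config: ExperimentConfig) -> list[tuple[int, ParameterSet, int, float]]:
    """All (theta_id, params, c_actual, cv) jobs; cv=0 denotes fixed sizes."""
    jobs = []
    for theta_id, params in enumerate(expand_parameter_sets(config)):
        for c_actual in c_actual_for(config, params.c80):
            for cv in (0.0, *config.cv_values):
                jobs.append((theta_id, params, c_actual, cv))
    return jobs


def _job_seed(master_seed: int, theta_id: int, c_actual: int, cv: float) -> np.random.SeedSequence:
    # keyed by grid coordinates, not job order, so results are invariant
    # to scheduling and worker count
    return np.random.SeedSequence([master_seed, theta_id, c_actual, int(round(cv * 10))])


def _run_job(config: ExperimentConfig, theta_id: int, params: ParameterSet,
             c_actual: int, cv: float) -> dict:
    seed = _job_seed(config.master_seed, theta_id, c_actual, cv)
    if cv == 0.0:
        est = estimate_power_fixed(params, c_actual, config.n_sims_fixed, seed,
                                   method=config.method)
    else:
        est = estimate_power_variable(params, c_actual, cv, config.n_sims_variable,
                                      seed, method=config.method)
    return dict(
        theta_id=theta_id, mu=params.mu, icc=params.icc, bcv=params.bcv,
        c80=params.c80, delta=params.delta, cv=cv, c_actual=c_actual,
        power=est.power, n_sims=est.n_sims, mc_se=est.mc_se,
        n_rejections=est.n_rejections, n_fallback=est.n_fallback,
    )


def _write_table(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps power == n_rejections/n_sims exact on reload
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


@dataclass
class ComparisonSummary:
    """How simulated requirements compare with the closed-form calibration."""

    n_scenarios: int
    n_excluded: dict[str, int]  # cv label -> curves without a valid crossing
    corr_chat_fixed_vs_c80: float
    mean_diff_fixed_vs_c80: float
    paired_tests: dict[str, dict[str, float]]  # label -> estimate/CI/p
    pct_change_summary: dict[str, dict[str, float]]  # cv -> median/min/max

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def summarize(required: pd.DataFrame, target_c80: pd.Series | None = None) -> ComparisonSummary:
    """Build the comparison summary from a required-clusters table.

    Only scenarios whose curves cross the target at every variability
    level contribute to the paired comparisons; exclusions are counted per
    level, never silently dropped.
    """
    wide = required.pivot_table(index="theta_id", columns="cv", values="c_hat")
    c80 = required.drop_duplicates("theta_id").set_index("theta_id")["c80"]
    levels = sorted(required["cv"].unique())
    n_excluded = {
        str(cv): int(wide[cv].isna().sum()) if cv in wide else 0 for cv in levels
    }
    complete = wide.dropna()
    fixed = complete[0.0] if 0.0 in complete else pd.Series(dtype=float)
    c80_c = c80.loc[complete.index]

    if len(complete) >= 2 and 0.0 in complete:
        # correlation is undefined when either side is constant
        if fixed.nunique() > 1 and c80_c.nunique() > 1:
            corr = float(np.corrcoef(fixed, c80_c)[0, 1])
        else:
            corr = float("nan")
        mean_diff = float((fixed - c80_c).mean())
    else:
        corr, mean_diff = float("nan"), float("nan")

    paired = {}
    pairs = [("fixed_minus_c80", fixed, c80_c)] if 0.0 in complete else []
    cvs = [cv for cv in levels if cv > 0]
    for lo, hi in zip([0.0] + cvs[:-1], cvs):
        if lo in complete and hi in complete:
            pairs.append((f"cv{hi}_minus_cv{lo}" if lo > 0 else f"cv{hi}_minus_fixed",
                          complete[hi], complete[lo]))
    for label, a, b in pairs:
        d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        if len(d) >= 2 and d.std(ddof=1) > 0:
            t = stats.ttest_1samp(d, 0.0)
            lo_ci, hi_ci = t.confidence_interval()
            paired[label] = dict(estimate=float(d.mean()), ci_low=float(lo_ci),
                                 ci_high=float(hi_ci), p_value=float(t.pvalue))
        else:
            paired[label] = dict(estimate=float(d.mean()) if len(d) else float("nan"),
                                 ci_low=float("nan"), ci_high=float("nan"),
                                 p_value=float("nan"))

    pct = {}
    for cv in cvs:
        if cv not in complete:
            continue
        vals = 100.0 * (complete[cv] - c80_c) / c80_c
        pct[str(cv)] = dict(median=float(vals.median()), min=float(vals.min()),
                            max=float(vals.max()))

    return ComparisonSummary(
        n_scenarios=int(required["theta_id"].nunique()),
        n_excluded=n_excluded,
        corr_chat_fixed_vs_c80=corr,
        mean_diff_fixed_vs_c80=mean_diff,
        paired_tests=paired,
        pct_change_summary=pct,
    )


def run_study(config: ExperimentConfig) -> dict[str, Path]:
    """Execute the study end to end and persist result tables.

    Returns paths to the power table, the required-clusters table, and the
    JSON comparison summary. If a power table from an interrupted run is
    present in the output directory, completed jobs are reused and only the
    missing ones are computed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    power_path = outdir / "power_estimates.tsv"
    req_path = outdir / "required_clusters.tsv"
    summary_path = outdir / "comparison_summary.json"

    jobs = expand_grid(config)
    done: dict[tuple[int, int, float], dict] = {}
    if power_path.exists():
        try:
            prev = read_table(power_path)
            for row in prev.to_dict("records"):
                done[(int(row["theta_id"]), int(row["c_actual"]), float(row["cv"]))] = row
            logger.info("resuming: %d completed jobs found", len(done))
        except Exception:
            logger.warning("could not parse existing %s; recomputing", power_path)

    pending = [(t, p, c, cv) for t, p, c, cv in jobs if (t, c, cv) not in done]
    if pending:
        if config.n_workers > 1:
            from joblib import Parallel, delayed

            rows = Parallel(n_jobs=config.n_workers)(
                delayed(_run_job)(config, t, p, c, cv) for t, p, c, cv in pending
            )
        else:
            rows = [_run_job(config, t, p, c, cv) for t, p, c, cv in pending]
        for row in rows:
            done[(row["theta_id"], row["c_actual"], row["cv"])] = row

    power_df = pd.DataFrame(list(done.values())).sort_values(
        ["theta_id", "cv", "c_actual"]).reset_index(drop=True)
    _write_table(power_df, power_path)

    n_fallback = int(power_df["n_fallback"].sum())
    if n_fallback:
        logger.info("fallback test used on %d replicates", n_fallback)

    req_rows = []
    for (theta_id, cv), grp in power_df.groupby(["theta_id", "cv"]):
        ests = [
            PowerEstimate(power=r.power, n_sims=int(r.n_sims), c_actual=int(r.c_actual),
                          cv_label=cv, n_rejections=int(r.n_rejections),
                          n_fallback=int(r.n_fallback))
            for r in grp.itertuples()
        ]
        curve = PowerCurve.from_estimates(ests)
        rc = interpolate_required(curve, target=config.target_power)
        first = grp.iloc[0]
        req_rows.append(dict(
            theta_id=theta_id, mu=first.mu, icc=first.icc, bcv=first.bcv,
            c80=int(first.c80), cv=cv, c_hat=rc.c_hat, status=rc.status,
            bracket_low_c=rc.bracket_low[0] if rc.ok else float("nan"),
            bracket_low_p=rc.bracket_low[1] if rc.ok else float("nan"),
            bracket_high_c=rc.bracket_high[0] if rc.ok else float("nan"),
            bracket_high_p=rc.bracket_high[1] if rc.ok else float("nan"),
            pct_change=percent_change(rc.c_hat, first.c80) if rc.ok else float("nan"),
        ))
        if not rc.ok:
            logger.info("theta %d cv %.1f: no %.0f%% crossing (%s)",
                        theta_id, cv, 100 * config.target_power, rc.status)
    req_df = pd.DataFrame(req_rows)
    _write_table(req_df, req_path)

    summary = summarize(req_df)
    summary_path.write_text(summary.to_json() + "\n")

    return {"power": power_path, "required": req_path, "summary": summary_path}


def replay_trial(config: ExperimentConfig, theta_id: int, c_actual: int,
                 cv: float, replicate: int):
    """Re-run a single replicate trial in isolation, byte-identical to the study run.

    Returns the (TrialData, TestResult) pair for the given replicate index
    of the given (scenario, cluster count, cv) job.
    """
    params = expand_parameter_sets(config)[theta_id]
    seed = _job_seed(config.master_seed, theta_id, c_actual, cv)
    rng = np.random.default_rng(seed.spawn(replicate + 1)[-1])
    if cv == 0.0:
        sizes = fixed_cluster_sizes(params.mu, c_actual)
    else:
        sizes = draw_cluster_sizes(params.mu, cv, c_actual, rng)
    arms = assign_arms(c_actual, rng)
    trial = simulate_trial(params, sizes, arms, rng)
    result = test_treatment_effect(trial, params.alpha, method=config.method)
    return trial, result
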