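"""Design-optimization experiments on synthetic cohorts.

Provides the trial-number cumulative/binned curves, between-arm design
comparisons (transition ratio, drift set, difficulty/order), and a
config-driven scenario runner that chains simulate → exclude → fit →
psychometrics and writes all artifacts to a directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .taskmodel import (InvalidArgument, TaskConfig, config_from_dict,
                        default_config, write_trials_csv)
from .cohort import PopulationSpec, apply_exclusions, associate, synth_population
from .psychometrics import split_half_oddeven
from . import stayfit

log = logging.getLogger(__name__)

COMPARE_FACTORS = ("transition_ratio", "drift_set", "difficulty_order")


# ---------------------------------------------------------------------------
# trial-number curves
# ---------------------------------------------------------------------------

@dataclass
class CurveResult:
    mode: str                       # "cumulative" or "binned"
    grid: list                      # trial counts or (lo, hi) ranges
    table: pd.DataFrame             # one row per grid point
    n_subjects: int
    n_dropped: int


def _estimate_point(rows: pd.DataFrame, covariates, estimator: str):
    if estimator == "hierarchical":
        fit = stayfit.fit_hierarchical(rows)
        mbi = stayfit.extract_mbi(fit)
    else:
        mbi = stayfit.extract_mbi(stayfit.pointwise_table(rows))
    rec = {"mean_mbi": float(mbi.mean()), "sd_mbi": float(mbi.std())}
    try:
        rel = split_half_oddeven(rows, estimator=estimator)
        rec.update(split_half_r=rel.r, split_half_lo=rel.ci_low,
                   split_half_hi=rel.ci_high)
    except InvalidArgument:
        rec.update(split_half_r=np.nan, split_half_lo=np.nan,
                   split_half_hi=np.nan)
    if covariates is not None:
        assoc = associate(mbi, covariates.loc[mbi.index.intersection(covariates.index)])
        for term, row in assoc.iterrows():
            rec[f"beta_{term}"] = row["estimate"]
            rec[f"se_{term}"] = row["se"]
    return rec, mbi


def trial_number_curve(
    trials: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    step: int = 25,
    max_trials: int = 300,
    mode: str = "cumulative",
    estimator: str = "hierarchical",
) -> CurveResult:
    """Re-estimate the MBI on growing (cumulative) or sliding (binned)
    trial windows, with reliability and covariate associations per point.

    Subjects with fewer than ``max_trials`` scheduled trials are dropped.
    """
    if mode not in ("cumulative", "binned"):
        raise InvalidArgument("mode must be 'cumulative' or 'binned'")
    if step <= 0 or max_trials % step != 0:
        raise InvalidArgument("step must be positive and divide max_trials")
    n_sched = trials.groupby("subject")["trial"].max() + 1
    long_enough = n_sched[n_sched >= max_trials].index
    n_dropped = n_sched.size - long_enough.size
    if n_dropped:
        log.info("trial_number_curve: dropped %d subject(s) with < %d trials",
                 n_dropped, max_trials)
    kept = trials[trials["subject"].isin(set(long_enough))
                  & (trials["trial"] < max_trials)]
    if kept.empty:
        raise InvalidArgument("no subject has enough trials for the curve")

    grid, records = [], []
    for upper in range(step, max_trials + 1, step):
        if mode == "cumulative":
            window = kept[kept["trial"] < upper]
            grid.append(upper)
        else:
            window = kept[(kept["trial"] >= upper - step)
                          & (kept["trial"] < upper)]
            grid.append((upper - step, upper))
        rows = stayfit.build_stay_design(window.reset_index(drop=True))
        rec, _ = _estimate_point(rows, covariates, estimator)
        rec["grid"] = grid[-1]
        rec["n_rows"] = len(rows)
        records.append(rec)
    table = pd.DataFrame(records).set_index(
        pd.Index([str(g) for g in grid], name="grid_point"))
    return CurveResult(mode=mode, grid=grid, table=table,
                       n_subjects=long_enough.size, n_dropped=int(n_dropped))


# ---------------------------------------------------------------------------
# design comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    factor: str
    labels: tuple
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float
    paired: bool
    comparison_fit: Optional[stayfit.HierFit] = None
    trait_interaction: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        d = {"factor": self.factor, "labels": list(self.labels),
             "mean_a": self.mean_a, "sd_a": self.sd_a, "n_a": self.n_a,
             "mean_b": self.mean_b, "sd_b": self.sd_b, "n_b": self.n_b,
             "t": self.t, "p": self.p, "paired": self.paired}
        if self.comparison_fit is not None:
            d["comparison_fixed"] = json.loads(
                self.comparison_fit.to_json())["fixed"]
        if self.trait_interaction is not None:
            d["trait_interaction"] = self.trait_interaction.to_dict()
        return d


def compare_design(
    factor: str,
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    labels: tuple = ("A", "B"),
    covariates_a: Optional[pd.DataFrame] = None,
    covariates_b: Optional[pd.DataFrame] = None,
    trait_col: str = "c",
    paired: bool = False,
    estimator: str = "hierarchical",
) -> ComparisonReport:
    """Compare per-subject MBI between two task-design arms.

    Each arm is estimated separately (group means/SDs, Welch or paired t),
    and a pooled comparison model adds the arm code (+1 for A, −1 for B)
    interacted with every base term.  With covariates supplied, a
    trait × arm interaction is tested on the per-subject estimates.
    """
    if factor not in COMPARE_FACTORS:
        raise InvalidArgument(f"unknown comparison factor {factor!r}")
    rows_a = stayfit.build_stay_design(cohort_a)
    rows_b = stayfit.build_stay_design(cohort_b)
    overlap = set(rows_a["subject"]) & set(rows_b["subject"])
    if overlap and not paired:
        raise InvalidArgument(
            "cohorts share subjects; use paired=True or disjoint cohorts")
    if paired and set(rows_a["subject"]) != set(rows_b["subject"]):
        raise InvalidArgument("paired comparison needs identical subjects")

    def _mbi(rows):
        if estimator == "hierarchical":
            return stayfit.extract_mbi(stayfit.fit_hierarchical(rows))
        return stayfit.extract_mbi(stayfit.pointwise_table(rows))

    mbi_a, mbi_b = _mbi(rows_a), _mbi(rows_b)
    if paired:
        a, b = mbi_a.align(mbi_b, join="inner")
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(mbi_a, mbi_b, equal_var=False)

    fit = None
    if not paired:
        tag_a = rows_a.assign(subject="A::" + rows_a["subject"].astype(str))
        tag_b = rows_b.assign(subject="B::" + rows_b["subject"].astype(str))
        pooled = pd.concat([tag_a, tag_b], ignore_index=True)
        group = pd.Series(
            {s: (1 if str(s).startswith("A::") else -1)
             for s in pooled["subject"].unique()})
        fit = stayfit.fit_comparison(pooled, group, label=factor)

    trait_tab = None
    if covariates_a is not None and covariates_b is not None \
            and trait_col in covariates_a.columns:
        da = pd.DataFrame({"mbi": mbi_a,
                           "trait": covariates_a[trait_col].reindex(mbi_a.index),
                           "arm": 1.0})
        db = pd.DataFrame({"mbi": mbi_b,
                           "trait": covariates_b[trait_col].reindex(mbi_b.index),
                           "arm": -1.0})
        dd = pd.concat([da, db]).dropna()
        X = pd.DataFrame({
            "trait": dd["trait"], "arm": dd["arm"],
            "trait_x_arm": dd["trait"] * dd["arm"],
        }, index=dd.index)
        trait_tab = associate(dd["mbi"], X, standardize=False)

    return ComparisonReport(
        factor=factor, labels=labels,
        mean_a=float(mbi_a.mean()), sd_a=float(mbi_a.std()), n_a=len(mbi_a),
        mean_b=float(mbi_b.mean()), sd_b=float(mbi_b.std()), n_b=len(mbi_b),
        t=float(t), p=float(p), paired=paired,
        comparison_fit=fit, trait_interaction=trait_tab)


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

BUILTIN_SCENARIOS: dict[str, dict] = {
    # population mean MBI should be indistinguishable from zero
    "null_cohort": {
        "task": {"p_common": 0.8},
        "population": {"n_subjects": 120, "kind": "uniform_random"},
        "estimation": {"estimator": "hierarchical"},
        "experiments": {"reliability": True},
    },
    # continuous model-based weight; report recovery correlation
    "recovery": {
        "task": {"p_common": 0.8},
        "population": {"n_subjects": 300, "kind": "hybrid",
                       "w_dist": "uniform", "beta_temp": 5.0},
        "estimation": {"estimator": "hierarchical"},
        "experiments": {"reliability": True, "recovery": True},
    },
}


def _population_from_config(pconf: dict) -> tuple[PopulationSpec, str]:
    kind = pconf.get("kind", "hybrid")
    keys = {f.name for f in dataclasses.fields(PopulationSpec)}
    spec = PopulationSpec(**{k: v for k, v in pconf.items() if k in keys})
    return spec, kind


def run_scenario(config, out_dir, seed: int = 0) -> Path:
    """Execute a full pipeline from a scenario config.

    ``config`` may be a bundled scenario name, a path to a YAML file, or a
    dict.  Outputs (trial log, covariates, coefficient table, JSON
    reports, run log) land in ``out_dir``; on failure partial outputs are
    removed.  Fully deterministic given (config, seed).
    """
    if isinstance(config, str) and config in BUILTIN_SCENARIOS:
        name, conf = config, BUILTIN_SCENARIOS[config]
    elif isinstance(config, dict):
        name, conf = conf_name(config), config
    else:
        path = Path(config)
        with open(path) as fh:
            conf = yaml.safe_load(fh)
        name = path.stem
    _validate_scenario(conf)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_scenario_inner(name, conf, out, seed)
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise


def conf_name(conf: dict) -> str:
    return conf.get("name", "scenario")


def _validate_scenario(conf: dict) -> None:
    required = {"task", "population"}
    missing = required - set(conf)
    if missing:
        raise InvalidArgument(f"scenario config missing sections: {sorted(missing)}")
    if "n_subjects" not in conf["population"]:
        raise InvalidArgument("scenario config missing key: population.n_subjects")


def _run_scenario_inner(name: str, conf: dict, out: Path, seed: int) -> Path:
    task_conf = dict(conf.get("task", {}))
    n_blocks = task_conf.pop("n_blocks", 2)
    if "blocks" in task_conf:
        config = config_from_dict(task_conf)
    else:
        config = default_config(n_blocks=n_blocks, **task_conf)
    pconf = dict(conf.get("population", {}))
    kind = pconf.pop("kind", "hybrid")
    spec, _ = _population_from_config(pconf)
    estimator = conf.get("estimation", {}).get("estimator", "hierarchical")
    experiments = conf.get("experiments", {})

    if kind == "uniform_random":
        # a hybrid agent with w=0, alpha irrelevant and beta_temp=0 chooses
        # uniformly at random
        spec = dataclasses.replace(spec, beta_temp=0.0, stickiness=0.0,
                                   w_noise_sd=0.0)
    trials, covariates = synth_population(spec, config, seed=seed)

    report: dict = {"scenario": name, "seed": seed, "version": __version__,
                    "n_subjects": spec.n_subjects}

    excl = apply_exclusions(trials)
    report["exclusions"] = excl.counts
    trials_kept = excl.filter(trials)

    rows = stayfit.build_stay_design(trials_kept)
    if estimator == "hierarchical":
        fit = stayfit.fit_hierarchical(rows)
        mbi = stayfit.extract_mbi(fit)
        coefs = fit.subject_coefficients()
        fit.to_json(out / "model.json")
        est = fit.fixed.loc["reward_x_transition"]
        report["population_mbi"] = {
            "estimate": float(est["estimate"]), "se": float(est["se"]),
            "ci": [float(est["estimate"] - 1.96 * est["se"]),
                   float(est["estimate"] + 1.96 * est["se"])],
        }
    else:
        coefs = stayfit.pointwise_table(rows)
        mbi = stayfit.extract_mbi(coefs)
        report["population_mbi"] = {"estimate": float(mbi.mean())}

    if experiments.get("reliability"):
        rel = split_half_oddeven(rows, estimator=estimator)
        report["split_half"] = rel.to_dict()
    if experiments.get("recovery"):
        joined = pd.concat(
            [mbi.rename("mbi"), covariates["w_true"]], axis=1).dropna()
        r = float(np.corrcoef(joined["w_true"], joined["mbi"])[0, 1])
        report["recovery_r"] = r

    write_trials_csv(trials, out / "trials.csv")
    covariates.to_csv(out / "covariates.csv")
    coefs.to_csv(out / "coefficients.csv")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    with open(out / "run.log", "w") as fh:
        fh.write(f"scenario={name}\nseed={seed}\nversion={__version__}\n"
                 f"numpy={np.__version__}\npandas={pd.__version__}\n")
    return out
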