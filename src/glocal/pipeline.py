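"""Reproducible generate -> fit -> measure -> correlate runs.

``run_pipeline`` takes a fully explicit :class:`RunConfig` (every seed and
setting serialisable to YAML), produces per-subject parameter and index
tables, and emits a report with the study's headline quantities:

* model-driven cross-task correlation: fitted theta_perceptual vs fitted
  theta_preference;
* data-driven cross-task correlation: accuracy congruency effect vs
  global-consistent choice fraction;
* loss-aversion method agreement and its (non-)relation to global bias;
* AIC comparison of the value model against the gain>loss heuristic.

Reports are pure functions of (config, input tables): identical inputs give
identical reports.  Ground truth (when simulating) is read only by the
clearly-labelled optional recovery-evaluation step.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .design import DISTANCE_BINS, NUMERIC_TRIAL_COLUMNS, PREFERENCE_TRIAL_COLUMNS
from .measures import pearson_r, subject_indices
from .numcog import fit_numcog
from .preference import fit_heuristic, fit_preference
from .synth import PopulationConfig, sample_population, simulate_study

__all__ = ["RunConfig", "ValidationReport", "validate_trials", "run_pipeline"]

log = logging.getLogger("glocal")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; round-trips through YAML."""

    outdir: str = "glocal_run"
    seed: int = 7
    simulate_first: bool = True
    numeric_trials: str | None = None
    preference_trials: str | None = None
    population: PopulationConfig = field(default_factory=PopulationConfig)
    pref_fit_starts: int = 10
    numcog_fit_starts: int = 2
    sims_per_cell: int = 500
    numcog_maxiter: int = 80
    distance_bins: tuple[tuple[int, int], ...] = DISTANCE_BINS
    rt_trim: tuple[float, float] | None = None
    evaluate_recovery: bool = True
    jobs: int = 1

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["distance_bins"] = [list(b) for b in self.distance_bins]
        d["rt_trim"] = list(self.rt_trim) if self.rt_trim else None
        d["population"]["numcog_param_ranges"] = {
            k: list(v) for k, v in self.population.numcog_param_ranges.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        pop = dict(d.pop("population", {}))
        if "numcog_param_ranges" in pop:
            pop["numcog_param_ranges"] = {
                k: tuple(v) for k, v in pop["numcog_param_ranges"].items()
            }
        d["population"] = PopulationConfig(**pop)
        if "distance_bins" in d:
            d["distance_bins"] = tuple(tuple(b) for b in d["distance_bins"])
        if d.get("rt_trim") is not None:
            d["rt_trim"] = tuple(d["rt_trim"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ValidationReport:
    path: str
    task: str
    errors: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_trials(path: str | Path, task: str) -> ValidationReport:
    """Schema / domain / design-count checks on a trial CSV.

    Domain violations are errors; deviations from the nominal per-subject
    trial counts (448 numeric, 512 preference) are warnings, since real data
    may legitimately contain dropped trials.
    """
    errors: list[str] = []
    warnings: list[str] = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        return ValidationReport(str(path), task, [f"unreadable CSV: {exc}"], [])
    if task == "numeric":
        required, expected_n = NUMERIC_TRIAL_COLUMNS, 448
    elif task == "preference":
        required, expected_n = PREFERENCE_TRIAL_COLUMNS, 512
    else:
        return ValidationReport(str(path), task, [f"unknown task {task!r}"], [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        errors.append(f"missing columns: {missing}")
        return ValidationReport(str(path), task, errors, warnings)

    def domain(col: str, ok_mask: pd.Series, desc: str) -> None:
        bad = df.index[~ok_mask]
        for row in bad[:5]:
            errors.append(f"row {row}, column {col!r}: {df.loc[row, col]!r} {desc}")
        if len(bad) > 5:
            errors.append(f"... and {len(bad) - 5} more rows with bad {col!r}")

    if task == "numeric":
        for col in ("global_digit", "local_digit"):
            domain(col, df[col].between(2, 9), "outside digits 2..9")
        domain("response", df["response"].isin(["global", "local"]),
               "not in {'global','local'}")
        domain("correct", df["correct"].isin([0, 1]), "not in {0,1}")
        domain("rt_s", df["rt_s"] > 0, "not a positive RT")
    else:
        for col in ("gain", "loss"):
            domain(col, df[col].between(2, 9), "outside amounts 2..9")
        domain("condition", df["condition"].isin(["GGLL", "GLLG"]),
               "not in {'GGLL','GLLG'}")
        domain("response", df["response"].isin(["accept", "reject"]),
               "not in {'accept','reject'}")
    counts = df.groupby("subject_id").size()
    for sid, n in counts.items():
        if n != expected_n:
            warnings.append(
                f"subject {sid}: {n} trials (expected {expected_n})"
            )
    return ValidationReport(str(path), task, errors, warnings)


def _corr_entry(x, y, label: str) -> dict[str, Any]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    from scipy.stats import spearmanr

    r, p = pearson_r(x[keep], y[keep])
    rs = spearmanr(x[keep], y[keep])
    return {
        "label": label,
        "n": int(keep.sum()),
        "pearson_r": r,
        "pearson_p": p,
        "spearman_r": float(rs.statistic),
        "spearman_p": float(rs.pvalue),
    }


def _fit_one_subject(args) -> dict[str, Any]:
    sid, num, pref, cfg_d = args
    cfg = RunConfig.from_dict(cfg_d)
    pf = fit_preference(pref, n_starts=cfg.pref_fit_starts, seed=cfg.seed + sid)
    hf = fit_heuristic(pref)
    nf = fit_numcog(
        num,
        sims_per_cell=cfg.sims_per_cell,
        n_starts=cfg.numcog_fit_starts,
        seed=cfg.seed + sid,
        maxiter=cfg.numcog_maxiter,
        bins=cfg.distance_bins,
    )
    idx = subject_indices(num, pref, bins=cfg.distance_bins, rt_range=cfg.rt_trim)
    return {
        "subject_id": sid,
        "beta": pf.params.beta, "lam": pf.params.lam,
        "theta_pref": pf.params.theta_pref,
        "pref_loglik": pf.loglik, "pref_aic": pf.aic,
        "pref_converged": pf.converged,
        "heuristic_eps": hf.params.eps, "heuristic_aic": hf.aic,
        "theta_perc": nf.params.theta_perc, "threshold": nf.params.threshold,
        "t_nd": nf.params.t_nd, "time_scale": nf.params.time_scale,
        "numcog_chi2": nf.chi2, "numcog_converged": nf.converged,
        "acc_congruency": idx.acc_congruency, "rt_congruency": idx.rt_congruency,
        "global_fraction": idx.global_fraction,
        "la_rejection_ev0": idx.la_rejection_ev0 if idx.la_rejection_ev0 is not None else np.nan,
        "la_acceptance": idx.la_acceptance,
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full study pipeline; returns (and writes) the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "data"
    truth = None
    try:
        if config.simulate_first:
            log.info("stage %s: simulating population", stage)
            pop = sample_population(config.population)
            numeric, preference, truth = simulate_study(pop, config.seed, outdir)
        else:
            numeric = pd.read_csv(config.numeric_trials)
            preference = pd.read_csv(config.preference_trials)
            for path, task in ((config.numeric_trials, "numeric"),
                               (config.preference_trials, "preference")):
                rep = validate_trials(path, task)
                if not rep.ok:
                    raise ValueError(f"invalid {task} table {path}: {rep.errors[:3]}")

        stage = "fit+measure"
        sids = sorted(numeric["subject_id"].unique())
        tasks = [
            (
                int(sid),
                numeric[numeric["subject_id"] == sid],
                preference[preference["subject_id"] == sid],
                config.to_dict(),
            )
            for sid in sids
        ]
        if config.jobs > 1:
            from concurrent.futures import ProcessPoolExecutor

            with ProcessPoolExecutor(max_workers=config.jobs) as ex:
                rows = list(ex.map(_fit_one_subject, tasks))
        else:
            rows = []
            for t in tasks:
                log.info("stage %s: subject %d", stage, t[0])
                rows.append(_fit_one_subject(t))
        subjects = pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)
        subjects.to_csv(outdir / "subjects.csv", index=False)

        stage = "correlate"
        correlations = {
            "model_driven": _corr_entry(
                subjects["theta_perc"], subjects["theta_pref"],
                "fitted theta_perceptual vs fitted theta_preference",
            ),
            "data_driven": _corr_entry(
                subjects["acc_congruency"], subjects["global_fraction"],
                "accuracy congruency effect vs global-consistent choice fraction",
            ),
            "la_methods": _corr_entry(
                subjects["la_rejection_ev0"], subjects["la_acceptance"],
                "loss aversion method 1 (EV=0 rejection) vs method 2 (acceptance)",
            ),
            "la_vs_global_bias": _corr_entry(
                subjects["lam"], subjects["theta_pref"],
                "fitted loss aversion vs fitted global-salience (preference)",
            ),
        }
        aic = {
            "value_model_total_aic": float(subjects["pref_aic"].sum()),
            "heuristic_total_aic": float(subjects["heuristic_aic"].sum()),
            "n_subjects_value_preferred": int(
                (subjects["pref_aic"] < subjects["heuristic_aic"]).sum()
            ),
        }
        report: dict[str, Any] = {
            "config": config.to_dict(),
            "n_subjects": len(subjects),
            "correlations": correlations,
            "aic_comparison": aic,
        }
        if truth is not None and config.evaluate_recovery:
            # recovery evaluation: the ONLY stage that reads generating truth
            stage = "recovery"
            merged = subjects.merge(truth, on="subject_id", suffixes=("_fit", "_true"))
            report["recovery"] = {
                "theta_pref": _corr_entry(
                    merged["theta_pref_true"], merged["theta_pref_fit"],
                    "true vs fitted theta_preference",
                ),
                "theta_perc": _corr_entry(
                    merged["theta_perc_true"], merged["theta_perc_fit"],
                    "true vs fitted theta_perceptual",
                ),
                "generating_rho_theta": config.population.rho_theta,
            }
    except Exception as exc:
        log.error("pipeline aborted in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    (outdir / "report.txt").write_text(_format_report(report))
    return report


def _format_report(report: dict[str, Any]) -> str:
    lines = [
        "glocal pipeline report",
        f"seed: {report['config']['seed']}   subjects: {report['n_subjects']}",
        "",
        "Cross-subject correlations (Pearson r [p] / Spearman r):",
    ]
    for key, c in report["correlations"].items():
        lines.append(
            f"  {key:20s} r={c['pearson_r']:+.3f} [p={c['pearson_p']:.3g}] "
            f"/ rho={c['spearman_r']:+.3f}   ({c['label']})"
        )
    aic = report["aic_comparison"]
    lines += [
        "",
        "Preference model comparison (summed over subjects; lower AIC is better):",
        f"  AIC value model = {aic['value_model_total_aic']:.0f}, "
        f"AIC heuristic = {aic['heuristic_total_aic']:.0f}, "
        f"value preferred for {aic['n_subjects_value_preferred']}/{report['n_subjects']} subjects",
    ]
    if "recovery" in report:
        rec = report["recovery"]
        lines += [
            "",
            "Parameter recovery vs generating truth "
            f"(generating rho_theta = {rec['generating_rho_theta']}):",
            f"  theta_preference: r={rec['theta_pref']['pearson_r']:+.3f}",
            f"  theta_perceptual: r={rec['theta_perc']['pearson_r']:+.3f}",
        ]
    return "\n".join(lines) + "\n"
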