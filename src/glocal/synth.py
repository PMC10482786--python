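"""Synthetic subject populations with known, correlated global/local biases.

Individual differences are placed on log theta so that global (theta > 1) and
local (theta < 1) biases are symmetric around no bias: (log theta_perceptual,
log theta_preference) are drawn bivariate normal with a controllable
correlation rho_theta; loss aversion and utility sensitivity are log-normal;
accumulator nuisance parameters are uniform in configured ranges.

``simulate_study`` then produces a complete two-session study — a 448-trial
numerical comparison session and a 512-trial gamble session per subject, with
counterbalanced framing-block order — plus a ground-truth parameter table, so
the whole fit/measure/correlate pipeline can be exercised and validated
without human data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import build_session
from .numcog import NumCogParams, simulate_numcog_dataset
from .preference import PreferenceParams, simulate_preference

__all__ = [
    "DEFAULT_NUMCOG_RANGES",
    "PopulationConfig",
    "SubjectRecord",
    "sample_population",
    "simulate_study",
]

#: Uniform sampling ranges for the accumulator nuisance parameters.
DEFAULT_NUMCOG_RANGES: dict[str, tuple[float, float]] = {
    "threshold": (2.2, 2.6),
    "t_nd": (0.25, 0.35),
    "time_scale": (0.04, 0.06),
}

TRUTH_COLUMNS = [
    "subject_id", "theta_perc", "theta_pref", "lam", "beta",
    "threshold", "t_nd", "time_scale", "condition_order",
]


@dataclass
class PopulationConfig:
    """Generating distribution of a synthetic-subject population.

    rho_theta is the correlation between log theta_perceptual and log
    theta_preference — the quantity the cross-task analysis estimates.
    sd_log_theta = 0.2 puts most biases in theta ~ [0.67, 1.5] around a
    median of 1 (no bias).
    """

    n_subjects: int = 30
    rho_theta: float = 0.8
    sd_log_theta: float = 0.2
    mu_log_theta: float = 0.0
    lam_log_mean: float = math.log(1.5)
    lam_log_sd: float = 0.3
    beta_log_mean: float = math.log(0.8)
    beta_log_sd: float = 0.3
    numcog_param_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NUMCOG_RANGES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if abs(self.rho_theta) > 1:
            raise ValueError("|rho_theta| must be <= 1")
        if self.sd_log_theta <= 0 or self.lam_log_sd <= 0 or self.beta_log_sd <= 0:
            raise ValueError("all SDs must be strictly positive")


@dataclass
class SubjectRecord:
    """One subject: generating parameters, and (after fitting) estimates."""

    subject_id: int
    pref_params: PreferenceParams
    numcog_params: NumCogParams
    condition_order: str
    fitted_pref: PreferenceParams | None = None
    fitted_numcog: NumCogParams | None = None


def _subject_seed(seed: int, subject_id: int, offset: int = 0) -> int:
    return (seed + 1000003 * subject_id + offset) % 2**31


def sample_population(config: PopulationConfig) -> list[SubjectRecord]:
    """Draw a population of subjects with known parameters."""
    rng = np.random.default_rng(config.seed)
    cov = (config.sd_log_theta**2) * np.array(
        [[1.0, config.rho_theta], [config.rho_theta, 1.0]]
    )
    log_thetas = rng.multivariate_normal(
        [config.mu_log_theta, config.mu_log_theta], cov, size=config.n_subjects,
        method="cholesky" if abs(config.rho_theta) < 1 else "svd",
    )
    lam = np.exp(rng.normal(config.lam_log_mean, config.lam_log_sd, config.n_subjects))
    beta = np.exp(rng.normal(config.beta_log_mean, config.beta_log_sd, config.n_subjects))
    ranges = config.numcog_param_ranges
    uni = {k: rng.uniform(lo, hi, config.n_subjects) for k, (lo, hi) in ranges.items()}
    subjects = []
    for s in range(config.n_subjects):
        theta_perc, theta_pref = np.exp(log_thetas[s])
        subjects.append(
            SubjectRecord(
                subject_id=s,
                pref_params=PreferenceParams(
                    beta=float(beta[s]), lam=float(lam[s]), theta_pref=float(theta_pref)
                ),
                numcog_params=NumCogParams(
                    theta_perc=float(theta_perc),
                    threshold=float(uni["threshold"][s]),
                    t_nd=float(uni["t_nd"][s]),
                    time_scale=float(uni["time_scale"][s]),
                ),
                # counterbalancing alternates by subject index
                condition_order="GGLL_first" if s % 2 == 0 else "GLLG_first",
            )
        )
    return subjects


def simulate_study(
    population: list[SubjectRecord],
    seed: int,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate both sessions for every subject.

    Returns (numeric trials, preference trials, truth) tables; the truth
    table holds generating parameters only, never responses.  If ``outdir``
    is given, writes numeric_trials.csv, preference_trials.csv, truth.csv.
    Per-subject seeds derive deterministically from ``seed`` and the subject
    id, so any subject can be regenerated in isolation.
    """
    num_parts, pref_parts, truth_rows = [], [], []
    for subj in population:
        s = subj.subject_id
        num_design = build_session("numeric", _subject_seed(seed, s, 0))
        pref_design = build_session(
            "preference", _subject_seed(seed, s, 1), condition_order=subj.condition_order
        )
        num = simulate_numcog_dataset(num_design, subj.numcog_params,
                                      _subject_seed(seed, s, 2))
        pref = simulate_preference(pref_design, subj.pref_params,
                                   _subject_seed(seed, s, 3))
        num["subject_id"] = s
        pref["subject_id"] = s
        num_parts.append(num)
        pref_parts.append(pref)
        truth_rows.append(
            {
                "subject_id": s,
                "theta_perc": subj.numcog_params.theta_perc,
                "theta_pref": subj.pref_params.theta_pref,
                "lam": subj.pref_params.lam,
                "beta": subj.pref_params.beta,
                "threshold": subj.numcog_params.threshold,
                "t_nd": subj.numcog_params.t_nd,
                "time_scale": subj.numcog_params.time_scale,
                "condition_order": subj.condition_order,
            }
        )
    numeric = pd.concat(num_parts, ignore_index=True)
    preference = pd.concat(pref_parts, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        numeric.to_csv(outdir / "numeric_trials.csv", index=False)
        preference.to_csv(outdir / "preference_trials.csv", index=False)
        truth.to_csv(outdir / "truth.csv", index=False)
    return numeric, preference, truth
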