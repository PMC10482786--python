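"""Data-driven, model-free per-subject indices.

Numerical task: congruency effects (accuracy and correct-RT differences
between trials where the global digit is larger vs smaller) and distance
profiles (accuracy / median correct RT per numerical-distance bin).

Preference task: the global-consistent choice fraction (accept when the gain
is global, reject when the loss is global — the data-driven salience index)
and two loss-aversion measures (rejection rate at EV = 0; overall acceptance
rate).  RT summaries use medians of correct trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DISTANCE_BINS, distance_bin_label

__all__ = [
    "SubjectIndices",
    "congruency_effect",
    "distance_effect",
    "global_fraction",
    "loss_aversion_measures",
    "loss_aversion_indifference_ev",
    "pearson_r",
    "cousineau_morey_se",
    "subject_indices",
]


@dataclass
class SubjectIndices:
    """One subject's model-free summary of both sessions."""

    acc_congruency: float  # acc(congruent) - acc(incongruent), in [-1, 1]
    rt_congruency: float  # median correct RT incongruent - congruent, seconds
    distance_profile: pd.DataFrame  # per-bin accuracy and median correct RT
    global_fraction: float  # in [0, 1]
    la_rejection_ev0: float | None  # method 1; None if no EV=0 trials
    la_acceptance: float  # method 2


def _rt_trim(trials: pd.DataFrame, rt_range: tuple[float, float] | None) -> pd.DataFrame:
    if rt_range is None:
        return trials
    lo, hi = rt_range
    return trials[(trials["rt_s"] >= lo) & (trials["rt_s"] <= hi)]


def congruency_effect(
    trials: pd.DataFrame, rt_range: tuple[float, float] | None = None
) -> tuple[float, float]:
    """(accuracy difference, median-correct-RT difference) by congruency.

    Accuracy difference is congruent minus incongruent (positive = global
    precedence); the RT difference is incongruent minus congruent on correct
    trials, so both are positive under a global bias.  Optional ``rt_range``
    trims RTs before the RT contrast (off by default).
    """
    for cong in (True, False):
        if not (trials["congruent"] == cong).any():
            raise ValueError(f"no trials with congruent == {cong}")
    acc = trials.groupby("congruent")["correct"].mean()
    t = _rt_trim(trials, rt_range)
    med = t[t["correct"] == 1].groupby("congruent")["rt_s"].median()
    acc_diff = float(acc.get(True, np.nan) - acc.get(False, np.nan))
    rt_diff = float(med.get(False, np.nan) - med.get(True, np.nan))
    return acc_diff, rt_diff


def distance_effect(
    trials: pd.DataFrame,
    bins: tuple[tuple[int, int], ...] = DISTANCE_BINS,
    rt_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Accuracy and median correct RT per numerical-distance bin."""
    t = trials.copy()
    t["dist_bin"] = [distance_bin_label(d, bins) for d in t["distance"]]
    tt = _rt_trim(t, rt_range)
    rows = []
    for lo, hi in bins:
        label = f"{lo}-{hi}"
        cell = t[t["dist_bin"] == label]
        if len(cell) == 0:
            raise ValueError(f"no trials in distance bin {label}")
        corr = tt[(tt["dist_bin"] == label) & (tt["correct"] == 1)]
        rows.append(
            {
                "dist_bin": label,
                "n": len(cell),
                "accuracy": float(cell["correct"].mean()),
                "median_rt_correct": float(corr["rt_s"].median()) if len(corr) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def global_fraction(trials: pd.DataFrame) -> float:
    """Fraction of trials answered purely by the global level.

    Counts accepts when the global digit is the gain (GGLL) plus rejects when
    the global digit is the loss (GLLG), over all trials.  1.0 means the
    subject followed the global level regardless of magnitudes; an EV-driven
    responder lands near 0.5 on the condition-balanced design.
    """
    conds = set(trials["condition"].unique())
    if not {"GGLL", "GLLG"} <= conds:
        raise ValueError(f"need both framing conditions, got {sorted(conds)}")
    ggll = trials["condition"] == "GGLL"
    accepted = trials["response"] == "accept"
    consistent = np.where(ggll, accepted, ~accepted)
    return float(np.mean(consistent))


def loss_aversion_measures(trials: pd.DataFrame) -> tuple[float | None, float]:
    """Two model-free loss-aversion indices.

    Method 1: rejection rate among EV = 0 (gain == loss) gambles; a
    loss-neutral chooser sits at 0.5, loss aversion pushes it above.  None if
    no EV = 0 trials exist.  Method 2: overall acceptance rate on the
    gain/loss-symmetric design; loss aversion pushes it below 0.5.
    """
    ev0 = trials[trials["ev"] == 0]
    la1 = float((ev0["response"] == "reject").mean()) if len(ev0) else None
    la2 = float((trials["response"] == "accept").mean())
    return la1, la2


def loss_aversion_indifference_ev(trials: pd.DataFrame) -> float:
    """EV at the acceptance indifference point (logistic fit variant).

    Fits accept ~ logistic(a + b*EV) by maximum likelihood and returns -a/b,
    the EV at which p(accept) = 0.5; positive values indicate loss aversion.
    """
    from scipy.optimize import minimize
    from scipy.special import expit

    ev = trials["ev"].to_numpy(float)
    y = (trials["response"] == "accept").to_numpy(float)

    def negll(x):
        p = np.clip(expit(x[0] + x[1] * ev), 1e-10, 1 - 1e-10)
        return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

    res = minimize(negll, np.array([0.0, 1.0]), method="BFGS")
    a, b = res.x
    if abs(b) < 1e-8:
        raise ValueError("acceptance does not depend on EV; indifference undefined")
    return float(-a / b)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cousineau_morey_se(data: pd.DataFrame, subject: str, condition: str,
                       value: str) -> pd.Series:
    """Within-subject SEs of condition means (Cousineau-Morey correction).

    Subject means are removed, the grand mean added back, and per-condition
    SEs scaled by sqrt(C / (C - 1)).  For plotting parity only.
    """
    d = data.copy()
    subj_mean = d.groupby(subject)[value].transform("mean")
    d["_norm"] = d[value] - subj_mean + d[value].mean()
    c = d[condition].nunique()
    if c < 2:
        raise ValueError("need at least two conditions")
    per_subj = d.groupby([subject, condition])["_norm"].mean().reset_index()
    se = per_subj.groupby(condition)["_norm"].sem()
    return se * np.sqrt(c / (c - 1))


def subject_indices(
    numeric_trials: pd.DataFrame,
    preference_trials: pd.DataFrame,
    bins: tuple[tuple[int, int], ...] = DISTANCE_BINS,
    rt_range: tuple[float, float] | None = None,
) -> SubjectIndices:
    """All model-free indices for one subject from both trial tables."""
    acc_c, rt_c = congruency_effect(numeric_trials, rt_range)
    la1, la2 = loss_aversion_measures(preference_trials)
    return SubjectIndices(
        acc_congruency=acc_c,
        rt_congruency=rt_c,
        distance_profile=distance_effect(numeric_trials, bins, rt_range),
        global_fraction=global_fraction(preference_trials),
        la_rejection_ev0=la1,
        la_acceptance=la2,
    )
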