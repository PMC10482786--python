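"""Logit model of mixed-gamble acceptance with loss aversion and global salience.

The probability of accepting a gamble is a logistic function of its subjective
utility, p(accept) = 1 / (1 + exp(-beta * U)).  Utility combines the gain and
loss magnitudes with a loss-aversion weight lambda and a global-salience
factor theta_pref that multiplies whichever amount is displayed at the global
level of the compound figure:

    GGLL (gain global):  U = gain * theta_pref - loss * lam
    GLLG (loss global):  U = gain - loss * lam * theta_pref

theta_pref > 1 means values shown globally loom larger (a global bias),
theta_pref < 1 a local bias, theta_pref = 1 no bias.  The value function is
linear in money (prospect-theory curvature fixed to 1).

Also provided: a rival one-parameter lapse model of the "accept iff
gain > loss" heuristic, maximum-likelihood fitting for both, and AIC/BIC for
comparing them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import qmc

from .design import Condition, Lottery, SessionDesign

__all__ = [
    "PreferenceParams",
    "HeuristicParams",
    "FitResult",
    "utility",
    "p_accept",
    "loglik_preference",
    "fit_preference",
    "loglik_heuristic",
    "fit_heuristic",
    "simulate_preference",
]

#: Probability floor guarding the Bernoulli log-likelihood.
P_FLOOR = 1e-10

#: Box bounds on the natural scale; optimisation runs on log parameters.
BOUNDS = {"beta": (0.01, 20.0), "lam": (0.2, 10.0), "theta_pref": (0.2, 5.0)}


@dataclass(frozen=True)
class PreferenceParams:
    """Parameters of the logit acceptance model.

    beta: sensitivity to utility (inverse choice noise), > 0.
    lam: loss aversion; losses are weighted lam times as much as gains.
    theta_pref: salience multiplier on the globally displayed amount;
        1 encodes no global/local bias.
    """

    beta: float
    lam: float
    theta_pref: float

    def __post_init__(self) -> None:
        if min(self.beta, self.lam, self.theta_pref) <= 0:
            raise ValueError("beta, lam and theta_pref must be strictly positive")


@dataclass(frozen=True)
class HeuristicParams:
    """Lapse rate of the accept-iff-gain>loss heuristic, 0 < eps < 0.5."""

    eps: float

    def __post_init__(self) -> None:
        if not (0.0 < self.eps < 0.5):
            raise ValueError("eps must lie in (0, 0.5)")


@dataclass
class FitResult:
    params: PreferenceParams | HeuristicParams
    loglik: float
    aic: float
    bic: float
    n_trials: int
    converged: bool
    n_starts: int


def _utility_arrays(
    gain: np.ndarray, loss: np.ndarray, is_ggll: np.ndarray, params: PreferenceParams
) -> np.ndarray:
    # The globally displayed magnitude is the one scaled by theta_pref.
    return np.where(
        is_ggll,
        gain * params.theta_pref - loss * params.lam,
        gain - loss * params.lam * params.theta_pref,
    )


def utility(lottery: Lottery, params: PreferenceParams) -> float:
    """Subjective utility of one lottery under ``params``."""
    is_ggll = Condition(lottery.condition) is Condition.GGLL
    return float(
        _utility_arrays(
            np.asarray(lottery.gain, float),
            np.asarray(lottery.loss, float),
            np.asarray(is_ggll),
            params,
        )
    )


def p_accept(lottery: Lottery, params: PreferenceParams) -> float:
    """Probability of accepting ``lottery``; p(reject) is its complement."""
    return float(expit(params.beta * utility(lottery, params)))


def _accept_probabilities(trials: pd.DataFrame, params: PreferenceParams) -> np.ndarray:
    u = _utility_arrays(
        trials["gain"].to_numpy(float),
        trials["loss"].to_numpy(float),
        trials["condition"].to_numpy() == Condition.GGLL.value,
        params,
    )
    return expit(params.beta * u)


def _check_preference_table(trials: pd.DataFrame) -> None:
    if len(trials) == 0:
        raise ValueError("empty trial table")
    bad = set(trials["response"].unique()) - {"accept", "reject"}
    if bad:
        raise ValueError(f"unknown responses {sorted(bad)}")


def loglik_preference(trials: pd.DataFrame, params: PreferenceParams) -> float:
    """Bernoulli log-likelihood of the observed accept/reject responses."""
    _check_preference_table(trials)
    p = _accept_probabilities(trials, params)
    accepted = trials["response"].to_numpy() == "accept"
    p_obs = np.where(accepted, p, 1.0 - p)
    return float(np.sum(np.log(np.clip(p_obs, P_FLOOR, None))))


def _aic_bic(loglik: float, k: int, n: int) -> tuple[float, float]:
    return 2 * k - 2 * loglik, k * np.log(n) - 2 * loglik


def fit_preference(
    trials: pd.DataFrame,
    n_starts: int = 10,
    seed: int = 0,
    include_equal: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of (beta, lam, theta_pref) for one subject.

    Optimises the log-transformed parameters (L-BFGS-B, box bounds) from
    ``n_starts`` seeded Latin-hypercube starting points and returns the best.
    ``include_equal=False`` drops gain == loss trials from the likelihood.

    Degenerate response patterns (all accept or all reject) cannot pin down
    the parameters; the best boundary solution is returned with
    ``converged=False``.
    """
    _check_preference_table(trials)
    if not include_equal:
        trials = trials[trials["gain"] != trials["loss"]]
    n = len(trials)
    if n < 50:
        raise ValueError(f"need at least 50 trials, got {n}")

    names = ("beta", "lam", "theta_pref")
    lo = np.log([BOUNDS[k][0] for k in names])
    hi = np.log([BOUNDS[k][1] for k in names])

    def negll(x: np.ndarray) -> float:
        b, l, t = np.exp(x)
        return -loglik_preference(trials, PreferenceParams(b, l, t))

    sampler = qmc.LatinHypercube(d=3, seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)

    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(negll, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)))
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    x = best.x
    at_boundary = bool(np.any(x <= lo + 1e-6) or np.any(x >= hi - 1e-6))
    degenerate = trials["response"].nunique() < 2
    b, l, t = np.exp(x)
    ll = -best.fun
    aic, bic = _aic_bic(ll, 3, n)
    return FitResult(
        params=PreferenceParams(b, l, t),
        loglik=ll,
        aic=aic,
        bic=bic,
        n_trials=n,
        converged=any_ok and not at_boundary and not degenerate,
        n_starts=n_starts,
    )


def _heuristic_probabilities(trials: pd.DataFrame, eps: float) -> np.ndarray:
    gain = trials["gain"].to_numpy(float)
    loss = trials["loss"].to_numpy(float)
    p = np.where(gain > loss, 1.0 - eps, np.where(gain < loss, eps, 0.5))
    return p


def loglik_heuristic(trials: pd.DataFrame, params: HeuristicParams) -> float:
    """Log-likelihood under the lapse-rate gain>loss heuristic."""
    _check_preference_table(trials)
    p = _heuristic_probabilities(trials, params.eps)
    accepted = trials["response"].to_numpy() == "accept"
    p_obs = np.where(accepted, p, 1.0 - p)
    return float(np.sum(np.log(np.clip(p_obs, P_FLOOR, None))))


def fit_heuristic(trials: pd.DataFrame, eps_min: float = 1e-3) -> FitResult:
    """Closed-form MLE of the heuristic lapse rate.

    eps is the fraction of heuristic-inconsistent responses among unequal
    gain/loss trials (equal trials contribute log 0.5 regardless of eps),
    clipped into [eps_min, 0.5 - eps_min].
    """
    _check_preference_table(trials)
    n = len(trials)
    gain = trials["gain"].to_numpy(float)
    loss = trials["loss"].to_numpy(float)
    accepted = trials["response"].to_numpy() == "accept"
    unequal = gain != loss
    if not unequal.any():
        raise ValueError("no unequal gain/loss trials; eps is unidentified")
    consistent = np.where(gain > loss, accepted, ~accepted)[unequal]
    eps_hat = 1.0 - consistent.mean()
    eps = float(np.clip(eps_hat, eps_min, 0.5 - eps_min))
    ll = loglik_heuristic(trials, HeuristicParams(eps))
    aic, bic = _aic_bic(ll, 1, n)
    return FitResult(
        params=HeuristicParams(eps),
        loglik=ll,
        aic=aic,
        bic=bic,
        n_trials=n,
        converged=True,
        n_starts=1,
    )


def simulate_preference(
    design: SessionDesign, params: PreferenceParams, seed: int
) -> pd.DataFrame:
    """Simulate one subject's preference session: Bernoulli accept draws.

    Returns a trial table with the standard preference schema (subject_id and
    session left for the caller to fill; set to 0/"preference" by default).
    """
    if design.task != "preference":
        raise ValueError("simulate_preference requires a preference-task design")
    rng = np.random.default_rng(seed)
    trials = design.trials.copy()
    p = _accept_probabilities(trials, params)
    accepted = rng.random(len(trials)) < p
    trials["response"] = np.where(accepted, "accept", "reject")
    trials.insert(0, "session", "preference")
    trials.insert(0, "subject_id", 0)
    return trials
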