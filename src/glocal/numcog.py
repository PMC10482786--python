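"""Place-coded network and accumulator model of global-vs-local number comparison.

The model has three layers, each a leaky linear unit bank:

* Input fields (one per hierarchical level), 15 place-coded units:
  dX_i/dt = -X_i + gain * I_i(t), where I_i indicates the presented digit and
  gain is theta_perc for the global field (global bias when > 1) and 1 for
  the local field.
* Number-line fields: dY_j/dt = -Y_j + sum_i exp(-|i-j|) * X_i, a graded
  spillover to neighbouring magnitudes.
* Two response units (global, local): dZ_k/dt = -Z_k + sum_j w_j * Y_j + eps,
  with Gaussian noise eps ~ N(0, sigma^2) and a concave increasing weight
  vector w spanning [0.1, 1.0].  A response is made when the difference
  |Z_global - Z_local| crosses a threshold; Z starts at (0, 0) each trial.

Because the X and Y layers are linear and noise-free, the drift feeding the
response units factorises exactly as c_digit * g(t), with c_digit the
weight-kernel inner product for the presented digit and g(t) a universal
unit-input response; simulation therefore integrates only the (scalar)
response difference.  This is an algebraic identity of the Euler scheme, not
an approximation, and is verified against the literal layer-by-layer update.

Euler-Maruyama discretisation with dt = 0.01 model-time units and a cap of
t_max = 30 units; RT in seconds is t_nd + time_scale * crossing time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize

from .design import DISTANCE_BINS, CompoundStimulus, SessionDesign, distance_bin_label

__all__ = [
    "N_UNITS",
    "NumCogParams",
    "NetworkState",
    "SimTrialOutcome",
    "NumCogFit",
    "make_weights",
    "kernel",
    "kernel_matrix",
    "step_network",
    "initial_state",
    "simulate_trial",
    "simulate_numcog_dataset",
    "rt_quantile_stats",
    "fit_numcog",
]

N_UNITS = 15

RT_QUANTILE_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)


def make_weights(n: int = N_UNITS) -> np.ndarray:
    """Concave increasing response-layer weights spanning [0.1, 1.0].

    w_j = 1.1 - 10^(-(j-1)/(n-1)) for j = 1..n, so w_1 = 0.1 and w_n = 1.0
    exactly, with strictly decreasing increments (concavity).
    """
    if n < 2:
        raise ValueError("need at least 2 units")
    j = np.arange(1, n + 1)
    return 1.1 - 10.0 ** (-(j - 1) / (n - 1))


def kernel(i: int, j: int) -> float:
    """Number-line spillover kernel exp(-|i-j|) between units i and j (1-based)."""
    if not (1 <= i <= N_UNITS and 1 <= j <= N_UNITS):
        raise ValueError(f"unit indices must lie in 1..{N_UNITS}")
    return float(np.exp(-abs(i - j)))


def kernel_matrix(n: int = N_UNITS) -> np.ndarray:
    """K[j, i] = exp(-|i-j|) mapping input-field to number-line activation."""
    idx = np.arange(n)
    return np.exp(-np.abs(idx[:, None] - idx[None, :]))


@dataclass(frozen=True)
class NumCogParams:
    """Accumulator-model parameters.

    theta_perc: input gain on the global field; > 1 global bias, 1 no bias.
    threshold: decision boundary on |Z_global - Z_local|.
    t_nd: non-decision time in seconds (encoding + motor).
    time_scale: seconds per model-time unit.
    sigma: SD of the response-layer Gaussian noise (fixed to 1 when fitting,
        to break the noise/threshold scale trade-off).
    dt, t_max: Euler step and trial cap, in model-time units.
    """

    theta_perc: float
    threshold: float
    t_nd: float = 0.3
    time_scale: float = 0.05
    sigma: float = 1.0
    dt: float = 0.01
    t_max: float = 30.0

    def __post_init__(self) -> None:
        if min(self.theta_perc, self.threshold, self.time_scale, self.dt, self.t_max) <= 0:
            raise ValueError("theta_perc, threshold, time_scale, dt, t_max must be > 0")
        if self.sigma < 0 or self.t_nd < 0:
            raise ValueError("sigma and t_nd must be nonnegative")
        if self.dt > 0.1:
            raise ValueError("dt must be <= 0.1 for a stable Euler scheme")
        if self.t_max < 100 * self.dt:
            raise ValueError("t_max must cover at least 100 steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))


@dataclass
class NetworkState:
    """Full network state; X/Y are per-field 15-vectors, Z the response pair."""

    X_global: np.ndarray = field(default_factory=lambda: np.zeros(N_UNITS))
    X_local: np.ndarray = field(default_factory=lambda: np.zeros(N_UNITS))
    Y_global: np.ndarray = field(default_factory=lambda: np.zeros(N_UNITS))
    Y_local: np.ndarray = field(default_factory=lambda: np.zeros(N_UNITS))
    Z: np.ndarray = field(default_factory=lambda: np.zeros(2))
    t: float = 0.0


def initial_state() -> NetworkState:
    """Rest state: all activations zero (Z reset applies at every trial start)."""
    return NetworkState()


def step_network(
    state: NetworkState,
    stimulus: CompoundStimulus,
    params: NumCogParams,
    noise_draws: np.ndarray | tuple[float, float] = (0.0, 0.0),
) -> NetworkState:
    """One Euler(-Maruyama) step of all layers; returns the new state.

    ``noise_draws`` are two standard-normal deviates for the (global, local)
    response units; they are scaled by sigma * sqrt(dt) internally.
    """
    dt = params.dt
    K = kernel_matrix()
    w = make_weights()
    I_g = np.zeros(N_UNITS)
    I_g[stimulus.global_digit - 1] = 1.0
    I_l = np.zeros(N_UNITS)
    I_l[stimulus.local_digit - 1] = 1.0
    eps = np.asarray(noise_draws, float) * params.sigma * np.sqrt(dt)
    Xg = state.X_global + dt * (-state.X_global + params.theta_perc * I_g)
    Xl = state.X_local + dt * (-state.X_local + I_l)
    Yg = state.Y_global + dt * (-state.Y_global + K @ state.X_global)
    Yl = state.Y_local + dt * (-state.Y_local + K @ state.X_local)
    drift = np.array([w @ state.Y_global, w @ state.Y_local])
    Z = state.Z + dt * (-state.Z + drift) + eps
    return NetworkState(Xg, Xl, Yg, Yl, Z, state.t + dt)


def digit_drive(digit: int) -> float:
    """Asymptotic response-layer drive of one digit: sum_j w_j exp(-|digit-j|)."""
    w = make_weights()
    j = np.arange(1, N_UNITS + 1)
    return float(np.sum(w * np.exp(-np.abs(j - digit))))


def unit_response_series(params: NumCogParams) -> np.ndarray:
    """Euler series g[t] of the Y-layer response to a unit step input.

    g solves g' = -g + x with x' = -x + 1 from rest, matching the literal
    layer update order, so the drive to Z at step t is c_digit * g[t].
    """
    n = params.n_steps
    g = np.empty(n)
    x = 0.0
    gv = 0.0
    dt = params.dt
    for t in range(n):
        g[t] = gv  # Z update at step t reads Y from before the step
        gv = gv + dt * (-gv + x)
        x = x + dt * (1.0 - x)
    return g


@dataclass(frozen=True)
class SimTrialOutcome:
    response: Literal["global", "local"]
    rt_s: float
    timed_out: bool


@njit(cache=True)
def _fp_batch_numba(
    amps: np.ndarray, g: np.ndarray, thr: float, noise_sd: float, dt: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First passage of D' = -D + amp*g(t) plus noise over [0, t_max].

    Returns (crossing step counts, sides +1 global / -1 local, timeout flags).
    """
    np.random.seed(seed)
    n = amps.shape[0]
    n_steps = g.shape[0]
    steps = np.empty(n, np.int64)
    side = np.empty(n, np.int64)
    timeout = np.zeros(n, np.bool_)
    for k in range(n):
        D = 0.0
        a = amps[k]
        hit = False
        for t in range(n_steps):
            D = D + dt * (-D + a * g[t]) + noise_sd * np.random.normal()
            if D >= thr or D <= -thr:
                steps[k] = t + 1
                side[k] = 1 if D > 0.0 else -1
                hit = True
                break
        if not hit:
            steps[k] = n_steps
            side[k] = 1 if D >= 0.0 else -1
            timeout[k] = True
    return steps, side, timeout


@njit(cache=True)
def _fp_batch_pool(
    amps: np.ndarray,
    g: np.ndarray,
    thr: float,
    noise_sd: float,
    dt: float,
    pool: np.ndarray,
    offsets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First passage reading pre-drawn standard normals from a shared pool.

    Path k reads pool[(offsets[k] + t) & (len(pool) - 1)]; with a fixed pool
    this yields a deterministic objective (common random numbers across
    optimizer evaluations).  ``len(pool)`` must be a power of two.
    """
    mask = pool.shape[0] - 1
    n = amps.shape[0]
    n_steps = g.shape[0]
    steps = np.empty(n, np.int64)
    side = np.empty(n, np.int64)
    timeout = np.zeros(n, np.bool_)
    for k in range(n):
        D = 0.0
        a = amps[k]
        off = offsets[k]
        hit = False
        for t in range(n_steps):
            D = D + dt * (-D + a * g[t]) + noise_sd * pool[(off + t) & mask]
            if D >= thr or D <= -thr:
                steps[k] = t + 1
                side[k] = 1 if D > 0.0 else -1
                hit = True
                break
        if not hit:
            steps[k] = n_steps
            side[k] = 1 if D >= 0.0 else -1
            timeout[k] = True
    return steps, side, timeout


def _fp_batch_numpy(
    amps: np.ndarray,
    g: np.ndarray,
    thr: float,
    noise_sd: float,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised reference implementation of the first-passage simulation."""
    n = len(amps)
    n_steps = len(g)
    D = np.zeros(n)
    steps = np.full(n, n_steps, np.int64)
    side = np.zeros(n, np.int64)
    active = np.arange(n)
    for t in range(n_steps):
        noise = rng.standard_normal(len(active)) * noise_sd
        D[active] += dt * (-D[active] + amps[active] * g[t]) + noise
        crossed = np.abs(D[active]) >= thr
        if crossed.any():
            idx = active[crossed]
            steps[idx] = t + 1
            side[idx] = np.where(D[idx] > 0, 1, -1)
            active = active[~crossed]
            if len(active) == 0:
                break
    timeout = side == 0
    side = np.where(timeout, np.where(D >= 0, 1, -1), side)
    return steps, side, timeout


def _fp_single_with_noise(
    amp: float, g: np.ndarray, thr: float, dt: float, noise_increments: np.ndarray
) -> tuple[int, int, bool]:
    """Deterministic first passage given explicit per-step noise increments."""
    D = 0.0
    for t in range(len(g)):
        D = D + dt * (-D + amp * g[t]) + noise_increments[t]
        if abs(D) >= thr:
            return t + 1, (1 if D > 0 else -1), False
    return len(g), (1 if D >= 0 else -1), True


def drift_amplitude(stimulus: CompoundStimulus, theta_perc: float) -> float:
    """Net drive toward the global response: theta_perc*c_global - c_local."""
    return theta_perc * digit_drive(stimulus.global_digit) - digit_drive(
        stimulus.local_digit
    )


def simulate_trial(
    stimulus: CompoundStimulus, params: NumCogParams, seed: int
) -> SimTrialOutcome:
    """Simulate one comparison trial; rejects equal-digit stimuli."""
    if stimulus.congruent is None:
        raise ValueError("equal-digit stimulus has no correct comparison response")
    g = unit_response_series(params)
    amp = drift_amplitude(stimulus, params.theta_perc)
    rng = np.random.default_rng(seed)
    noise_sd = params.sigma * np.sqrt(2.0 * params.dt)
    steps, side, timeout = _fp_batch_numpy(
        np.array([amp]), g, params.threshold, noise_sd, params.dt, rng
    )
    rt = params.t_nd + params.time_scale * steps[0] * params.dt
    return SimTrialOutcome(
        response="global" if side[0] > 0 else "local",
        rt_s=float(rt),
        timed_out=bool(timeout[0]),
    )


def simulate_numcog_dataset(
    design: SessionDesign,
    params: NumCogParams,
    seed: int,
    engine: Literal["numba", "numpy"] = "numba",
) -> pd.DataFrame:
    """Simulate a full numeric session; one accumulator run per design trial."""
    if design.task != "numeric":
        raise ValueError("simulate_numcog_dataset requires a numeric-task design")
    trials = design.trials.copy()
    drives = {d: digit_drive(d) for d in range(2, 10)}
    amps = np.array(
        [
            params.theta_perc * drives[g] - drives[l]
            for g, l in zip(trials["global_digit"], trials["local_digit"])
        ]
    )
    g = unit_response_series(params)
    noise_sd = params.sigma * np.sqrt(2.0 * params.dt)
    if engine == "numba":
        steps, side, timeout = _fp_batch_numba(
            amps, g, params.threshold, noise_sd, params.dt, int(seed) % 2**31
        )
    else:
        steps, side, timeout = _fp_batch_numpy(
            amps, g, params.threshold, noise_sd, params.dt,
            np.random.default_rng(seed),
        )
    trials["response"] = np.where(side > 0, "global", "local")
    larger_is_global = trials["global_digit"].to_numpy() > trials["local_digit"].to_numpy()
    trials["correct"] = (
        (trials["response"].to_numpy() == "global") == larger_is_global
    ).astype(int)
    trials["rt_s"] = params.t_nd + params.time_scale * steps * params.dt
    trials["timed_out"] = timeout
    trials.insert(0, "session", "numeric")
    trials.insert(0, "subject_id", 0)
    return trials


def rt_quantile_stats(
    trials: pd.DataFrame,
    bins: tuple[tuple[int, int], ...] = DISTANCE_BINS,
    probs: tuple[float, ...] = RT_QUANTILE_PROBS,
    min_error_n: int = 5,
) -> pd.DataFrame:
    """Per-cell RT quantile summary over congruency x distance-bin cells.

    For each cell: trial/correct/error/timeout counts, correct-RT quantiles
    (type-7 interpolation over non-timeout correct trials) and error-RT
    quantiles when at least ``min_error_n`` non-timeout errors exist
    (otherwise errors stay a single count bin, quantiles NaN).  Raises if any
    requested cell is empty.
    """
    t = trials.copy()
    t["dist_bin"] = [distance_bin_label(d, bins) for d in t["distance"]]
    if "timed_out" not in t:
        t["timed_out"] = False
    rows = []
    empty = []
    bin_labels = [f"{lo}-{hi}" for lo, hi in bins]
    for cong in (True, False):
        for label in bin_labels:
            cell = t[(t["congruent"] == cong) & (t["dist_bin"] == label)]
            if len(cell) == 0:
                empty.append((cong, label))
                continue
            ok = cell[~cell["timed_out"]]
            corr = ok[ok["correct"] == 1]["rt_s"].to_numpy(float)
            err = ok[ok["correct"] == 0]["rt_s"].to_numpy(float)
            row = {
                "congruent": cong,
                "dist_bin": label,
                "n": len(cell),
                "n_correct": int((cell["correct"] == 1).sum()),
                "n_error": int((cell["correct"] == 0).sum()),
                "n_timeout": int(cell["timed_out"].sum()),
            }
            for p in probs:
                row[f"correct_q{int(p * 100)}"] = (
                    float(np.quantile(corr, p)) if len(corr) > 0 else np.nan
                )
            for p in probs:
                row[f"error_q{int(p * 100)}"] = (
                    float(np.quantile(err, p)) if len(err) >= min_error_n else np.nan
                )
            rows.append(row)
    if empty:
        raise ValueError(f"empty design cells: {empty}")
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Fitting: quantile chi-square with profiled time mapping
# --------------------------------------------------------------------------

_MASS_SPLIT = np.array([0.1, 0.2, 0.2, 0.2, 0.2, 0.1])
_P_FLOOR = 1e-3
_MIN_QUANTILE_N = 10


@dataclass
class NumCogFit:
    params: NumCogParams
    chi2: float
    converged: bool
    flags: list[str]
    n_trials: int
    n_starts: int


class _Cell:
    """Observed summary of one congruency x distance cell, as plain arrays."""

    def __init__(self, sub: pd.DataFrame, probs: tuple[float, ...]) -> None:
        self.n = len(sub)
        ok = sub[~sub["timed_out"]] if "timed_out" in sub else sub
        corr = np.sort(ok[ok["correct"] == 1]["rt_s"].to_numpy(float))
        err = np.sort(ok[ok["correct"] == 0]["rt_s"].to_numpy(float))
        self.n_corr, self.n_err = len(corr), len(err)
        self.n_timeout = self.n - self.n_corr - self.n_err
        self.corr_q = np.quantile(corr, probs) if self.n_corr >= _MIN_QUANTILE_N else None
        self.err_q = np.quantile(err, probs) if self.n_err >= _MIN_QUANTILE_N else None
        self.obs_mass = self._masses(
            self.n_corr / self.n, self.n_err / self.n, self.n_timeout / self.n,
            use_corr_q=self.corr_q is not None, use_err_q=self.err_q is not None,
        )

    @staticmethod
    def _masses(p_corr, p_err, p_to, use_corr_q, use_err_q):
        parts = [p_corr * _MASS_SPLIT if use_corr_q else np.array([p_corr])]
        parts.append(p_err * _MASS_SPLIT if use_err_q else np.array([p_err]))
        parts.append(np.array([p_to]))
        return np.concatenate(parts)

    def predicted_mass(self, rt_corr: np.ndarray, rt_err: np.ndarray, n_sim: int,
                       n_sim_timeout: int) -> np.ndarray:
        def binned(rts, q):
            if len(rts) == 0:
                return np.zeros(len(q) + 1)
            counts = np.diff(np.concatenate(
                ([0], np.searchsorted(np.sort(rts), q, side="right"), [len(rts)])
            ))
            return counts / n_sim
        parts = []
        if self.corr_q is not None:
            parts.append(binned(rt_corr, self.corr_q))
        else:
            parts.append(np.array([len(rt_corr) / n_sim]))
        if self.err_q is not None:
            parts.append(binned(rt_err, self.err_q))
        else:
            parts.append(np.array([len(rt_err) / n_sim]))
        parts.append(np.array([n_sim_timeout / n_sim]))
        return np.concatenate(parts)


def _calibrate_time_map(
    pairs: list[tuple[np.ndarray, np.ndarray, float]], min_rt: float
) -> tuple[float, float]:
    """WLS fit of rt = t_nd + time_scale * t_model over pooled cell quantiles."""
    xs = np.concatenate([p[0] for p in pairs])
    ys = np.concatenate([p[1] for p in pairs])
    ws = np.concatenate([np.full(len(p[0]), p[2]) for p in pairs])
    W = ws.sum()
    mx, my = (ws * xs).sum() / W, (ws * ys).sum() / W
    vx = (ws * (xs - mx) ** 2).sum() / W
    if vx <= 0:
        return max(min_rt / 2, 0.0), 1e-3
    slope = (ws * (xs - mx) * (ys - my)).sum() / W / vx
    slope = max(slope, 1e-3)
    t_nd = my - slope * mx
    if t_nd < 0 or t_nd > min_rt:
        t_nd = float(np.clip(t_nd, 0.0, min_rt))
        denom = (ws * xs**2).sum()
        if denom > 0:
            slope = max(float((ws * xs * (ys - t_nd)).sum() / denom), 1e-3)
    return float(t_nd), float(slope)


def fit_numcog(
    trials: pd.DataFrame,
    sims_per_cell: int = 500,
    n_starts: int = 3,
    seed: int = 7,
    maxiter: int = 80,
    bins: tuple[tuple[int, int], ...] = DISTANCE_BINS,
    base: NumCogParams | None = None,
    engine: Literal["numba", "numpy"] = "numba",
) -> NumCogFit:
    """Fit the accumulator model to one subject's comparison data.

    Minimises a Ratcliff-style quantile chi-square between observed and
    simulated RT-quantile/error/timeout masses over congruency x distance-bin
    cells.  theta_perc and threshold are searched by multistart Nelder-Mead on
    the log scale; for every candidate, t_nd and time_scale (which enter the
    simulated RTs linearly) are profiled out by weighted least squares on the
    correct-RT quantiles.  sigma, dt and t_max are fixed (``base`` supplies
    them; sigma defaults to 1 for identifiability).  Common random numbers
    (one seed per fit) make the objective deterministic.

    ``sims_per_cell`` is the number of simulated trials per unique stimulus
    per objective evaluation.
    """
    base = base or NumCogParams(theta_perc=1.0, threshold=2.4)
    flags: list[str] = []
    t = trials.copy()
    if "timed_out" not in t:
        t["timed_out"] = False
    if (t["correct"] == 1).sum() == 0:
        flags.append("all_errors")
    if t["timed_out"].mean() > 0.2:
        flags.append("timeouts_gt_20pct")

    t["dist_bin"] = [distance_bin_label(d, bins) for d in t["distance"]]
    cells: list[tuple[np.ndarray, _Cell]] = []
    stim_key = t["global_digit"].astype(str) + "_" + t["local_digit"].astype(str)
    uniq_stims = (
        t.assign(key=stim_key)
        .groupby(["key", "global_digit", "local_digit", "congruent", "dist_bin"])
        .size()
        .reset_index(name="count")
    )
    drives = {d: digit_drive(d) for d in range(2, 10)}
    for cong in (True, False):
        for lo, hi in bins:
            label = f"{lo}-{hi}"
            sub = t[(t["congruent"] == cong) & (t["dist_bin"] == label)]
            if len(sub) == 0:
                continue
            stims = uniq_stims[
                (uniq_stims["congruent"] == cong) & (uniq_stims["dist_bin"] == label)
            ]
            cells.append((stims[["global_digit", "local_digit"]].to_numpy(int),
                          _Cell(sub, RT_QUANTILE_PROBS)))
    if not cells:
        raise ValueError("no usable cells in trial table")

    min_rt = float(t["rt_s"].min())
    g = unit_response_series(base)
    dt, sigma = base.dt, base.sigma
    noise_sd = sigma * np.sqrt(2.0 * dt)
    sim_seed = int(seed) % 2**31
    # one flat stimulus list; slices map simulations back to cells
    all_gl = np.concatenate([c[0] for c in cells])
    cell_sizes = [len(c[0]) * sims_per_cell for c in cells]
    offsets = np.concatenate([[0], np.cumsum(cell_sizes)])
    c_g = np.array([drives[d] for d in all_gl[:, 0]])
    c_l = np.array([drives[d] for d in all_gl[:, 1]])

    # fixed noise pool -> deterministic objective (common random numbers)
    n_paths = int(offsets[-1])
    pool_size = 1 << 21
    while pool_size < 2 * n_paths * 1000 and pool_size < (1 << 25):
        pool_size <<= 1
    pool_rng = np.random.default_rng(sim_seed)
    pool = pool_rng.standard_normal(pool_size)
    path_offsets = pool_rng.integers(0, pool_size, size=n_paths, dtype=np.int64)

    def objective(x: np.ndarray) -> float:
        theta, thr = np.exp(x)
        amps = np.repeat(theta * c_g - c_l, sims_per_cell)
        if engine == "numba":
            steps, side, timeout = _fp_batch_pool(
                amps, g, thr, noise_sd, dt, pool, path_offsets
            )
        else:
            steps, side, timeout = _fp_batch_numpy(
                amps, g, thr, noise_sd, dt, np.random.default_rng(sim_seed)
            )
        t_model = steps * dt
        pairs = []
        per_cell = []
        for ci, (gl, cell) in enumerate(cells):
            sl = slice(offsets[ci], offsets[ci + 1])
            glv = np.repeat(gl[:, 0] > gl[:, 1], sims_per_cell)
            corr_mask = ((side[sl] > 0) == glv) & ~timeout[sl]
            err_mask = ((side[sl] > 0) != glv) & ~timeout[sl]
            tc = t_model[sl][corr_mask]
            te = t_model[sl][err_mask]
            per_cell.append((cell, tc, te, int(timeout[sl].sum()), cell_sizes[ci]))
            if cell.corr_q is not None and len(tc) >= _MIN_QUANTILE_N:
                pairs.append((np.quantile(tc, RT_QUANTILE_PROBS), cell.corr_q,
                              float(cell.n_corr)))
        if not pairs:
            return 1e8
        t_nd, ts = _calibrate_time_map(pairs, min_rt)
        chi2 = 0.0
        for cell, tc, te, n_to, n_sim in per_cell:
            pred = cell.predicted_mass(t_nd + ts * tc, t_nd + ts * te, n_sim, n_to)
            chi2 += cell.n * float(
                np.sum((cell.obs_mass - pred) ** 2 / np.maximum(pred, _P_FLOOR))
            )
        objective.last_map = (t_nd, ts)
        return chi2

    objective.last_map = (base.t_nd, base.time_scale)  # fallback for degenerate data
    rng = np.random.default_rng(seed)
    starts = [np.array([0.0, np.log(base.threshold)])]
    while len(starts) < n_starts:
        starts.append(
            np.array(
                [
                    rng.uniform(np.log(0.7), np.log(1.4)),
                    rng.uniform(np.log(0.8 * base.threshold), np.log(1.4 * base.threshold)),
                ]
            )
        )
    best = None
    any_ok = False
    for x0 in starts[:n_starts]:
        # explicit simplex: NM's default barely perturbs coordinates at 0
        simplex = np.array([x0, x0 + [0.15, 0.0], x0 + [0.0, 0.15]])
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-2,
                     "initial_simplex": simplex},
        )
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    objective(best.x)  # refresh the profiled time map at the optimum
    t_nd, ts = objective.last_map
    theta, thr = np.exp(best.x)
    params = replace(base, theta_perc=float(theta), threshold=float(thr),
                     t_nd=t_nd, time_scale=ts)
    return NumCogFit(
        params=params,
        chi2=float(best.fun),
        converged=any_ok and not flags,
        flags=flags,
        n_trials=len(t),
        n_starts=n_starts,
    )
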