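"""Experimental designs for the two sessions.

Both sessions use compound (Navon-style) number figures: a large digit built
out of small digits.  Session 1 is a numerical comparison task (which level
holds the larger digit?); Session 2 is an accept/reject task over 50/50 mixed
gambles in which one level carries the potential gain and the other the
potential loss.

This module enumerates the stimulus sets, derives per-stimulus attributes
(congruency, numerical distance, expected value, framing condition) and builds
balanced, seeded trial orders for both sessions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "CompoundStimulus",
    "Lottery",
    "SessionDesign",
    "DIGIT_MIN",
    "DIGIT_MAX",
    "DISTANCE_BINS",
    "NUMERIC_TRIAL_COLUMNS",
    "PREFERENCE_TRIAL_COLUMNS",
    "enumerate_numeric_stimuli",
    "enumerate_lotteries",
    "expected_value",
    "build_session",
]

DIGIT_MIN = 2
DIGIT_MAX = 9

#: Three-level numerical-distance factor used for binned summaries; chosen to
#: keep stimulus counts per bin roughly balanced (26/18/12 of the 56 stimuli).
DISTANCE_BINS: tuple[tuple[int, int], ...] = ((1, 2), (3, 4), (5, 7))

NUMERIC_TRIAL_COLUMNS = [
    "subject_id", "session", "block", "trial_index",
    "global_digit", "local_digit", "congruent", "distance",
    "response", "correct", "rt_s",
]
PREFERENCE_TRIAL_COLUMNS = [
    "subject_id", "session", "block", "trial_index",
    "condition", "gain", "loss", "ev", "response",
]


class Condition(str, enum.Enum):
    """Framing condition of the preference task.

    GGLL: the global digit is the potential gain, the local digit the loss.
    GLLG: the global digit is the potential loss, the local digit the gain.
    """

    GGLL = "GGLL"
    GLLG = "GLLG"


@dataclass(frozen=True)
class CompoundStimulus:
    """One compound number figure: a global digit made of local digits.

    ``congruent`` is True when the global digit is numerically larger than the
    local one, False when smaller, and None for equal digits (congruency is
    undefined because neither level is larger).
    """

    global_digit: int
    local_digit: int

    def __post_init__(self) -> None:
        for d in (self.global_digit, self.local_digit):
            if not (DIGIT_MIN <= d <= DIGIT_MAX):
                raise ValueError(f"digit {d} outside [{DIGIT_MIN}, {DIGIT_MAX}]")

    @property
    def distance(self) -> int:
        return abs(self.global_digit - self.local_digit)

    @property
    def congruent(self) -> bool | None:
        if self.global_digit == self.local_digit:
            return None
        return self.global_digit > self.local_digit


@dataclass(frozen=True)
class Lottery:
    """A 50/50 mixed gamble presented as a compound figure.

    ``gain`` and ``loss`` are stored as positive magnitudes in money units;
    ``condition`` states which hierarchical level displays the gain.
    """

    gain: float
    loss: float
    condition: Condition

    def __post_init__(self) -> None:
        if self.gain < 0 or self.loss < 0:
            raise ValueError("gain and loss must be nonnegative magnitudes")

    @property
    def ev(self) -> float:
        return expected_value(self.gain, self.loss)


def expected_value(gain: float, loss: float) -> float:
    """Expected value of a 50/50 mixed gamble, 0.5*gain - 0.5*loss.

    ``loss`` is a positive magnitude and enters negatively.
    """
    if gain < 0 or loss < 0:
        raise ValueError("gain and loss must be nonnegative magnitudes")
    return 0.5 * gain - 0.5 * loss


def enumerate_numeric_stimuli() -> list[CompoundStimulus]:
    """All 56 ordered (global, local) digit pairs in 2..9 with unequal digits.

    Canonical deterministic ordering: global ascending, then local ascending.
    """
    return [
        CompoundStimulus(g, l)
        for g in range(DIGIT_MIN, DIGIT_MAX + 1)
        for l in range(DIGIT_MIN, DIGIT_MAX + 1)
        if g != l
    ]


def enumerate_lotteries(condition: Condition = Condition.GGLL) -> list[Lottery]:
    """All 64 (gain, loss) pairs in 2..9 (equal pairs included), one condition.

    The preference session crosses this set with both framing conditions.
    """
    condition = Condition(condition)
    return [
        Lottery(gain=g, loss=l, condition=condition)
        for g in range(DIGIT_MIN, DIGIT_MAX + 1)
        for l in range(DIGIT_MIN, DIGIT_MAX + 1)
    ]


@dataclass
class SessionDesign:
    """An ordered trial list for one subject-session.

    ``trials`` holds one row per trial with block index and within-block
    position plus the stimulus/lottery attributes; responses are filled in by
    the simulators (or by real data).
    """

    task: Literal["numeric", "preference"]
    trials: pd.DataFrame = field(repr=False)
    n_blocks: int
    seed: int


def _shuffled_blocks(rng: np.random.Generator, block_items: list[pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for b, items in enumerate(block_items):
        order = rng.permutation(len(items))
        blk = items.iloc[order].reset_index(drop=True)
        blk.insert(0, "block", b)
        rows.append(blk)
    out = pd.concat(rows, ignore_index=True)
    out.insert(1, "trial_index", np.arange(len(out)))
    return out


def build_session(
    task: Literal["numeric", "preference"],
    seed: int,
    condition_order: Literal["GGLL_first", "GLLG_first"] = "GGLL_first",
) -> SessionDesign:
    """Build one balanced, seeded session.

    Numeric: 448 trials, 4 blocks of 112; each of the 56 stimuli twice per
    block (8 presentations in total).  Preference: 512 trials, 4 blocks of
    128, blocks alternating between framing conditions starting from
    ``condition_order``; each of the 64 lotteries twice per block (4 per
    condition).  Within-block order is a seeded random permutation.
    """
    rng = np.random.default_rng(seed)
    if task == "numeric":
        stims = enumerate_numeric_stimuli()
        base = pd.DataFrame(
            {
                "global_digit": [s.global_digit for s in stims],
                "local_digit": [s.local_digit for s in stims],
                "congruent": [s.congruent for s in stims],
                "distance": [s.distance for s in stims],
            }
        )
        blocks = [pd.concat([base, base], ignore_index=True) for _ in range(4)]
        trials = _shuffled_blocks(rng, blocks)
    elif task == "preference":
        if condition_order == "GGLL_first":
            seq = [Condition.GGLL, Condition.GLLG, Condition.GGLL, Condition.GLLG]
        elif condition_order == "GLLG_first":
            seq = [Condition.GLLG, Condition.GGLL, Condition.GLLG, Condition.GGLL]
        else:
            raise ValueError(f"unknown condition_order {condition_order!r}")
        blocks = []
        for cond in seq:
            lots = enumerate_lotteries(cond)
            base = pd.DataFrame(
                {
                    "condition": [lot.condition.value for lot in lots],
                    "gain": [lot.gain for lot in lots],
                    "loss": [lot.loss for lot in lots],
                    "ev": [lot.ev for lot in lots],
                }
            )
            blocks.append(pd.concat([base, base], ignore_index=True))
        trials = _shuffled_blocks(rng, blocks)
    else:
        raise ValueError(f"unknown task {task!r}")
    return SessionDesign(task=task, trials=trials, n_blocks=4, seed=seed)


def distance_bin_label(distance: int, bins: tuple[tuple[int, int], ...] = DISTANCE_BINS) -> str:
    """Label for the distance bin containing ``distance`` (e.g. ``"1-2"``)."""
    for lo, hi in bins:
        if lo <= distance <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"distance {distance} not covered by bins {bins}")
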