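"""Trial-sequence design for the four response-inhibition conditions.

The battery comprises a choice reaction time task (CRT), a flanker task,
a stop signal task (SST) and a combined stop signal flanker task (SSFT).
Left/right stimuli occur with equal frequency, flanker congruency levels
(congruent / incongruent / neutral) occur with equal frequency, and stop
signals occur on 30% of SST/SSFT trials, balanced over every
hand x congruency cell.  The stop signal delay (SSD) is adapted with a
one-up/one-down staircase (50 ms steps, 200 ms initial value), tracked
independently for each hand (SST) and each hand x congruency cell (SSFT),
which drives long-run stop success toward 50%.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError

__all__ = [
    "Condition",
    "Congruency",
    "Hand",
    "TrialSpec",
    "SessionDesign",
    "StaircaseState",
    "SessionPlan",
    "SESSION_PLANS",
    "sample_fixation",
    "generate_session",
    "staircase_update",
    "make_staircases",
    "slow_feedback_flag",
    "write_session_tsv",
    "read_session_tsv",
]


class Condition(str, enum.Enum):
    CRT = "CRT"
    FLANKER = "FLANKER"
    SST = "SST"
    SSFT = "SSFT"


class Congruency(str, enum.Enum):
    NONE = "NONE"
    CONGRUENT = "CONGRUENT"
    INCONGRUENT = "INCONGRUENT"
    NEUTRAL = "NEUTRAL"


class Hand(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


#: congruency levels shown in each condition
_CONGRUENCIES = {
    Condition.CRT: (Congruency.NONE,),
    Condition.FLANKER: (Congruency.CONGRUENT, Congruency.INCONGRUENT, Congruency.NEUTRAL),
    Condition.SST: (Congruency.NONE,),
    Condition.SSFT: (Congruency.CONGRUENT, Congruency.INCONGRUENT, Congruency.NEUTRAL),
}


@dataclass(frozen=True)
class SessionPlan:
    """Planned trial numbers for one condition (test trials exclude practice)."""

    n_trials: int
    n_practice: int
    n_blocks: int
    stop_fraction: float


#: published trial numbers per condition
SESSION_PLANS = {
    Condition.CRT: SessionPlan(32, 8, 1, 0.0),
    Condition.FLANKER: SessionPlan(180, 12, 2, 0.0),
    Condition.SST: SessionPlan(120, 8, 2, 0.30),
    Condition.SSFT: SessionPlan(360, 16, 4, 0.30),
}

FIXATION_LO_S = 0.6
FIXATION_HI_S = 1.1
#: rate of the exponential before truncation; only the [0.6, 1.1] s support
#: is normative, the rate is a package default.
FIXATION_RATE = 2.0

INITIAL_SSD_MS = 200.0
SSD_STEP_MS = 50.0
SLOW_FEEDBACK_MARGIN_MS = 150.0


@dataclass
class TrialSpec:
    """One planned trial."""

    condition: Condition
    congruency: Congruency
    hand: Hand
    is_stop: bool
    fixation_s: float
    trial_index: int = -1
    practice: bool = False

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.congruency = Congruency(self.congruency)
        self.hand = Hand(self.hand)
        if self.condition in (Condition.CRT, Condition.FLANKER) and self.is_stop:
            raise DesignError(f"{self.condition.value} trials cannot be stop trials")
        if self.condition in (Condition.CRT, Condition.SST) and self.congruency is not Congruency.NONE:
            raise DesignError(f"{self.condition.value} trials carry no flankers")
        if not (FIXATION_LO_S <= self.fixation_s <= FIXATION_HI_S):
            raise DesignError(f"fixation {self.fixation_s} s outside [{FIXATION_LO_S}, {FIXATION_HI_S}] s")


@dataclass
class SessionDesign:
    """A full condition's trial sequence (practice first, then test trials)."""

    condition: Condition
    trials: list[TrialSpec]
    seed: int

    @property
    def test_trials(self) -> list[TrialSpec]:
        return [t for t in self.trials if not t.practice]

    @property
    def practice_trials(self) -> list[TrialSpec]:
        return [t for t in self.trials if t.practice]

    def counts_by_cell(self, include_practice: bool = False) -> dict[tuple[Hand, Congruency, bool], int]:
        counts: dict[tuple[Hand, Congruency, bool], int] = {}
        for t in self.trials:
            if t.practice and not include_practice:
                continue
            key = (t.hand, t.congruency, t.is_stop)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": [t.trial_index for t in self.trials],
                "condition": [t.condition.value for t in self.trials],
                "congruency": [t.congruency.value for t in self.trials],
                "hand": [t.hand.value for t in self.trials],
                "is_stop": [t.is_stop for t in self.trials],
                "fixation_s": [t.fixation_s for t in self.trials],
                "practice": [t.practice for t in self.trials],
            }
        )


def sample_fixation(
    rng: np.random.Generator,
    lo: float = FIXATION_LO_S,
    hi: float = FIXATION_HI_S,
    rate: float = FIXATION_RATE,
) -> float:
    """Draw one fixation duration from an exponential truncated to [lo, hi].

    Uses the inverse CDF of the truncated exponential so the draw is exact.
    """
    if not (np.isfinite(lo) and np.isfinite(hi) and np.isfinite(rate)):
        raise ValueError("fixation bounds and rate must be finite")
    if not (0 < lo < hi) or rate <= 0:
        raise ValueError(f"invalid truncated-exponential parameters lo={lo}, hi={hi}, rate={rate}")
    u = rng.random()
    z = 1.0 - math.exp(-rate * (hi - lo))
    return lo - math.log1p(-u * z) / rate


def truncated_exponential_mean(lo: float, hi: float, rate: float) -> float:
    """Closed-form mean of an exponential of the given rate truncated to [lo, hi]."""
    if not (0 < lo < hi) or rate <= 0:
        raise ValueError("invalid truncated-exponential parameters")
    w = hi - lo
    z = 1.0 - math.exp(-rate * w)
    # E[X] = lo + 1/rate - w * exp(-rate w) / (1 - exp(-rate w))
    return lo + 1.0 / rate - w * math.exp(-rate * w) / z


def _build_cells(condition: Condition, n_trials: int, stop_fraction: float) -> list[tuple[Hand, Congruency, bool]]:
    """Exact per-cell trial assignments; raises DesignError on indivisible counts."""
    congruencies = _CONGRUENCIES[condition]
    n_cells = len(Hand) * len(congruencies)
    if n_trials % n_cells != 0:
        raise DesignError(
            f"{n_trials} trials not divisible over {n_cells} hand x congruency cells of {condition.value}"
        )
    per_cell = n_trials // n_cells
    n_stop_f = stop_fraction * per_cell
    n_stop = int(round(n_stop_f))
    if abs(n_stop_f - n_stop) > 1e-9:
        raise DesignError(
            f"stop fraction {stop_fraction} does not yield an integer stop count for cells of {per_cell} trials"
        )
    cells: list[tuple[Hand, Congruency, bool]] = []
    for hand in Hand:
        for cong in congruencies:
            cells.extend([(hand, cong, True)] * n_stop)
            cells.extend([(hand, cong, False)] * (per_cell - n_stop))
    return cells


def _practice_cells(condition: Condition, n_practice: int, stop_fraction: float) -> list[tuple[Hand, Congruency, bool]]:
    """Practice trials cycle round-robin over cells; stop count is rounded down.

    Practice counts are not balanced exactly when indivisible (they are
    excluded from every analysis, so only their flagging is normative).
    """
    congruencies = _CONGRUENCIES[condition]
    combos = [(h, c) for h in Hand for c in congruencies]
    n_stop = int(math.floor(stop_fraction * n_practice))
    cells = []
    for i in range(n_practice):
        hand, cong = combos[i % len(combos)]
        cells.append((hand, cong, i < n_stop))
    return cells


def generate_session(
    condition: Condition | str,
    seed: int,
    n_trials: Optional[int] = None,
    n_practice: Optional[int] = None,
    fixation_rate: float = FIXATION_RATE,
) -> SessionDesign:
    """Generate a randomised session for one condition.

    Defaults reproduce the published trial numbers; ``n_trials`` may be
    overridden (e.g. for long simulated runs) provided the hand x congruency
    x stop cell structure stays integral.  Practice trials come first and are
    flagged; the test-trial order is a seeded permutation.
    """
    condition = Condition(condition)
    plan = SESSION_PLANS[condition]
    n_trials = plan.n_trials if n_trials is None else int(n_trials)
    n_practice = plan.n_practice if n_practice is None else int(n_practice)
    if n_trials <= 0:
        raise DesignError("n_trials must be positive")

    rng = np.random.default_rng(seed)
    test_cells = _build_cells(condition, n_trials, plan.stop_fraction)
    order = rng.permutation(len(test_cells))
    practice = _practice_cells(condition, n_practice, plan.stop_fraction)
    p_order = rng.permutation(len(practice))

    trials: list[TrialSpec] = []
    idx = 0
    for j in p_order:
        hand, cong, is_stop = practice[j]
        trials.append(
            TrialSpec(condition, cong, hand, is_stop,
                      sample_fixation(rng, rate=fixation_rate), trial_index=idx, practice=True)
        )
        idx += 1
    for j in order:
        hand, cong, is_stop = test_cells[j]
        trials.append(
            TrialSpec(condition, cong, hand, is_stop,
                      sample_fixation(rng, rate=fixation_rate), trial_index=idx, practice=False)
        )
        idx += 1
    return SessionDesign(condition=condition, trials=trials, seed=seed)


@dataclass(frozen=True)
class StaircaseState:
    """One-up/one-down SSD staircase for a single (hand, congruency) cell."""

    key: tuple[Hand, Congruency]
    ssd_ms: float = INITIAL_SSD_MS
    step_ms: float = SSD_STEP_MS
    floor_ms: float = 0.0
    history: tuple[tuple[float, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.ssd_ms < self.floor_ms:
            raise DesignError("staircase SSD below floor")


def staircase_update(state: StaircaseState, stop_success: bool) -> StaircaseState:
    """Advance the staircase: +step after a successful stop, -step (clamped
    at the floor) after a failed stop.  Returns a new state; history records
    the SSD at which the outcome was observed."""
    if stop_success:
        new_ssd = state.ssd_ms + state.step_ms
    else:
        new_ssd = max(state.ssd_ms - state.step_ms, state.floor_ms)
    return replace(state, ssd_ms=new_ssd, history=state.history + ((state.ssd_ms, stop_success),))


def make_staircases(
    condition: Condition | str,
    initial_ssd_ms: float = INITIAL_SSD_MS,
    step_ms: float = SSD_STEP_MS,
    floor_ms: float = 0.0,
) -> dict[tuple[Hand, Congruency], StaircaseState]:
    """Independent staircases per hand (SST) or per hand x congruency (SSFT)."""
    condition = Condition(condition)
    if SESSION_PLANS[condition].stop_fraction == 0:
        return {}
    return {
        (hand, cong): StaircaseState(key=(hand, cong), ssd_ms=initial_ssd_ms,
                                     step_ms=step_ms, floor_ms=floor_ms)
        for hand in Hand
        for cong in _CONGRUENCIES[condition]
    }


def slow_feedback_flag(
    rt_ms: float, ref_mean_rt_ms: float, margin_ms: float = SLOW_FEEDBACK_MARGIN_MS
) -> bool:
    """True when a go RT is strictly more than ``margin_ms`` above the
    participant's reference mean (CRT mean for SST; congruency-matched
    flanker-task mean for SSFT), triggering "You've slowed down!" feedback."""
    if not (np.isfinite(rt_ms) and np.isfinite(ref_mean_rt_ms)):
        raise ValueError("RT and reference mean must be finite")
    return rt_ms > ref_mean_rt_ms + margin_ms


def write_session_tsv(design: SessionDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_session_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
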