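"""Deterministic-contract simulator of the location-discrimination task.

The engine owns the contingency state (which well of the cued pair is
currently rewarded), the reversal criterion (9 of the last 10 consecutive
choices correct), session termination (reversal cap or duration cap,
whichever first) and the well geometry (eight wells in a row, 6 cm apart).

A session is produced by :func:`run_session` from any *agent*: an object
with ``reset() / choose(rng) / observe(side, reward)`` (see
:class:`PRLAgent`).  All stochasticity — agent choices, response
latencies, initiation rewards, blank pokes — is drawn from a single
``numpy`` generator seeded by the caller, so the same seed reproduces a
session exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np
import yaml

from .records import LEFT, RIGHT, N_WELLS, Session, SessionMeta, TrialRecord


@dataclass
class TaskConfig:
    """Protocol constants of one session type.

    Defaults are the test-session protocol: reversal after 9-of-10
    consecutive correct, at most 6 reversals within 60 min, 5 s time-out
    (preceded by a 3 s house-light cue), 10 s inter-trial interval.
    Pretraining sessions enable the 20 % initiation reward and cap at
    40 min (see :func:`pretraining_config`).
    """

    n_wells: int = N_WELLS
    well_spacing_cm: float = 6.0
    criterion_window: int = 10
    criterion_required: int = 9
    strict_window: bool = False      # require a full window of elapsed trials
    max_reversals: int = 6
    max_duration_s: float = 3600.0
    timeout_s: float = 5.0
    penalty_light_s: float = 3.0
    reward_consume_s: float = 2.0
    iti_s: float = 10.0
    initiation_hold_s: float = 0.3
    initiation_reward_prob: float = 0.0   # 0.20 with the pretraining rule
    cued_pair: tuple[int, int] = (4, 5)
    initial_rewarded_well: int = 4
    # latency generator: log-normal, median latency_median_s, log-sd sigma
    latency_median_s: float = 1.5
    latency_sigma_log: float = 0.4
    # mean number of blank pokes per trial (Poisson)
    blank_poke_rate: float = 0.1

    def __post_init__(self) -> None:
        a, b = self.cued_pair
        if not (1 <= a <= self.n_wells and 1 <= b <= self.n_wells and a != b):
            raise ValueError(f"cued_pair {self.cued_pair} must be distinct wells in 1..{self.n_wells}")
        if a > b:
            self.cued_pair = (b, a)
        if self.criterion_required > self.criterion_window:
            raise ValueError("criterion_required must not exceed criterion_window")
        if self.initial_rewarded_well not in self.cued_pair:
            raise ValueError("initial_rewarded_well must belong to cued_pair")
        if self.max_duration_s <= 0:
            raise ValueError("max_duration_s must be positive")

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        d["cued_pair"] = list(self.cued_pair)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["cued_pair"] = tuple(d["cued_pair"])
        return cls(**d)


def test_config(separation: str = "small", **overrides) -> TaskConfig:
    """Test-session config for a named separation ('small' = L4-L5, 'large' = L2-L7)."""
    from .records import TEST_PAIRS

    pair = TEST_PAIRS[separation]
    cfg = TaskConfig(cued_pair=pair, initial_rewarded_well=pair[0])
    return replace(cfg, **overrides) if overrides else cfg


def pretraining_config(**overrides) -> TaskConfig:
    """Pretraining-style config: 20 % initiation reward, 40 min cap.

    The full pretraining schedule (90 trials at >= 80 % correct over two
    sessions to advance) is a promotion rule, not an in-session mechanic;
    it is recorded here as metadata only.
    """
    cfg = TaskConfig(
        initiation_reward_prob=0.20,
        max_duration_s=2400.0,
        max_reversals=10**6,  # pretraining has no reversal cap
    )
    return replace(cfg, **overrides) if overrides else cfg


PRETRAINING_PROMOTION = {"trials": 90, "session_min": 40, "min_correct": 0.80, "consecutive_sessions": 2}


# ---------------------------------------------------------------------------
# geometry

def well_distance(i: int, j: int, config: TaskConfig | None = None) -> float:
    """Centre-to-centre distance in cm between wells ``i`` and ``j``."""
    config = config or TaskConfig()
    for w in (i, j):
        if not 1 <= w <= config.n_wells:
            raise ValueError(f"well index {w} outside 1..{config.n_wells}")
    return abs(i - j) * config.well_spacing_cm


#: Arena rectangle in cm, origin front-left: (xmin, xmax, ymin, ymax).
ARENA_BOUNDS = (0.0, 48.0, 0.0, 40.0)
#: Initiation well on the wall opposite the nose-poke panel.
CENTRAL_WELL_XY = (24.0, 30.0)


def well_position(i: int, config: TaskConfig | None = None) -> tuple[float, float]:
    """(x, y) of well ``i`` along the front wall (y = 0)."""
    config = config or TaskConfig()
    if not 1 <= i <= config.n_wells:
        raise ValueError(f"well index {i} outside 1..{config.n_wells}")
    return (3.0 + (i - 1) * config.well_spacing_cm, 0.0)


# ---------------------------------------------------------------------------
# reversal criterion

def criterion_met(correct_history: Sequence[bool], config: TaskConfig) -> bool:
    """True iff the current block's trailing window satisfies the reversal rule.

    The rule is "9 out of 10 consecutive correct": the trailing window of
    length ``min(criterion_window, n)`` must contain at least
    ``criterion_required`` correct trials, and at least
    ``criterion_required`` trials must have elapsed in the block.  Under
    this reading a perfect performer reverses after 9 trials; set
    ``strict_window=True`` to additionally require a full window of
    elapsed trials.
    """
    n = len(correct_history)
    needed = config.criterion_window if config.strict_window else config.criterion_required
    if n < needed:
        return False
    window = correct_history[-config.criterion_window:]
    return sum(bool(c) for c in window) >= config.criterion_required


@dataclass
class ContingencyState:
    """Mutable engine state while a session runs."""

    rewarded_well: int
    block_index: int = 0
    reversal_count: int = 0
    elapsed_s: float = 0.0
    correct_history_in_block: list[bool] = field(default_factory=list)


# ---------------------------------------------------------------------------
# agents

class Agent(Protocol):
    """Choice policy driven by the engine.

    ``choose`` receives the side (0 left / 1 right) that is currently
    rewarded so that contract-test agents (always-correct, always-wrong)
    can be written; learning agents must ignore it.
    """

    def reset(self) -> None: ...
    def choose(self, rng: np.random.Generator, rewarded_side: int) -> int: ...
    def observe(self, side: int, reward: int) -> None: ...


class PRLAgent:
    """Generative perseverance-RL agent.

    Values update by the Rescorla-Wagner rule ``V <- V + alpha (r - V)`` on
    the chosen side only; the choice is a logistic in
    ``beta (V_right - V_left) + delta (C_right - C_left)`` where the C's
    indicate the previous choice.  Positive ``delta`` is perseverance,
    negative is alternation; ``delta = 0`` reduces to the simple RL agent.

    ``block_overrides`` maps a contingency-block index to ``(alpha, beta,
    delta)`` used while that block runs (e.g. an acquisition-only
    treatment effect); value state is continuous across blocks.
    """

    def __init__(self, alpha: float, beta: float, delta: float = 0.0,
                 block_overrides: dict[int, tuple[float, float, float]] | None = None):
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if beta < 0:
            raise ValueError("beta must be non-negative")
        self.alpha, self.beta, self.delta = alpha, beta, delta
        self.block_overrides = dict(block_overrides or {})
        self.reset()

    def reset(self) -> None:
        self.v = [0.0, 0.0]
        self.prev: int | None = None
        self.block = 0

    def set_block(self, block_index: int) -> None:
        self.block = block_index

    def _params(self) -> tuple[float, float, float]:
        return self.block_overrides.get(self.block, (self.alpha, self.beta, self.delta))

    def p_right(self) -> float:
        _, beta, delta = self._params()
        logit = beta * (self.v[RIGHT] - self.v[LEFT])
        if self.prev == RIGHT:
            logit += delta
        elif self.prev == LEFT:
            logit -= delta
        return 1.0 / (1.0 + math.exp(-logit))

    def choose(self, rng: np.random.Generator, rewarded_side: int = -1) -> int:
        return RIGHT if rng.random() < self.p_right() else LEFT

    def observe(self, side: int, reward: int) -> None:
        alpha, _, _ = self._params()
        self.v[side] += alpha * (reward - self.v[side])
        self.prev = side


class FixedSideAgent:
    """Always pokes the same side; useful for contract tests."""

    def __init__(self, side: int):
        self.side = side

    def reset(self) -> None: ...
    def choose(self, rng: np.random.Generator, rewarded_side: int = -1) -> int:
        return self.side
    def observe(self, side: int, reward: int) -> None: ...


class AlwaysCorrectAgent:
    """Pokes the currently rewarded well on every trial (contract testing)."""

    def reset(self) -> None: ...
    def choose(self, rng: np.random.Generator, rewarded_side: int) -> int:
        return rewarded_side
    def observe(self, side: int, reward: int) -> None: ...


# ---------------------------------------------------------------------------
# session simulation

def run_session(agent: Agent, config: TaskConfig, seed: int,
                meta: SessionMeta | None = None,
                max_trials: int | None = None) -> Session:
    """Simulate one session; fully reproducible from ``seed``.

    The simulated clock advances per trial by initiation hold, response
    latency (log-normal), reward consumption or house-light + time-out,
    and the inter-trial interval.  The session ends when the duration cap
    is reached, or — once ``max_reversals`` contingency switches have
    occurred — when the criterion is met one further time (the final
    block completes but triggers no extra switch).  ``max_trials``
    additionally caps the trial count (used for fixed-length simulation
    experiments; no protocol session uses it).
    """
    if not callable(getattr(agent, "choose", None)):
        raise TypeError("agent must provide a choose() method")
    rng = np.random.default_rng(seed)
    agent.reset()
    pair = config.cued_pair
    state = ContingencyState(rewarded_well=config.initial_rewarded_well)
    mu = math.log(config.latency_median_s)
    trials: list[TrialRecord] = []
    n_init = n_init_rewarded = 0
    blanks_universe = [w for w in range(1, config.n_wells + 1) if w not in pair]
    ended_by = "duration"

    while state.elapsed_s < config.max_duration_s:
        if max_trials is not None and len(trials) >= max_trials:
            ended_by = "trial_cap"
            break
        # trial initiation at the central well
        t = state.elapsed_s + config.initiation_hold_s
        n_init += 1
        if config.initiation_reward_prob > 0:
            if rng.random() < config.initiation_reward_prob:
                n_init_rewarded += 1
                t += config.reward_consume_s

        latency = float(rng.lognormal(mu, config.latency_sigma_log))
        rewarded_side = pair.index(state.rewarded_well)
        side = int(agent.choose(rng, rewarded_side))
        choice_well = pair[side]
        correct = choice_well == state.rewarded_well
        rewarded = correct
        agent.observe(side, int(rewarded))

        n_blank = int(rng.poisson(config.blank_poke_rate)) if config.blank_poke_rate > 0 else 0
        blank = [int(rng.choice(blanks_universe)) for _ in range(n_blank)] if blanks_universe else []

        t_start, t_end = t, t + latency
        t = t_end + (config.reward_consume_s if rewarded
                     else config.penalty_light_s + config.timeout_s)
        t += config.iti_s

        trials.append(TrialRecord(
            trial_index=len(trials) + 1, block_index=state.block_index,
            cue_a=pair[0], cue_b=pair[1], rewarded_well=state.rewarded_well,
            choice_well=choice_well, correct=correct, rewarded=rewarded,
            latency_s=latency, t_start_s=t_start, t_end_s=t_end,
            blank_pokes=blank,
        ))
        state.correct_history_in_block.append(correct)
        state.elapsed_s = t

        if criterion_met(state.correct_history_in_block, config):
            if state.reversal_count >= config.max_reversals:
                ended_by = "reversal_cap"
                break
            state.reversal_count += 1
            state.block_index += 1
            state.rewarded_well = pair[1] if state.rewarded_well == pair[0] else pair[0]
            state.correct_history_in_block = []
            if hasattr(agent, "set_block"):
                agent.set_block(state.block_index)

    return Session(trials=trials, meta=meta, info={
        "seed": seed,
        "reversal_count": state.reversal_count,
        "elapsed_s": state.elapsed_s,
        "ended_by": ended_by,
        "n_initiations": n_init,
        "n_initiation_rewards": n_init_rewarded,
    })
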