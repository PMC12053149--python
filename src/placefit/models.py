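"""Rescorla-Wagner (RL) and Perseverance-RL (PRL) choice models.

Both models describe binary left/right choices in the two-alternative
location task.  The learned value of the chosen side is updated by the
Rescorla-Wagner prediction-error rule

    V_c  <-  V_c + alpha * (r - V_c),        r in {0, 1},

with the unchosen side untouched, and the probability of a rightward
choice on trial t is a logistic in the value difference plus, for the PRL
model, a choice-repetition term:

    P(right) = sigma( beta * (V_right - V_left)
                      + delta * (C_right_prev - C_left_prev) ),

where sigma is the standard logistic, C_side_prev indicates the previous
trial's choice, ``beta >= 0`` is the reward sensitivity (how strongly the
binary choice follows the graded values) and ``delta`` is the
perseverance weight: positive values favour repeating the previous side,
negative values favour alternating.  The RL model is the special case
``delta = 0``.

Values start at 0 and the previous-choice indicator at "none" at the
start of each session, so the first trial is at chance (P = 0.5); state
is never carried across sessions, and a contingency reversal changes the
task, not the model state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import LEFT, RIGHT, TrialRecord

PROB_EPS = 1e-9

MODELS = ("rl", "prl")


@dataclass(frozen=True)
class ParamVector:
    """Parameters of one model: (alpha, beta) for RL, (alpha, beta, delta) for PRL."""

    model: str
    alpha: float
    beta: float
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be non-negative")
        if (self.delta is None) != (self.model == "rl"):
            raise ValueError("delta must be present iff model is 'prl'")

    @property
    def k(self) -> int:
        """Number of free parameters (2 for RL, 3 for PRL)."""
        return 2 if self.model == "rl" else 3

    @property
    def delta_or_zero(self) -> float:
        return 0.0 if self.delta is None else self.delta


@dataclass
class ValueState:
    """Learned side values plus the previous-choice indicator."""

    v_left: float = 0.0
    v_right: float = 0.0
    prev_choice: int | None = None     # LEFT / RIGHT / None before trial 1


def value_update(state: ValueState, choice: int, reward: int, alpha: float) -> ValueState:
    """One Rescorla-Wagner step on the chosen side; returns a new state."""
    if choice not in (LEFT, RIGHT):
        raise ValueError("choice must be LEFT (0) or RIGHT (1)")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    v = [state.v_left, state.v_right]
    v[choice] += alpha * (reward - v[choice])
    return ValueState(v_left=v[0], v_right=v[1], prev_choice=choice)


def choice_probability(state: ValueState, params: ParamVector) -> float:
    """Probability of choosing the right side given the current state."""
    logit = params.beta * (state.v_right - state.v_left)
    delta = params.delta_or_zero
    if state.prev_choice == RIGHT:
        logit += delta
    elif state.prev_choice == LEFT:
        logit -= delta
    return 1.0 / (1.0 + math.exp(-logit))


def choice_probability_literal(state: ValueState, params: ParamVector) -> float:
    """Debug evaluator of the textbook-shorthand form ``0.5 + sigma(logit)``.

    That expression exceeds 1 for positive logits and is not a valid
    probability; it is provided, clipped to [0, 1], only so the plain
    logistic used by :func:`choice_probability` can be compared against
    the shorthand.  Never used in fitting.
    """
    p = 0.5 + choice_probability(state, params)
    return min(1.0, max(0.0, p))


def trials_to_arrays(trials: Iterable[TrialRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Extract (choice side, reward) arrays; off-pair choices are dropped.

    The side coding (0 = lower well index = left) is the same convention
    the generative agent uses, so likelihoods are invariant under any
    consistent well-to-side relabelling.
    """
    sides, rewards = [], []
    for tr in trials:
        s = tr.choice_side
        if s is None:
            continue
        sides.append(s)
        rewards.append(int(tr.rewarded))
    return np.asarray(sides, dtype=np.int64), np.asarray(rewards, dtype=np.int64)


def session_log_likelihood(
    trials: Sequence[TrialRecord] | tuple[np.ndarray, np.ndarray],
    params: ParamVector,
) -> tuple[float, np.ndarray]:
    """Log-likelihood of a session's choices plus per-trial P(right).

    State is reset (values 0, no previous choice) at the start, advanced
    trial by trial with the *observed* choice and reward.  Probabilities
    are clipped to ``[eps, 1 - eps]`` with ``eps = 1e-9`` before taking
    logs.  An empty trial list is degenerate, not an error: log-likelihood
    0 with an empty prediction series.
    """
    if isinstance(trials, tuple):
        choices, rewards = trials
    else:
        choices, rewards = trials_to_arrays(trials)
    state = ValueState()
    logl = 0.0
    probs = np.empty(len(choices))
    for t, (c, r) in enumerate(zip(choices, rewards)):
        p = choice_probability(state, params)
        p = min(1.0 - PROB_EPS, max(PROB_EPS, p))
        probs[t] = p
        logl += math.log(p if c == RIGHT else 1.0 - p)
        state = value_update(state, int(c), int(r), params.alpha)
    return logl, probs
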