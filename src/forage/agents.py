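"""Decision policies and latency models acting as synthetic mice.

The study's animals are not generatively modeled by any committed theory;
these agents are explicitly synthetic stand-ins spanning the strategy space
the behavioral metrics are designed to detect: win-stay/lose-switch (with
optional lapse noise), side-biased random choice, a value-learning softmax
agent that exhibits matching under baited rewards, plus two deterministic
reference agents (strict alternation, ideal high-side tracking) used to pin
down the task rules in tests.

Latencies: self-paced inter-trial intervals are drawn from a log-normal
whose median is conditioned on the previous trial's outcome — animals
initiate more slowly after a rewarded trial — with defaults calibrated to
the published wild-type medians (1.8 s rewarded / 1.1 s unrewarded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .task_engine import (LEFT, NONE, RIGHT, InvalidParameterError)


@dataclass
class LatencyModel:
    """Outcome-conditional log-normal inter-trial-interval generator.

    ``median_rewarded_s`` / ``median_unrewarded_s`` set the log-scale
    location per condition; ``dispersion`` is the log-scale sigma (a
    dispersion of 0 returns the conditional median exactly).
    """

    median_rewarded_s: float = 1.8
    median_unrewarded_s: float = 1.1
    dispersion: float = 0.4

    def __post_init__(self) -> None:
        if self.median_rewarded_s <= 0 or self.median_unrewarded_s <= 0:
            raise InvalidParameterError("latency medians must be positive")
        if self.dispersion < 0:
            raise InvalidParameterError("dispersion must be nonnegative")

    def sample(self, prev_rewarded: bool, rng: np.random.Generator) -> float:
        median = (self.median_rewarded_s if prev_rewarded
                  else self.median_unrewarded_s)
        if self.dispersion == 0:
            return median
        return float(median * math.exp(self.dispersion * rng.standard_normal()))


class AgentPolicy:
    """Base policy: maps choice/outcome history to the next choice.

    Subclasses implement ``_decide``; the base class handles the uniform
    first-trial choice and optional no-response lapses.  ``choose`` receives
    the current high side so that oracle agents can use it; ordinary
    policies ignore it.
    """

    name = "base"

    def __init__(self, latency: Optional[LatencyModel] = None,
                 p_no_response: float = 0.0):
        if not 0.0 <= p_no_response <= 1.0:
            raise InvalidParameterError("p_no_response outside [0, 1]")
        self.latency = LatencyModel() if latency is None else latency
        self.p_no_response = p_no_response
        self.prev_choice: Optional[str] = None
        self.prev_rewarded: Optional[bool] = None

    def reset(self) -> None:
        self.prev_choice = None
        self.prev_rewarded = None

    def choose(self, rng: np.random.Generator, high_side: str = LEFT) -> str:
        if self.p_no_response and rng.random() < self.p_no_response:
            return NONE
        return self._decide(rng, high_side)

    def _decide(self, rng: np.random.Generator, high_side: str) -> str:
        raise NotImplementedError

    def update(self, choice: str, rewarded: bool) -> None:
        self.prev_choice = choice
        self.prev_rewarded = rewarded


def wsls_choose(prev_choice: str, prev_rewarded: bool) -> str:
    """Win-stay/lose-switch rule: repeat a rewarded choice, switch after an
    unrewarded one."""
    if prev_choice not in (LEFT, RIGHT):
        raise InvalidParameterError(f"invalid previous choice {prev_choice!r}")
    if prev_rewarded:
        return prev_choice
    return RIGHT if prev_choice == LEFT else LEFT


class WSLSAgent(AgentPolicy):
    """Win-stay/lose-switch with an optional lapse rate.

    With probability ``eps`` the agent lapses to a uniform random choice;
    ``eps=0`` is the pure strategy.  First trial: uniform random.
    """

    name = "wsls"

    def __init__(self, eps: float = 0.0, **kwargs):
        super().__init__(**kwargs)
        if not 0.0 <= eps <= 1.0:
            raise InvalidParameterError("eps outside [0, 1]")
        self.eps = eps

    def _decide(self, rng, high_side):
        if self.prev_choice is None or (self.eps and rng.random() < self.eps):
            return LEFT if rng.random() < 0.5 else RIGHT
        return wsls_choose(self.prev_choice, self.prev_rewarded)


class BiasedRandomAgent(AgentPolicy):
    """Chooses left with fixed probability ``bias``, ignoring history."""

    name = "biased_random"

    def __init__(self, bias: float = 0.5, **kwargs):
        super().__init__(**kwargs)
        if not 0.0 <= bias <= 1.0:
            raise InvalidParameterError("bias outside [0, 1]")
        self.bias = bias

    def _decide(self, rng, high_side):
        return LEFT if rng.random() < self.bias else RIGHT


class QSoftmaxAgent(AgentPolicy):
    """Incremental value learner with softmax choice.

    Per-side action values are updated toward the observed reward with step
    ``alpha``; the next choice is softmax in the values with inverse
    temperature ``beta`` (``beta=0`` is uniform, large ``beta`` greedy).
    """

    name = "q_softmax"

    def __init__(self, alpha: float = 0.2, beta: float = 3.0, **kwargs):
        super().__init__(**kwargs)
        if not 0.0 <= alpha <= 1.0:
            raise InvalidParameterError("alpha outside [0, 1]")
        if beta < 0:
            raise InvalidParameterError("beta must be nonnegative")
        self.alpha = alpha
        self.beta = beta
        self.values = {LEFT: 0.0, RIGHT: 0.0}

    def reset(self) -> None:
        super().reset()
        self.values = {LEFT: 0.0, RIGHT: 0.0}

    def p_left(self) -> float:
        d = self.beta * (self.values[LEFT] - self.values[RIGHT])
        if d > 700:
            return 1.0
        if d < -700:
            return 0.0
        return 1.0 / (1.0 + math.exp(-d))

    def _decide(self, rng, high_side):
        return LEFT if rng.random() < self.p_left() else RIGHT

    def update(self, choice: str, rewarded: bool) -> None:
        super().update(choice, rewarded)
        v = self.values[choice]
        self.values[choice] = v + self.alpha * (float(rewarded) - v)


class AlternatingAgent(AgentPolicy):
    """Strict left-right alternation, starting left."""

    name = "alternator"

    def _decide(self, rng, high_side):
        if self.prev_choice is None:
            return LEFT
        return RIGHT if self.prev_choice == LEFT else LEFT


class IdealTrackerAgent(AgentPolicy):
    """Oracle agent that always chooses the current high-probability side.

    Unrealizable by a real animal (it sees the hidden state); used to probe
    the earliest possible reversal trigger and reward-rate ceilings.
    """

    name = "ideal_tracker"

    def _decide(self, rng, high_side):
        return high_side


AGENT_TYPES = {
    "wsls": WSLSAgent,
    "biased_random": BiasedRandomAgent,
    "q_softmax": QSoftmaxAgent,
    "alternator": AlternatingAgent,
    "ideal_tracker": IdealTrackerAgent,
}


def make_agent(spec: dict) -> AgentPolicy:
    """Build an agent from a ``{type: ..., params: {...}}`` mapping.

    Latency parameters (``median_rewarded_s``, ``median_unrewarded_s``,
    ``dispersion``) may be given inside ``params`` and are routed to the
    agent's :class:`LatencyModel`.
    """
    try:
        cls = AGENT_TYPES[spec["type"]]
    except KeyError:
        raise InvalidParameterError(
            f"unknown agent type {spec.get('type')!r}; "
            f"available: {sorted(AGENT_TYPES)}") from None
    params = dict(spec.get("params", {}))
    lat_kwargs = {k: params.pop(k) for k in
                  ("median_rewarded_s", "median_unrewarded_s", "dispersion")
                  if k in params}
    if lat_kwargs:
        params["latency"] = LatencyModel(**lat_kwargs)
    return cls(**params)


def sample_iti(model: LatencyModel, prev_rewarded: bool,
               rng: np.random.Generator) -> float:
    """Draw one inter-trial interval conditioned on the previous outcome."""
    return model.sample(prev_rewarded, rng)
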