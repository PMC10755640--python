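"""Stochastic environment for the dynamic foraging task.

Implements the freely-moving two-port task (baited probabilistic rewards,
uncued block reversals) in its training and full variants, and the
head-fixed two-armed bandit variant (no-lick periods, performance-plus-
random-delay block transitions, no-response session termination).

The trial loop is: bait ports -> agent chooses (or fails to respond) ->
resolve reward -> record latency -> evaluate the reversal rule -> possibly
swap the high-probability side.  All randomness flows through a single
``numpy.random.Generator`` per session, consumed in that fixed order, so a
session is fully reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

LEFT = "left"
RIGHT = "right"
NONE = "none"
SIDES = (LEFT, RIGHT)

VARIANTS = (
    "training_single_port",
    "training_0_100",
    "full_freely_moving",
    "headfixed_bandit",
)


class InvalidParameterError(ValueError):
    """A parameter is outside its documented domain."""


class ContractViolationError(RuntimeError):
    """A collaborator (e.g. an agent policy) broke its interface contract."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskConfig:
    """Full parameterization of one task variant.

    Parameters
    ----------
    variant
        One of ``training_single_port``, ``training_0_100``,
        ``full_freely_moving``, ``headfixed_bandit``.
    p_high, p_low
        Reward probabilities of the high and low port, in [0, 1].
    contingency_schedule
        Optional ordered list of ``(p_left, p_right)`` pairs, one per block
        (cycled if the session outlives the list).  When set, it overrides
        ``p_high``/``p_low`` and the notion of reversal becomes "advance to
        the next scheduled pair".
    block_length_cap
        Fixed block length in trials, or ``None`` for no cap.
    perf_window, perf_threshold
        Performance-triggered reversal: the block ends once at least
        ``perf_threshold`` of the last ``perf_window`` choices were to the
        high-probability port.  Set either to ``None`` to disable the rule.
    baited
        If True, a reward assigned to a port stays available until that
        port is next chosen; if False, rewards are drawn fresh per trial.
    max_trials
        Session length cap.
    no_response_limit
        End the session after this many consecutive no-response trials
        (``None`` disables; the head-fixed task uses 20).
    nolick_rate, nolick_min, nolick_max, nolick_max_draws
        Truncated-exponential no-lick period (head-fixed): rate per second,
        support bounds in seconds, and the maximum number of draws summed
        when the animal licks during the period.
    geo_mean, geo_min, geo_max
        Truncated-geometric block-transition delay (head-fixed):
        untruncated mean and support bounds, in trials.
    headfixed_switch_trials
        Cumulative high-side choices within a block that arm the head-fixed
        block transition.
    seed
        Default session seed (can be overridden per run).
    """

    variant: str = "full_freely_moving"
    p_high: float = 0.60
    p_low: float = 0.15
    contingency_schedule: Optional[Tuple[Tuple[float, float], ...]] = None
    block_length_cap: Optional[int] = 80
    perf_window: Optional[int] = None
    perf_threshold: Optional[int] = None
    baited: bool = True
    max_trials: int = 938
    no_response_limit: Optional[int] = None
    nolick_rate: float = 0.3333
    nolick_min: float = 1.0
    nolick_max: float = 5.0
    nolick_max_draws: int = 5
    geo_mean: float = 11.0
    geo_min: int = 0
    geo_max: int = 30
    headfixed_switch_trials: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise InvalidParameterError(f"unknown variant {self.variant!r}")
        for name in ("p_high", "p_low"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"{name}={p} outside [0, 1]")
        if self.p_low > self.p_high:
            raise InvalidParameterError("p_low must not exceed p_high")
        if self.contingency_schedule is not None:
            sched = tuple(tuple(pair) for pair in self.contingency_schedule)
            object.__setattr__(self, "contingency_schedule", sched)
            for pair in sched:
                if len(pair) != 2 or not all(0.0 <= p <= 1.0 for p in pair):
                    raise InvalidParameterError(
                        f"bad contingency pair {pair!r}")
        if self.block_length_cap is not None and self.block_length_cap < 1:
            raise InvalidParameterError("block_length_cap must be positive")
        if self.perf_rule_enabled and self.perf_threshold > self.perf_window:
            raise InvalidParameterError(
                "perf_threshold must not exceed perf_window")
        if self.max_trials < 1:
            raise InvalidParameterError("max_trials must be positive")
        if self.nolick_rate <= 0:
            raise InvalidParameterError("nolick_rate must be positive")
        if not self.nolick_min < self.nolick_max:
            raise InvalidParameterError("need nolick_min < nolick_max")
        if self.nolick_max_draws < 1:
            raise InvalidParameterError("nolick_max_draws must be >= 1")
        if self.geo_min > self.geo_max:
            raise InvalidParameterError("need geo_min <= geo_max")

    @property
    def perf_rule_enabled(self) -> bool:
        return self.perf_window is not None and self.perf_threshold is not None

    def block_probabilities(self, block_index: int,
                            high_side: str) -> Tuple[float, float]:
        """(p_left, p_right) in force during the given block."""
        if self.contingency_schedule is not None:
            sched = self.contingency_schedule
            return sched[block_index % len(sched)]
        if high_side == LEFT:
            return self.p_high, self.p_low
        return self.p_low, self.p_high


# Named presets mirroring the published task variants.  The training task
# pairs a 100-trial cap with the 9-of-10 performance rule; the full task
# reverses strictly on the block-length cap.
PRESETS = {
    "training_0_100": TaskConfig(
        variant="training_0_100", p_high=1.0, p_low=0.0,
        block_length_cap=100, perf_window=10, perf_threshold=9,
        baited=True, max_trials=714),
    "full_15_60": TaskConfig(
        variant="full_freely_moving", p_high=0.60, p_low=0.15,
        block_length_cap=80, baited=True, max_trials=938),
    "block40": TaskConfig(
        variant="full_freely_moving", p_high=0.60, p_low=0.15,
        block_length_cap=40, baited=True, max_trials=938),
    "block100": TaskConfig(
        variant="full_freely_moving", p_high=0.60, p_low=0.15,
        block_length_cap=100, baited=True, max_trials=938),
    "contingencies_30_30_15_45_10_50": TaskConfig(
        variant="full_freely_moving", p_high=0.50, p_low=0.10,
        contingency_schedule=((0.30, 0.30), (0.15, 0.45), (0.10, 0.50)),
        block_length_cap=80, baited=True, max_trials=938),
    "contingencies_50_50_15_85_25_75": TaskConfig(
        variant="full_freely_moving", p_high=0.85, p_low=0.15,
        contingency_schedule=((0.50, 0.50), (0.15, 0.85), (0.25, 0.75)),
        block_length_cap=80, baited=True, max_trials=938),
    "headfixed_70_10": TaskConfig(
        variant="headfixed_bandit", p_high=0.70, p_low=0.10,
        block_length_cap=None, baited=False, max_trials=500,
        no_response_limit=20),
}


def get_preset(name: str, **overrides) -> TaskConfig:
    """Return a named task preset, optionally with field overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# Trial-level state and records
# ---------------------------------------------------------------------------

@dataclass
class PortState:
    """Bait flags of the two ports.

    Flags are set only by baiting draws and cleared only when the animal
    chooses the port: an assigned reward stays available until collected.
    """

    baited_left: bool = False
    baited_right: bool = False

    def copy(self) -> "PortState":
        return PortState(self.baited_left, self.baited_right)


@dataclass
class Trial:
    """One choice event with its outcome and timing."""

    index: int
    block_index: int
    high_side: str
    choice: str              # left / right / none
    rewarded: bool
    iti_s: Optional[float] = None        # latency preceding this trial
    nolick_duration_s: Optional[float] = None

    @property
    def correct(self) -> bool:
        """Chose the high-probability port, regardless of reward receipt."""
        return self.choice == self.high_side


@dataclass
class Session:
    """Ordered trials of one behavioral session plus subject metadata."""

    subject_id: str
    genotype: str            # WT / HET
    sex: str                 # M / F
    variant: str
    trials: List[Trial] = field(default_factory=list)
    block_boundaries: List[int] = field(default_factory=list)
    seed_used: int = 0
    session_id: str = "s0"

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def block_lengths(self) -> List[int]:
        """Lengths of completed blocks (bounded by recorded reversals)."""
        edges = [0] + list(self.block_boundaries)
        return [b - a for a, b in zip(edges, edges[1:])]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def sample_baiting(state: PortState, p_left: float, p_right: float,
                   rng: np.random.Generator) -> PortState:
    """One baiting draw per port: an unbaited port becomes baited with its
    probability; an already-baited port stays baited.

    Called once per trial before the choice is resolved.  Returns a new
    ``PortState``; the input is not mutated.
    """
    for name, p in (("p_left", p_left), ("p_right", p_right)):
        if not 0.0 <= p <= 1.0:
            raise InvalidParameterError(f"{name}={p} outside [0, 1]")
    u_left, u_right = rng.random(2)
    return PortState(
        baited_left=state.baited_left or u_left < p_left,
        baited_right=state.baited_right or u_right < p_right,
    )


def resolve_choice(state: PortState, choice: str) -> Tuple[bool, PortState]:
    """Collect the chosen port's bait, if any.

    Returns ``(rewarded, new_state)``: reward equals the chosen port's bait
    flag, which is then cleared; the other port is untouched.
    """
    if choice not in SIDES:
        raise InvalidParameterError(f"choice must be left/right, got {choice!r}")
    new = state.copy()
    if choice == LEFT:
        rewarded = new.baited_left
        new.baited_left = False
    else:
        rewarded = new.baited_right
        new.baited_right = False
    return rewarded, new


def check_reversal(block_trials: Sequence[Trial], config: TaskConfig) -> bool:
    """Should the high side reverse after the last completed trial?

    True iff the block reached ``block_length_cap`` trials, or the
    performance rule is enabled and at least ``perf_threshold`` of the last
    ``perf_window`` trials (all within the current block) chose the
    high-probability port.
    """
    n = len(block_trials)
    if config.block_length_cap is not None and n >= config.block_length_cap:
        return True
    if config.perf_rule_enabled and n >= config.perf_window:
        recent = block_trials[n - config.perf_window:]
        if sum(t.correct for t in recent) >= config.perf_threshold:
            return True
    return False


def _truncexp_ppf(u: float, rate: float, lo: float, hi: float) -> float:
    """Inverse CDF of Exp(rate) truncated to [lo, hi], at quantile u."""
    z = 1.0 - math.exp(-rate * (hi - lo))
    return lo - math.log1p(-u * z) / rate


def truncated_exponential_mean(rate: float, lo: float, hi: float) -> float:
    """Closed-form mean of Exp(rate) truncated to [lo, hi]."""
    z = 1.0 - math.exp(-rate * (hi - lo))
    # E[X] = lo + 1/rate - (hi - lo) * exp(-rate*(hi-lo)) / z
    return lo + 1.0 / rate - (hi - lo) * (1.0 - z) / z


def sample_nolick_period(rng: np.random.Generator, config: TaskConfig,
                         n_violations: int = 0) -> float:
    """Total no-lick period in seconds after ``n_violations`` premature licks.

    The initial draw and each violation-triggered extension are independent
    truncated-exponential samples (inverse CDF, so every draw is bounded);
    the total number of draws is capped at ``nolick_max_draws``, giving a
    hard ceiling of ``nolick_max_draws * nolick_max`` seconds (25 s at the
    defaults).
    """
    if n_violations < 0:
        raise InvalidParameterError("n_violations must be nonnegative")
    n_draws = 1 + min(n_violations, config.nolick_max_draws - 1)
    total = 0.0
    for u in rng.random(n_draws):
        total += _truncexp_ppf(u, config.nolick_rate,
                               config.nolick_min, config.nolick_max)
    return total


def nolick_duration_bounds(config: TaskConfig) -> Tuple[float, float]:
    """Attainable [infimum, supremum] of the total no-lick duration.

    Analytic: a single draw lies in [nolick_min, nolick_max], and at most
    ``nolick_max_draws`` draws are summed.
    """
    return config.nolick_min, config.nolick_max_draws * config.nolick_max


def _truncated_geometric_pmf(config: TaskConfig) -> np.ndarray:
    """Renormalized pmf of the block-transition delay on [geo_min, geo_max].

    Geometric on {0, 1, 2, ...} with success probability 1/(geo_mean + 1)
    (so the untruncated mean is geo_mean), renormalized over the support.
    """
    p = 1.0 / (config.geo_mean + 1.0)
    k = np.arange(config.geo_min, config.geo_max + 1)
    w = (1.0 - p) ** k * p
    return w / w.sum()


def truncated_geometric_mean(config: TaskConfig) -> float:
    """Analytic mean of the truncated block-transition distribution."""
    pmf = _truncated_geometric_pmf(config)
    k = np.arange(config.geo_min, config.geo_max + 1)
    return float((k * pmf).sum())


def sample_block_transition(rng: np.random.Generator,
                            config: TaskConfig) -> int:
    """Draw the number of extra trials before a head-fixed block switch."""
    if config.geo_min == config.geo_max:
        return int(config.geo_min)
    pmf = _truncated_geometric_pmf(config)
    return int(config.geo_min + rng.choice(len(pmf), p=pmf))


# ---------------------------------------------------------------------------
# Session loop
# ---------------------------------------------------------------------------

def run_session(agent, config: TaskConfig, rng=None, *,
                subject_id: str = "sub0", genotype: str = "WT",
                sex: str = "M", session_id: str = "s0",
                seed: Optional[int] = None) -> Session:
    """Simulate one session of ``agent`` behaving under ``config``.

    Deterministic given (agent, config, seed).  The loop per trial:
    bait -> agent chooses (possibly ``none``) -> resolve reward -> record
    the agent's self-paced latency -> evaluate the reversal rule.  The
    session ends at ``max_trials`` or after ``no_response_limit``
    consecutive no-response trials.
    """
    if seed is None:
        seed = config.seed
    if rng is None:
        rng = np.random.default_rng(seed)
    agent.reset()

    session = Session(subject_id=subject_id, genotype=genotype, sex=sex,
                      variant=config.variant, seed_used=seed,
                      session_id=session_id)
    state = PortState()
    high_side = LEFT if rng.random() < 0.5 else RIGHT
    block_index = 0
    block_trials: List[Trial] = []
    headfixed = config.variant == "headfixed_bandit"
    high_choices_in_block = 0
    switch_countdown: Optional[int] = None   # armed head-fixed transition
    consecutive_none = 0
    prev_outcome: Optional[bool] = None      # None until a completed trial

    for t in range(config.max_trials):
        p_left, p_right = config.block_probabilities(block_index, high_side)
        if config.contingency_schedule is not None:
            # the scheduled pair, not the swap logic, defines the high side
            # (ties, e.g. 30:30, are labeled left by convention)
            high_side = LEFT if p_left >= p_right else RIGHT
        if not config.baited:
            state = PortState()              # rewards do not persist
        state = sample_baiting(state, p_left, p_right, rng)

        choice = agent.choose(rng, high_side=high_side)
        if choice not in (LEFT, RIGHT, NONE, None):
            raise ContractViolationError(
                f"agent returned invalid side {choice!r}")
        if choice is None:
            choice = NONE

        nolick = sample_nolick_period(rng, config, 0) if headfixed else None
        iti = None
        if prev_outcome is not None and hasattr(agent, "latency"):
            if agent.latency is not None:
                iti = agent.latency.sample(prev_outcome, rng)

        if choice == NONE:
            rewarded = False
            consecutive_none += 1
        else:
            rewarded, state = resolve_choice(state, choice)
            consecutive_none = 0
            agent.update(choice, rewarded)
            prev_outcome = rewarded

        trial = Trial(index=t, block_index=block_index, high_side=high_side,
                      choice=choice, rewarded=rewarded, iti_s=iti,
                      nolick_duration_s=nolick)
        session.trials.append(trial)
        block_trials.append(trial)

        # Block-transition logic.
        reverse = False
        if headfixed:
            if trial.correct:
                high_choices_in_block += 1
            if (switch_countdown is None
                    and high_choices_in_block >= config.headfixed_switch_trials):
                switch_countdown = sample_block_transition(rng, config)
            if switch_countdown is not None:
                if switch_countdown == 0:
                    reverse = True
                else:
                    switch_countdown -= 1
        else:
            reverse = check_reversal(block_trials, config)

        if reverse:
            high_side = RIGHT if high_side == LEFT else LEFT
            block_index += 1
            session.block_boundaries.append(t + 1)
            block_trials = []
            high_choices_in_block = 0
            switch_countdown = None

        if (config.no_response_limit is not None
                and consecutive_none >= config.no_response_limit):
            break

    # A boundary recorded at the very end delimits no following block.
    if session.block_boundaries and \
            session.block_boundaries[-1] >= session.n_trials:
        session.block_boundaries.pop()
    return session
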