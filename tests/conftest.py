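import numpy as np
import pytest

from forage.task_engine import LEFT, RIGHT, Session, Trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_session(choices, rewards, boundaries=(), itis=None,
                  high_sides=None, subject_id="sub0", genotype="WT",
                  sex="M"):
    """Hand-build a session from parallel per-trial lists.

    ``high_sides`` defaults to left before the first boundary, flipping at
    every boundary.
    """
    boundaries = sorted(boundaries)
    if high_sides is None:
        high_sides = []
        side, b_iter = LEFT, list(boundaries)
        for i in range(len(choices)):
            if b_iter and i == b_iter[0]:
                side = RIGHT if side == LEFT else LEFT
                b_iter.pop(0)
            high_sides.append(side)
    trials = []
    block = 0
    b_iter = list(boundaries)
    for i, (c, r) in enumerate(zip(choices, rewards)):
        if b_iter and i == b_iter[0]:
            block += 1
            b_iter.pop(0)
        trials.append(Trial(
            index=i, block_index=block, high_side=high_sides[i], choice=c,
            rewarded=bool(r),
            iti_s=None if itis is None or itis[i] is None else float(itis[i])))
    return Session(subject_id=subject_id, genotype=genotype, sex=sex,
                   variant="full_freely_moving", trials=trials,
                   block_boundaries=list(boundaries))


def random_session(rng, n_trials=50, p_none=0.05, with_iti=True):
    """A random session used by the brute-force equivalence properties."""
    n_bound = int(rng.integers(0, 4))
    boundaries = sorted(rng.choice(np.arange(1, n_trials), size=n_bound,
                                   replace=False).tolist()) if n_bound else []
    choices = []
    for _ in range(n_trials):
        u = rng.random()
        if u < p_none:
            choices.append("none")
        else:
            choices.append(LEFT if u < (1 + p_none) / 2 else RIGHT)
    rewards = [bool(rng.random() < 0.5) and c != "none" for c in choices]
    itis = [None] + [float(rng.gamma(2.0, 1.0)) + 1e-3
                     for _ in range(n_trials - 1)] if with_iti else None
    return build_session(choices, rewards, boundaries, itis=itis)
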