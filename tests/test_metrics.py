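"""Behavioral metrics: examples by hand, brute-force equivalence, and
relabeling invariance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_session, random_session
from forage import (IdealTrackerAgent, LatencyModel, WSLSAgent,
                    conditional_iti, contingency_ratio, learning_curve,
                    moving_average_choice, reversal_aligned, run_session,
                    wsls_fractions)
from forage.task_engine import (LEFT, NONE, RIGHT, InvalidParameterError,
                                Session, Trial, get_preset)

L, R, N = LEFT, RIGHT, NONE


# ---------------------------------------------------------------------------
# Brute-force oracles (independent recounts used by the property tests)
# ---------------------------------------------------------------------------

def brute_wsls(session):
    trials = session.trials
    ws = wn = ls = ln_ = 0
    for i in range(len(trials) - 1):
        a, b = trials[i], trials[i + 1]
        if a.choice == N or b.choice == N:
            continue
        if a.rewarded:
            wn += 1
            ws += int(b.choice == a.choice)
        else:
            ln_ += 1
            ls += int(b.choice != a.choice)
    return (ws / wn if wn else None, ls / ln_ if ln_ else None, wn, ln_)


def brute_reversal(session, n_after):
    bounds = list(session.block_boundaries)
    ends = bounds[1:] + [len(session.trials)]
    out = []
    for k in range(1, n_after + 1):
        num = den = 0
        for b, end in zip(bounds, ends):
            idx = b + k - 1
            if idx >= end:                  # block shorter than k
                continue
            t = session.trials[idx]
            if t.choice == N:
                continue
            den += 1
            num += int(t.choice == t.high_side)
        out.append(num / den if den else float("nan"))
    return out


def brute_iti(session):
    rew, unrew = [], []
    for i in range(1, len(session.trials)):
        prev, cur = session.trials[i - 1], session.trials[i]
        if cur.iti_s is None or prev.choice == N:
            continue
        (rew if prev.rewarded else unrew).append(cur.iti_s)
    med = lambda xs: float(np.percentile(xs, 50)) if xs else float("nan")
    return med(rew), med(unrew)


# ---------------------------------------------------------------------------
# Learning curve
# ---------------------------------------------------------------------------

class TestLearningCurve:
    def test_ideal_tracker_is_perfect(self):
        cfg = get_preset("training_0_100", max_trials=100)
        days = {d: [run_session(IdealTrackerAgent(), cfg, seed=d,
                                subject_id="a")] for d in (1, 2)}
        curve = learning_curve(days)
        assert (curve.p_high_choice == 1.0).all()

    def test_alternator_is_at_chance(self):
        from forage import AlternatingAgent
        cfg = get_preset("training_0_100", max_trials=600)
        curve = learning_curve(
            {1: [run_session(AlternatingAgent(), cfg, seed=1)]})
        frac = curve.p_high_choice.iloc[0]
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / 600)

    def test_wsls_steady_state_is_point_nine(self):
        """One error per 10-trial block -> 0.9 high-port fraction."""
        cfg = get_preset("training_0_100", max_trials=1010)
        s = run_session(WSLSAgent(eps=0.0), cfg, seed=3)
        # drop the startup block, keep full 10-trial cycles
        start = s.block_boundaries[0]
        trials = s.trials[start:start + 10 * ((s.n_trials - start) // 10)]
        frac = np.mean([t.correct for t in trials])
        assert frac == pytest.approx(0.9)

    def test_day_without_valid_trials_is_missing(self):
        s = build_session([N, N], [0, 0])
        curve = learning_curve({1: [s]})
        assert np.isnan(curve.p_high_choice.iloc[0])


# ---------------------------------------------------------------------------
# Reversal-aligned curve
# ---------------------------------------------------------------------------

class TestReversalAligned:
    def test_wsls_on_deterministic_training(self):
        """Pure WSLS carries its pre-reversal win into trial 1 (always
        wrong), then tracks perfectly from trial 2 on."""
        cfg = get_preset("training_0_100", max_trials=400)
        s = run_session(WSLSAgent(eps=0.0), cfg, seed=17)
        curve = reversal_aligned(s, n_after=5)
        assert curve.n_blocks >= 5
        assert curve.p_new_high[0] == 0.0
        assert (curve.p_new_high[1:] == 1.0).all()

    def test_uniform_agent_is_flat_at_half(self):
        from forage import BiasedRandomAgent
        cfg = get_preset("full_15_60", max_trials=8000)
        s = run_session(BiasedRandomAgent(bias=0.5), cfg, seed=19)
        curve = reversal_aligned(s, n_after=10)
        n = curve.n_blocks
        for p in curve.p_new_high:
            assert abs(p - 0.5) < 4 * math.sqrt(0.25 / n)

    def test_hand_built_session(self):
        # boundary at 5: new high side is right for trials 5..
        choices = [L, L, R, L, L, R, R, N, L, R]
        rewards = [1, 1, 0, 1, 0, 1, 1, 0, 0, 1]
        s = build_session(choices, rewards, boundaries=[5])
        curve = reversal_aligned(s, n_after=4)
        assert curve.n_blocks == 1
        # trial 5 chose R (new high) -> 1; trial 6 R -> 1; trial 7 none ->
        # NaN; trial 8 L -> 0
        assert curve.p_new_high[0] == 1.0
        assert curve.p_new_high[1] == 1.0
        assert np.isnan(curve.p_new_high[2])
        assert curve.p_new_high[3] == 0.0

    def test_no_reversals_gives_empty_curve(self):
        s = build_session([L, R, L], [1, 0, 1])
        curve = reversal_aligned(s, n_after=3)
        assert curve.n_blocks == 0
        assert np.isnan(curve.p_new_high).all()

    def test_short_blocks_drop_out_of_late_denominators(self):
        choices = [L, L, R, R, L, L]
        rewards = [1, 0, 1, 0, 1, 0]
        s = build_session(choices, rewards, boundaries=[2, 4])
        curve = reversal_aligned(s, n_after=4)
        assert curve.n_blocks == 2
        # block 1 (trials 2,3, high=right): k=1 -> R correct; block 2
        # (trials 4,5, high=left): k=1 -> L correct
        assert curve.p_new_high[0] == 1.0
        assert curve.p_new_high[1] == 1.0   # trials 3 (R) and 5 (L) correct
        assert np.isnan(curve.p_new_high[2])


# ---------------------------------------------------------------------------
# WSLS fractions
# ---------------------------------------------------------------------------

class TestWSLSFractions:
    def test_worked_example(self):
        s = build_session([L, L, R, R], [1, 1, 0, 1])
        stats = wsls_fractions(s)
        assert stats.win_stay == pytest.approx(0.5)
        assert stats.lose_switch == 0.0
        assert stats.n_win_transitions == 2
        assert stats.n_lose_transitions == 1

    def test_pure_perseverator(self):
        s = build_session([L] * 6, [1, 0, 1, 0, 1, 0])
        stats = wsls_fractions(s)
        assert stats.win_stay == 1.0 and stats.lose_switch == 0.0

    def test_zero_denominator_yields_missing(self):
        s = build_session([L, R], [1, 1])   # no unrewarded trial with successor
        stats = wsls_fractions(s)
        assert stats.lose_switch is None
        assert stats.n_lose_transitions == 0

    def test_pairs_spanning_no_response_excluded(self):
        s = build_session([L, N, L, L], [1, 0, 1, 1])
        stats = wsls_fractions(s)
        # only the (2,3) pair counts
        assert stats.n_win_transitions == 1 and stats.win_stay == 1.0


# ---------------------------------------------------------------------------
# Conditional ITI
# ---------------------------------------------------------------------------

class TestConditionalITI:
    def test_constant_itis(self):
        s = build_session([L, R, L, R], [1, 0, 1, 0],
                          itis=[None, 2.0, 2.0, 2.0])
        stats = conditional_iti(s)
        assert stats.median_rewarded_s == 2.0
        assert stats.median_unrewarded_s == 2.0
        assert stats.iqr_rewarded == (2.0, 2.0)

    def test_hand_fixture_medians(self):
        # rewarded predecessors get ITIs [2.0, 3.0, 4.0]; unrewarded [1.0,
        # 1.5, 0.5]
        choices = [L, L, L, L, L, L, L]
        rewards = [1, 0, 1, 0, 1, 0, 1]
        itis = [None, 2.0, 1.0, 3.0, 1.5, 4.0, 0.5]
        s = build_session(choices, rewards, itis=itis)
        stats = conditional_iti(s)
        assert stats.median_rewarded_s == 3.0
        assert stats.median_unrewarded_s == 1.0
        assert stats.iqr_rewarded == (2.5, 3.5)   # linear interpolation

    def test_parameter_recovery_from_generated_session(self):
        cfg = get_preset("full_15_60", max_trials=10_000)
        agent = WSLSAgent(eps=0.2, latency=LatencyModel(
            median_rewarded_s=1.8, median_unrewarded_s=1.1, dispersion=0.1))
        s = run_session(agent, cfg, seed=23)
        stats = conditional_iti(s)
        assert abs(stats.median_rewarded_s - 1.8) / 1.8 < 0.02
        assert abs(stats.median_unrewarded_s - 1.1) / 1.1 < 0.02


# ---------------------------------------------------------------------------
# Moving average and matching ratio
# ---------------------------------------------------------------------------

class TestMovingAverage:
    def test_constant_left(self):
        s = build_session([L] * 15, [1] * 15)
        assert (moving_average_choice(s.trials) == 1.0).all()

    def test_alternation_settles_at_half(self):
        s = build_session([L, R] * 10, [1] * 20)
        trace = moving_average_choice(s.trials, window=10)
        assert (trace[9:] == 0.5).all()

    def test_hand_fixture_trace(self):
        choices = [L, L, R, L, R, R, R, L, L, L, R, L]
        s = build_session(choices, [1] * 12)
        trace = moving_average_choice(s.trials, window=4)
        expect = []
        vals = [1 if c == L else 0 for c in choices]
        for i in range(len(vals)):
            lo = max(0, i - 3)
            expect.append(np.mean(vals[lo:i + 1]))
        assert np.allclose(trace, expect)

    def test_invalid_window(self):
        with pytest.raises(InvalidParameterError):
            moving_average_choice([], window=0)


class TestContingencyRatio:
    @pytest.mark.parametrize("pl,pr,expect", [
        (60, 15, 0.8), (15, 60, 0.2), (30, 30, 0.5)])
    def test_printed_ratios(self, pl, pr, expect):
        assert contingency_ratio(pl, pr) == pytest.approx(expect)

    def test_both_zero_rejected(self):
        with pytest.raises(InvalidParameterError):
            contingency_ratio(0, 0)


# ---------------------------------------------------------------------------
# Properties: brute-force equivalence and relabeling invariance
# ---------------------------------------------------------------------------

@settings(max_examples=100, derandomize=True, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_metrics_match_brute_force_recount(seed):
    rng = np.random.default_rng(seed)
    s = random_session(rng, n_trials=50)

    stats = wsls_fractions(s)
    bw, bl, bwn, bln = brute_wsls(s)
    assert stats.win_stay == bw and stats.lose_switch == bl
    assert stats.n_win_transitions == bwn
    assert stats.n_lose_transitions == bln

    curve = reversal_aligned(s, n_after=6)
    expect = brute_reversal(s, 6)
    assert np.allclose(curve.p_new_high, expect, equal_nan=True)

    iti = conditional_iti(s)
    med_r, med_u = brute_iti(s)
    for a, b in ((iti.median_rewarded_s, med_r),
                 (iti.median_unrewarded_s, med_u)):
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


def _mirror(session):
    flip = {L: R, R: L, N: N}
    out = Session(subject_id=session.subject_id, genotype=session.genotype,
                  sex=session.sex, variant=session.variant,
                  block_boundaries=list(session.block_boundaries))
    for t in session.trials:
        out.trials.append(Trial(
            index=t.index, block_index=t.block_index,
            high_side=flip[t.high_side], choice=flip[t.choice],
            rewarded=t.rewarded, iti_s=t.iti_s))
    return out


@settings(max_examples=50, derandomize=True, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_metrics_invariant_to_left_right_relabeling(seed):
    """Jointly flipping choices and schedules changes no metric."""
    rng = np.random.default_rng(seed)
    s = random_session(rng, n_trials=50)
    m = _mirror(s)

    a, b = wsls_fractions(s), wsls_fractions(m)
    assert a.win_stay == b.win_stay and a.lose_switch == b.lose_switch

    ca = reversal_aligned(s, n_after=5).p_new_high
    cb = reversal_aligned(m, n_after=5).p_new_high
    assert np.allclose(ca, cb, equal_nan=True)

    ia, ib = conditional_iti(s), conditional_iti(m)
    for x, y in ((ia.median_rewarded_s, ib.median_rewarded_s),
                 (ia.median_unrewarded_s, ib.median_unrewarded_s)):
        assert (np.isnan(x) and np.isnan(y)) or x == y
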