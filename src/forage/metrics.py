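"""Behavioral statistics computed from trial-level session logs.

Covers the full analysis battery of the foraging study: per-day learning
curves, reversal-aligned choice probability, win-stay/lose-switch
fractions, outcome-conditional inter-trial intervals, the 10-trial moving
average of choice, and the reward-contingency ratio that choice fractions
"match".

Conventions (applied uniformly):
- trials with choice ``none`` carry no choice information and are excluded
  from every choice-based numerator and denominator;
- WSLS transitions are pairs of consecutive valid-choice trials, including
  pairs that span a reversal (the strategy is defined on outcome and
  choice, not on block identity);
- quartiles use linear interpolation so reported IQRs are reproducible
  bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .task_engine import (LEFT, NONE, RIGHT, InvalidParameterError, Session,
                          Trial)


@dataclass
class ReversalCurve:
    """Probability of choosing the new high side on trials 1..N after an
    uncued reversal, with the number of contributing blocks."""

    trials_since_reversal: np.ndarray
    p_new_high: np.ndarray
    n_blocks: int


@dataclass
class WSLSStats:
    win_stay: Optional[float]
    lose_switch: Optional[float]
    n_win_transitions: int
    n_lose_transitions: int


@dataclass
class ITIStats:
    median_rewarded_s: float
    median_unrewarded_s: float
    iqr_rewarded: Tuple[float, float]
    iqr_unrewarded: Tuple[float, float]


def _valid(trials: Iterable[Trial]) -> List[Trial]:
    return [t for t in trials if t.choice in (LEFT, RIGHT)]


# ---------------------------------------------------------------------------
# Learning curve (training sessions across days)
# ---------------------------------------------------------------------------

def learning_curve(sessions_by_day: Dict[int, Sequence[Session]]
                   ) -> pd.DataFrame:
    """Per subject per training day, fraction of valid-choice trials on the
    high-probability port.

    ``sessions_by_day`` maps day number to that day's sessions.  A
    subject-day with zero valid trials yields a missing value, not zero.
    Returns a tidy frame with columns ``subject_id, day, p_high_choice``.
    """
    rows = []
    for day, sessions in sorted(sessions_by_day.items()):
        for s in sessions:
            valid = _valid(s.trials)
            frac = (sum(t.correct for t in valid) / len(valid)
                    if valid else np.nan)
            rows.append({"subject_id": s.subject_id, "day": day,
                         "p_high_choice": frac})
    return pd.DataFrame(rows, columns=["subject_id", "day", "p_high_choice"])


# ---------------------------------------------------------------------------
# Reversal-aligned choice probability
# ---------------------------------------------------------------------------

def reversal_aligned(sessions, n_after: int = 10) -> ReversalCurve:
    """Fraction of blocks choosing the new high side on each of the first
    ``n_after`` post-reversal trials.

    For k = 1..n_after, the numerator counts blocks whose k-th
    post-reversal trial was a valid choice of the new high side; blocks
    shorter than k (and no-response trials) drop out of trial k's
    denominator.  With no reversals in the input the curve is empty with
    ``n_blocks=0``.
    """
    if n_after < 1:
        raise InvalidParameterError("n_after must be >= 1")
    if isinstance(sessions, Session):
        sessions = [sessions]
    hits = np.zeros(n_after)
    counts = np.zeros(n_after)
    n_blocks = 0
    for s in sessions:
        bounds = list(s.block_boundaries)
        for j, b in enumerate(bounds):
            n_blocks += 1
            end = bounds[j + 1] if j + 1 < len(bounds) else len(s.trials)
            post = s.trials[b:min(b + n_after, end)]
            for k, t in enumerate(post):
                if t.choice == NONE:
                    continue
                counts[k] += 1
                hits[k] += t.correct
    with np.errstate(invalid="ignore"):
        p = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    return ReversalCurve(np.arange(1, n_after + 1), p, n_blocks)


def reversal_aligned_by_subject(sessions: Sequence[Session],
                                n_after: int = 10,
                                per_subject: bool = True) -> pd.DataFrame:
    """Group-level reversal curve as a tidy frame.

    With ``per_subject=True`` (default) blocks are pooled within subject
    first and the returned rows are per subject-trial, ready for
    across-subject averaging; with ``per_subject=False`` all blocks are
    pooled into a single curve.
    """
    if not per_subject:
        curve = reversal_aligned(list(sessions), n_after)
        return pd.DataFrame({"subject_id": "pooled",
                             "trial": curve.trials_since_reversal,
                             "p_new_high": curve.p_new_high})
    rows = []
    by_subject: Dict[str, List[Session]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject_id, []).append(s)
    for sid, ss in by_subject.items():
        curve = reversal_aligned(ss, n_after)
        for k, p in zip(curve.trials_since_reversal, curve.p_new_high):
            rows.append({"subject_id": sid, "trial": int(k), "p_new_high": p})
    return pd.DataFrame(rows, columns=["subject_id", "trial", "p_new_high"])


# ---------------------------------------------------------------------------
# Win-stay / lose-switch
# ---------------------------------------------------------------------------

def wsls_fractions(session: Session) -> WSLSStats:
    """Win-stay and lose-switch fractions over consecutive valid-choice
    trial pairs.

    win_stay = (stays following a rewarded trial) / (rewarded trials with a
    valid successor); lose_switch analogously for unrewarded trials.  A
    zero denominator yields a missing fraction.
    """
    valid = _valid(session.trials)
    win_stay = win_n = lose_switch = lose_n = 0
    for a, b in zip(valid, valid[1:]):
        if b.index != a.index + 1:
            continue                       # a no-response interrupted the pair
        if a.rewarded:
            win_n += 1
            win_stay += b.choice == a.choice
        else:
            lose_n += 1
            lose_switch += b.choice != a.choice
    return WSLSStats(
        win_stay=win_stay / win_n if win_n else None,
        lose_switch=lose_switch / lose_n if lose_n else None,
        n_win_transitions=win_n,
        n_lose_transitions=lose_n,
    )


# ---------------------------------------------------------------------------
# Outcome-conditional inter-trial intervals
# ---------------------------------------------------------------------------

def conditional_iti(session: Session) -> ITIStats:
    """Medians and IQRs of the inter-trial interval, split by the outcome
    of the preceding trial.

    Trial t's latency is attributed to trial t-1's outcome; quartiles by
    linear interpolation.
    """
    rewarded, unrewarded = [], []
    for prev, cur in zip(session.trials, session.trials[1:]):
        if cur.iti_s is None or prev.choice == NONE:
            continue
        (rewarded if prev.rewarded else unrewarded).append(cur.iti_s)

    def _summary(xs):
        if not xs:
            return np.nan, (np.nan, np.nan)
        q1, med, q3 = np.percentile(xs, [25, 50, 75])
        return float(med), (float(q1), float(q3))

    med_r, iqr_r = _summary(rewarded)
    med_u, iqr_u = _summary(unrewarded)
    return ITIStats(med_r, med_u, iqr_r, iqr_u)


# ---------------------------------------------------------------------------
# Moving-average choice trace and matching ratio
# ---------------------------------------------------------------------------

def moving_average_choice(trials: Sequence[Trial],
                          window: int = 10) -> np.ndarray:
    """Trailing-window mean of the left-choice indicator.

    The first ``window - 1`` positions average over the history available
    so far; no-response trials are skipped in both numerator and
    denominator (a position with no valid history yet is NaN).
    """
    if window < 1:
        raise InvalidParameterError("window must be >= 1")
    out = np.full(len(trials), np.nan)
    recent: List[float] = []
    for i, t in enumerate(trials):
        if t.choice in (LEFT, RIGHT):
            recent.append(1.0 if t.choice == LEFT else 0.0)
            if len(recent) > window:
                recent.pop(0)
        if recent:
            out[i] = sum(recent) / len(recent)
    return out


def contingency_ratio(p_left: float, p_right: float) -> float:
    """Relative left-side reward probability, p_left / (p_left + p_right).

    The matching reference plotted against the choice trace, e.g.
    60/(15+60) = 0.8 when the left port is the 60% port.
    """
    if p_left < 0 or p_right < 0:
        raise InvalidParameterError("probabilities must be nonnegative")
    if p_left + p_right == 0:
        raise InvalidParameterError("p_left + p_right must be positive")
    return p_left / (p_left + p_right)


# ---------------------------------------------------------------------------
# Per-subject metric table (feeds the group comparison)
# ---------------------------------------------------------------------------

def subject_metrics(sessions: Sequence[Session]) -> pd.DataFrame:
    """One row per subject: WSLS fractions and conditional ITI medians,
    pooled over the subject's sessions."""
    by_subject: Dict[str, List[Session]] = {}
    meta: Dict[str, Tuple[str, str]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject_id, []).append(s)
        meta[s.subject_id] = (s.genotype, s.sex)
    rows = []
    for sid, ss in by_subject.items():
        merged = Session(subject_id=sid, genotype=meta[sid][0],
                         sex=meta[sid][1], variant=ss[0].variant)
        offset = 0
        for s in ss:
            for t in s.trials:
                merged.trials.append(Trial(
                    index=offset + t.index, block_index=t.block_index,
                    high_side=t.high_side, choice=t.choice,
                    rewarded=t.rewarded, iti_s=t.iti_s,
                    nolick_duration_s=t.nolick_duration_s))
            offset += s.n_trials + 1       # gap: no WSLS pair across sessions
        w = wsls_fractions(merged)
        iti = conditional_iti(merged)
        rows.append({
            "subject_id": sid, "genotype": meta[sid][0], "sex": meta[sid][1],
            "win_stay": w.win_stay, "lose_switch": w.lose_switch,
            "iti_median_rewarded_s": iti.median_rewarded_s,
            "iti_median_unrewarded_s": iti.median_unrewarded_s,
        })
    return pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)
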