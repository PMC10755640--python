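"""Group-comparison statistics for behavioral metrics.

The study's inferential toolkit, implemented from first principles so every
sum of squares and rank statistic is auditable:

- mixed-design (split-plot) two-way ANOVA — one between-subject factor
  (genotype) crossed with one within-subject factor (training day or trial
  since reversal), subject nested in group as the between error term, no
  sphericity correction;
- Mann–Whitney U with midranks for ties, exact enumeration of the null
  distribution for small untied samples, and the tie- and
  continuity-corrected normal approximation otherwise;
- Bonferroni adjustment for the pairwise-comparison families.

All tests are two-sided; the package-wide significance level defaults to
``ALPHA = 0.05``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .task_engine import InvalidParameterError

ALPHA = 0.05


class MissingDataError(ValueError):
    """The design has empty or incomplete cells; no silent imputation."""


@dataclass
class RMAnovaResult:
    """Mixed-design ANOVA decomposition.

    ``between`` is the group main effect (tested against subject-within-
    group), ``within`` the repeated-factor main effect and ``interaction``
    the group-by-factor term (both tested against the residual).
    """

    F_between: float
    F_within: float
    F_interaction: float
    df_between: Tuple[int, int]
    df_within: Tuple[int, int]
    df_interaction: Tuple[int, int]
    p_between: float
    p_within: float
    p_interaction: float
    ss: Dict[str, float]


@dataclass
class MWUResult:
    U: float
    p_two_sided: float
    n1: int
    n2: int


# ---------------------------------------------------------------------------
# Mixed-design two-way ANOVA
# ---------------------------------------------------------------------------

def rm_two_way_anova(data, groups) -> RMAnovaResult:
    """Mixed two-way ANOVA on a subjects x within-levels matrix.

    Parameters
    ----------
    data
        Array of shape (n_subjects, n_levels); each row is one subject's
        measurements across the repeated factor.  Must be complete.
    groups
        Length-n_subjects labels assigning each subject to a between group.

    Sums of squares are the classical split-plot decomposition: total =
    group + subject(group) + level + group:level + residual.  F ratios use
    subject(group) as the error for the group effect and the residual for
    the within and interaction effects; p-values from the F distribution
    with no sphericity correction.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise InvalidParameterError("data must be 2-D (subjects x levels)")
    if np.isnan(x).any():
        raise MissingDataError("design contains missing cells")
    groups = np.asarray(groups)
    if groups.shape[0] != x.shape[0]:
        raise InvalidParameterError("one group label per subject required")
    levels = np.unique(groups)
    g, k = len(levels), x.shape[1]
    n_total = x.shape[0]
    if g < 2:
        raise InvalidParameterError("need >= 2 groups")
    if k < 2:
        raise InvalidParameterError("need >= 2 within levels")
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise MissingDataError(f"group {lev!r} has < 2 subjects")

    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    subj_means = x.mean(axis=1)
    ss_subjects = k * ((subj_means - grand) ** 2).sum()
    group_means = {lev: x[groups == lev].mean() for lev in levels}
    ss_group = k * sum((groups == lev).sum() * (group_means[lev] - grand) ** 2
                       for lev in levels)
    ss_subj_within = ss_subjects - ss_group
    level_means = x.mean(axis=0)
    ss_level = n_total * ((level_means - grand) ** 2).sum()
    ss_cells = sum(
        (groups == lev).sum() * ((x[groups == lev].mean(axis=0) - grand) ** 2).sum()
        for lev in levels)
    ss_interaction = ss_cells - ss_group - ss_level
    ss_resid = ss_total - ss_subjects - ss_level - ss_interaction

    df_group = g - 1
    df_subj_within = n_total - g
    df_level = k - 1
    df_inter = (g - 1) * (k - 1)
    df_resid = (n_total - g) * (k - 1)

    ms = {
        "group": ss_group / df_group,
        "subj_within": ss_subj_within / df_subj_within,
        "level": ss_level / df_level,
        "interaction": ss_interaction / df_inter,
        "resid": ss_resid / df_resid,
    }
    f_between = ms["group"] / ms["subj_within"]
    f_within = ms["level"] / ms["resid"]
    f_inter = ms["interaction"] / ms["resid"]
    return RMAnovaResult(
        F_between=float(f_between), F_within=float(f_within),
        F_interaction=float(f_inter),
        df_between=(df_group, df_subj_within),
        df_within=(df_level, df_resid),
        df_interaction=(df_inter, df_resid),
        p_between=float(sps.f.sf(f_between, df_group, df_subj_within)),
        p_within=float(sps.f.sf(f_within, df_level, df_resid)),
        p_interaction=float(sps.f.sf(f_inter, df_inter, df_resid)),
        ss={"group": float(ss_group), "subj_within": float(ss_subj_within),
            "level": float(ss_level), "interaction": float(ss_interaction),
            "resid": float(ss_resid), "total": float(ss_total)},
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def _mwu_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements giving each U value, u = 0..n1*n2.

    Dynamic program over the pooled ranks 1..n1+n2: dp[j, s] counts the
    ways to pick j ranks for the first sample with rank sum s; U follows
    by subtracting the minimal rank sum n1(n1+1)/2.  Cached per (n1, n2);
    callers must not mutate the returned array.
    """
    n = n1 + n2
    max_sum = n1 * n + 1                   # loose upper bound on rank sums
    dp = np.zeros((n1 + 1, max_sum), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for j in range(min(r, n1), 0, -1):
            dp[j, r:] += dp[j - 1, :-r]
    offset = n1 * (n1 + 1) // 2
    return dp[n1, offset:offset + n1 * n2 + 1].copy()


def mann_whitney_u(x, y, exact_max_n: int = 8) -> MWUResult:
    """Two-sided Mann-Whitney U test.

    U is the statistic of the first sample (rank sum of ``x`` minus its
    minimum).  The p-value is exact — full enumeration of the null rank
    distribution — when ``min(n1, n2) <= exact_max_n`` and the pooled data
    are tie-free; otherwise the normal approximation with tie correction
    and a 0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise InvalidParameterError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)           # midranks for ties
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if min(n1, n2) <= exact_max_n and not has_ties:
        cdf = np.cumsum(_mwu_counts(n1, n2))
        cdf /= cdf[-1]
        u_min = int(round(min(u1, u2)))
        p = min(1.0, 2.0 * cdf[u_min])
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:                    # all observations identical
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * sps.norm.sf(z))
    return MWUResult(U=float(u1), p_two_sided=float(p), n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------

def bonferroni(p_values: Sequence[float], m: Optional[int] = None
               ) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * m).

    ``m`` defaults to the family size ``len(p_values)`` and must be at
    least that large.
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise InvalidParameterError("m must be >= number of p-values")
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# Metric-family comparison (the Fig. 2E/2F scheme)
# ---------------------------------------------------------------------------

def compare_metric_tables(table_a, table_b,
                          metrics: Optional[Sequence[str]] = None,
                          alpha: float = ALPHA) -> Dict:
    """Pairwise Mann-Whitney tests with Bonferroni correction across a
    family of per-subject metrics.

    ``table_a`` / ``table_b`` are per-subject metric DataFrames (one row
    per subject) for the two groups; ``metrics`` names the numeric columns
    to compare (default: every shared numeric metric column).  Returns a
    report dict with per-metric U, raw and adjusted p, and the family-wise
    conclusion at ``alpha``.
    """
    skip = {"subject_id", "genotype", "sex"}
    if metrics is None:
        metrics = [c for c in table_a.columns
                   if c in table_b.columns and c not in skip
                   and np.issubdtype(table_a[c].dtype, np.number)]
    results = {}
    raw_ps = []
    for mname in metrics:
        a = np.asarray(table_a[mname].dropna(), dtype=float)
        b = np.asarray(table_b[mname].dropna(), dtype=float)
        res = mann_whitney_u(a, b)
        results[mname] = {"U": res.U, "p": res.p_two_sided,
                          "n1": res.n1, "n2": res.n2}
        raw_ps.append(res.p_two_sided)
    adj = bonferroni(raw_ps, m=len(metrics))
    for mname, p_adj in zip(metrics, adj):
        results[mname]["p_adjusted"] = float(p_adj)
        results[mname]["significant"] = bool(p_adj < alpha)
    return {
        "alpha": alpha,
        "m": len(metrics),
        "metrics": results,
        "any_significant": bool((adj < alpha).any()) if len(metrics) else False,
    }
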