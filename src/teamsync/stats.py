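"""Group comparisons across opposition levels.

One-way fixed-effects ANOVA with partial eta-squared, Fisher's LSD pairwise
tests on the pooled error term, and Cohen's d with a large-sample 95%
confidence interval:

    d  = (mean_a - mean_b) / s_pooled
    se = sqrt((n_a + n_b)/(n_a * n_b) + d^2 / (2 (n_a + n_b - 2)))
    CI = d +/- 1.96 se

Pairs are reported with the higher-ranked opposition level first, so a
positive d means the outcome was larger against the stronger opponent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PairwiseEffect",
    "one_way_anova",
    "lsd_pairwise",
    "cohens_d_ci",
    "LEVEL_RANK",
]

# canonical ordering: stronger opposition first
LEVEL_RANK = {"first_league": 0, "second_league": 1, "amateur": 2}


@dataclass
class AnovaResult:
    outcome: str
    F: float
    df_between: int
    df_within: int
    p: float
    partial_eta_sq: float
    ms_error: float
    group_means: dict
    group_ns: dict


@dataclass
class PairwiseEffect:
    level_a: str
    level_b: str
    mean_diff: float
    lsd_p: float
    d: float
    d_ci_low: float
    d_ci_high: float


def _ordered_levels(levels):
    return sorted(levels, key=lambda s: (LEVEL_RANK.get(s, 99), s))


def one_way_anova(groups: dict[str, np.ndarray], outcome: str = "") -> AnovaResult:
    """Classical one-way ANOVA with partial eta-squared.

    ``groups`` maps level name -> observations. Partial eta-squared is
    SS_effect / (SS_effect + SS_error), which for a one-way design equals
    plain eta-squared.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrs.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        if np.any(~np.isfinite(v)):
            raise ValueError(f"group {g!r} contains non-finite values")
    allv = np.concatenate(list(arrs.values()))
    if np.ptp(allv) < 1e-300:
        raise ValueError("zero total variance: ANOVA undefined")
    grand = allv.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in arrs.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrs.values())
    df_b = len(arrs) - 1
    df_w = len(allv) - len(arrs)
    if ss_within <= 0:
        raise ValueError("zero within-group variance: F undefined")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    F = ms_b / ms_w
    return AnovaResult(
        outcome=outcome,
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=float(sps.f.sf(F, df_b, df_w)),
        partial_eta_sq=float(ss_between / (ss_between + ss_within)),
        ms_error=float(ms_w),
        group_means={g: float(v.mean()) for g, v in arrs.items()},
        group_ns={g: int(len(v)) for g, v in arrs.items()},
    )


def cohens_d_ci(a, b, conf_z: float = 1.96) -> tuple[float, float, float]:
    """Cohen's d (pooled SD) with a large-sample normal CI.

    Returns ``(d, ci_low, ci_high)``; swapping the groups negates d and
    reflects the interval.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 observations per group")
    s_pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if s_pooled <= 0:
        raise ValueError("zero pooled variance: d undefined")
    d = (a.mean() - b.mean()) / s_pooled
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2.0 * (na + nb - 2)))
    return float(d), float(d - conf_z * se), float(d + conf_z * se)


def lsd_pairwise(
    groups: dict[str, np.ndarray], anova: AnovaResult
) -> list[PairwiseEffect]:
    """Fisher's LSD pairwise t-tests plus Cohen's d per pair.

    Each t uses the ANOVA's pooled MS_error and error df; p-values are
    unadjusted, per the LSD convention. Pairs are ordered with the
    higher-ranked opposition level first.
    """
    arrs = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    levels = _ordered_levels(arrs)
    out = []
    for la, lb in combinations(levels, 2):
        va, vb = arrs[la], arrs[lb]
        diff = va.mean() - vb.mean()
        se = np.sqrt(anova.ms_error * (1.0 / len(va) + 1.0 / len(vb)))
        t = diff / se
        p = 2.0 * sps.t.sf(abs(t), anova.df_within)
        d, lo, hi = cohens_d_ci(va, vb)
        out.append(PairwiseEffect(
            level_a=la, level_b=lb, mean_diff=float(diff),
            lsd_p=float(p), d=d, d_ci_low=lo, d_ci_high=hi,
        ))
    return out
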