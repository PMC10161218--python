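"""Group comparisons and error propagation for derived quantities.

One-way ANOVA with a post-hoc Tukey HSD test compares per-cell measurements
(colocalization shares, mobile fractions, dG37 values) across groups; the
Tukey step uses the Tukey-Kramer form so unequal group sizes are handled.
Gaussian (first-order) error propagation converts the (T_m, g1) fit
covariance into the standard deviation of dG37 = (310 - T_m)*g1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from .thermo import MeltingParameters, T_REF

__all__ = ["GroupSummary", "AnovaResult", "summarize_groups", "one_way_anova",
           "tukey_hsd", "gaussian_error_prop"]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


def summarize_groups(groups, labels=None) -> pd.DataFrame:
    """Per-group n / mean / SD table (mean +/- SD convention)."""
    labels = labels or [f"group{i}" for i in range(len(groups))]
    rows = [GroupSummary(lab, len(g), float(np.mean(g)), float(np.std(g, ddof=1)))
            for lab, g in zip(labels, groups)]
    return pd.DataFrame([r.__dict__ for r in rows])


def _validate(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    return groups


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


def one_way_anova(groups) -> AnovaResult:
    """Standard one-way ANOVA decomposition.

    Degenerate zero within-group variance with distinct means is reported
    as F = inf, p = 0.
    """
    groups = _validate(groups)
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, df_b, df_w)
        return AnovaResult(np.inf, 0.0, df_b, df_w)
    F = ms_between / ms_within
    return AnovaResult(float(F), float(f_dist.sf(F, df_b, df_w)), df_b, df_w)


def tukey_hsd(groups, labels=None) -> pd.DataFrame:
    """Tukey(-Kramer) HSD pairwise comparisons.

    For groups i, j the studentized-range statistic is
    q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) with MSW the pooled
    within-group mean square, and the family-wise adjusted p-value is the
    survival function of the studentized-range distribution with k groups
    and the within-group degrees of freedom.
    """
    groups = _validate(groups)
    labels = labels or [f"group{i}" for i in range(len(groups))]
    k = len(groups)
    df_w = sum(len(g) for g in groups) - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
    rows = []
    for i, j in combinations(range(k), 2):
        diff = float(groups[i].mean() - groups[j].mean())
        se = np.sqrt(msw / 2.0 * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else np.inf
            p = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p = float(studentized_range.sf(q, k, df_w))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "mean_diff": diff, "q": float(q), "p_adj": p})
    return pd.DataFrame(rows)


def gaussian_error_prop(params: MeltingParameters) -> float:
    """SD of dG37 = (310 - T_m)*g1 by first-order error propagation.

    With partial derivatives d(dG37)/dT_m = -g1 and d(dG37)/dg1 = 310 - T_m:

    sigma^2 = (g1*sigma_Tm)^2 + ((310 - T_m)*sigma_g1)^2
              - 2*g1*(310 - T_m)*cov(T_m, g1)

    A pathological covariance driving the variance negative raises.
    """
    dt = T_REF - params.tm
    var = ((params.g1 * params.sigma_tm) ** 2 + (dt * params.sigma_g1) ** 2
           - 2.0 * params.g1 * dt * params.cov_tm_g1)
    if var < 0:
        raise ValueError(f"covariance-inconsistent variance {var:.3g} < 0")
    return float(np.sqrt(var))
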