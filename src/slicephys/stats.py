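"""Cohort-level statistics: QC filtering, feature-vs-time regression and
two-group comparisons.

The statistical battery mirrors a common ex vivo slice-physiology design:
ordinary least squares with Pearson r² for features against hours
post-slicing, Welch's unequal-variance t-test for parametric two-group
contrasts, and the Mann-Whitney U test (medians reported) for
non-parametric contrasts.  p-values are reported raw: no multiple-testing
correction is applied, and reports say so prominently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import FeatureRow, ValidationError

#: Inclusion criteria: resting potential more negative than this (mV) and at
#: least one AP whose peak exceeds the overshoot level (mV).
QC_RMP_MAX_MV = -50.0
QC_OVERSHOOT_MV = 0.0


@dataclass
class RegressionResult:
    """OLS fit of a feature against hours post-slicing."""

    feature: str
    slope: float          # feature units per hour
    intercept: float
    r_squared: float      # squared Pearson correlation
    p_value: float        # two-sided, H0: slope = 0
    n: int

    def to_dict(self) -> dict:
        return {
            "analysis": "regression_vs_time", "feature": self.feature,
            "slope_per_hour": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "p_value": self.p_value, "n": self.n,
        }


@dataclass
class GroupComparison:
    """Two-group comparison result (Welch t or Mann-Whitney U)."""

    feature: str
    test: str                     # "welch_t" | "mann_whitney_u"
    group_labels: tuple[str, str]
    n: tuple[int, int]
    location: tuple[float, float]   # means (Welch) or medians (MWU)
    dispersion: tuple[float, float]  # SEMs (Welch) or IQRs (MWU)
    statistic: float
    p_value: float
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "analysis": "group_comparison", "feature": self.feature,
            "test": self.test, "groups": list(self.group_labels),
            "n": list(self.n), "location": list(self.location),
            "dispersion": list(self.dispersion),
            "statistic": self.statistic, "p_value": self.p_value,
            **self.extra,
        }


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def apply_inclusion_filter(rows: list[FeatureRow]
                           ) -> tuple[list[FeatureRow], list[dict]]:
    """Apply the health inclusion criteria to a cohort.

    A neuron passes when its RMP is more negative than −50 mV AND at least
    one detected AP peak overshoots 0 mV.  Returns the passing rows (with
    ``qc_pass`` set on every row) and a rejection log naming the violated
    criterion (or criteria) per excluded neuron.
    """
    passing: list[FeatureRow] = []
    log: list[dict] = []
    for row in rows:
        reasons = []
        if row.rmp_mv is None or not row.rmp_mv < QC_RMP_MAX_MV:
            reasons.append(f"rmp_not_below_{QC_RMP_MAX_MV:g}mV")
        if row.max_ap_peak_mv is None or not row.max_ap_peak_mv > QC_OVERSHOOT_MV:
            reasons.append(f"no_ap_overshoot_above_{QC_OVERSHOOT_MV:g}mV")
        row.qc_pass = not reasons
        if reasons:
            log.append({"neuron_id": row.neuron_id, "reasons": reasons})
        else:
            passing.append(row)
    return passing, log


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def feature_vs_time(df: pd.DataFrame, feature: str,
                    hours_col: str = "hours_post_slicing") -> RegressionResult:
    """OLS of a feature on hours post-slicing; r² is the squared Pearson r."""
    if feature not in df.columns:
        raise ValidationError(f"unknown feature {feature!r}")
    sub = df[[hours_col, feature]].dropna()
    if len(sub) < 3:
        raise ValidationError(
            f"feature {feature}: need >= 3 rows with hours and feature present, "
            f"got {len(sub)}"
        )
    res = sps.linregress(sub[hours_col].to_numpy(), sub[feature].to_numpy())
    return RegressionResult(
        feature=feature, slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), p_value=float(res.pvalue), n=len(sub),
    )


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _clean(sample) -> np.ndarray:
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValidationError("each group needs >= 2 finite values")
    return x


def welch_t(a, b, feature: str = "", labels: tuple[str, str] = ("a", "b")
            ) -> GroupComparison:
    """Unpaired t-test with Welch's correction (Welch–Satterthwaite df).

    Degenerate case: when both groups have zero variance and equal means the
    statistic is 0 and p = 1 by convention (flagged in ``extra``).
    """
    a, b = _clean(a), _clean(b)
    extra: dict = {}
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            stat, p = 0.0, 1.0
            extra["degenerate"] = "zero variance in both groups, equal means"
        else:
            stat, p = np.inf, 0.0
            extra["degenerate"] = "zero variance in both groups, unequal means"
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(x.size))  # noqa: E731
    return GroupComparison(
        feature=feature, test="welch_t", group_labels=labels,
        n=(a.size, b.size), location=(float(np.mean(a)), float(np.mean(b))),
        dispersion=(sem(a), sem(b)), statistic=stat, p_value=p, extra=extra,
    )


def _pair_count_u(a: np.ndarray, b: np.ndarray) -> float:
    """U_ab = #{(i,j): a_i < b_j} + ½·#ties, via midranks (vectorized)."""
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r_a = float(np.sum(ranks[: a.size]))
    n1, n2 = a.size, b.size
    # rank-sum identity: U_ba (#a>b + ½ ties) = R_a − n1(n1+1)/2
    u_ba = r_a - n1 * (n1 + 1) / 2.0
    return n1 * n2 - u_ba


def mann_whitney_u(a, b, feature: str = "", labels: tuple[str, str] = ("a", "b")
                   ) -> GroupComparison:
    """Mann-Whitney U test; medians reported.

    ``u_ab`` counts pairs with a < b (½ per tie), ``u_ba`` the reverse; the
    reported statistic is min(u_ab, u_ba).  The two-sided p-value is exact
    when the smaller group has ≤ 8 observations and there are no ties,
    otherwise the normal approximation with tie correction is used.
    """
    a, b = _clean(a), _clean(b)
    u_ab = _pair_count_u(a, b)
    u_ba = a.size * b.size - u_ab
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    iqr = lambda x: float(np.subtract(*np.percentile(x, [75, 25])))  # noqa: E731
    return GroupComparison(
        feature=feature, test="mann_whitney_u", group_labels=labels,
        n=(a.size, b.size),
        location=(float(np.median(a)), float(np.median(b))),
        dispersion=(iqr(a), iqr(b)),
        statistic=float(min(u_ab, u_ba)), p_value=float(res.pvalue),
        extra={"u_ab": u_ab, "u_ba": u_ba, "p_method": method},
    )
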