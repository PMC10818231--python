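"""Agreement and comparison statistics for competing fraud classifiers.

Two binary classifiers over the same responses are compared through a
2x2 confusion matrix and Cohen's kappa,

    kappa = (p_o - p_e) / (1 - p_e),

where p_o is the observed agreement fraction and p_e the chance
agreement expected from the marginals.  The kappa standard error uses

    SE = sqrt( p_o (1 - p_o) / ( n (1 - p_e)^2 ) ),

with a normal-approximation confidence interval kappa +/- z * SE.  Two
conventional qualitative scales are reported alongside: the Landis-Koch
bands (slight/fair/moderate/substantial/almost perfect) and the McHugh
bands (none/minimal/weak/moderate/strong/almost perfect).

Covariate comparisons between fraud- and valid-labeled groups delegate
to scipy: Pearson chi-square for categorical variables, Welch's t for
normally distributed continuous variables, and the Mann-Whitney U test
otherwise (exact enumeration for pooled n <= 10, tie-corrected normal
approximation above).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import DataError, Label

_LANDIS_KOCH = [
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
]
_MCHUGH = [
    (0.20, "none"),
    (0.39, "minimal"),
    (0.59, "weak"),
    (0.79, "moderate"),
    (0.90, "strong"),
    (1.0, "almost perfect"),
]


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Joint classification counts of two binary fraud classifiers.

    a: both fraud; b: A fraud / B valid; c: A valid / B fraud;
    d: both valid.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion cells must be nonnegative")
        if self.n == 0:
            raise ValueError("confusion matrix must contain at least one response")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its normal-approximation confidence interval."""

    po: float
    pe: float
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95


@dataclass(frozen=True)
class SubgroupEstimate:
    """Subgroup mean with a z-based (normal-approximation) CI."""

    group: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class GroupComparison:
    """One covariate's fraud-vs-valid test statistic and p value."""

    variable: str
    test: str  # chi_square | t_test | mann_whitney
    statistic: float
    p_value: float


def build_confusion(
    labels_a: Mapping[str, Label], labels_b: Mapping[str, Label]
) -> ConfusionMatrix2x2:
    """Cross-classify two label maps defined over identical response ids."""
    if set(labels_a) != set(labels_b):
        diff = sorted(set(labels_a) ^ set(labels_b))
        raise DataError(f"label maps cover different responses: {diff[:10]}")
    a = b = c = d = 0
    for rid, la in labels_a.items():
        lb = labels_b[rid]
        if la is Label.FRAUD:
            if lb is Label.FRAUD:
                a += 1
            else:
                b += 1
        elif lb is Label.FRAUD:
            c += 1
        else:
            d += 1
    return ConfusionMatrix2x2(a, b, c, d)


def cohen_kappa(cm: ConfusionMatrix2x2, confidence: float = 0.95) -> KappaResult:
    """Cohen's kappa with SE = sqrt(po(1-po) / (n (1-pe)^2)) and a z CI."""
    n = cm.n
    po = (cm.a + cm.d) / n
    pe = ((cm.a + cm.b) / n) * ((cm.a + cm.c) / n) + (
        (cm.c + cm.d) / n
    ) * ((cm.b + cm.d) / n)
    if pe >= 1.0:
        raise DataError("kappa undefined: chance agreement pe = 1 (degenerate marginals)")
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return KappaResult(
        po=po, pe=pe, kappa=kappa, se=se,
        ci_low=kappa - z * se, ci_high=kappa + z * se,
        confidence=confidence,
    )


def interpret_kappa(kappa: float) -> Tuple[str, str]:
    """Qualitative (Landis-Koch, McHugh) agreement bands for a kappa value."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1]; got {kappa}")

    def band(scale, value):
        for cut, name in scale:
            if value <= cut:
                return name
        return scale[-1][1]

    lk = "poor" if kappa < 0 else band(_LANDIS_KOCH[1:], kappa)
    return lk, band(_MCHUGH, kappa)


def mean_ci_normal(
    mean: float, sd: float, n: int, confidence: float = 0.95, group: str = ""
) -> SubgroupEstimate:
    """Normal-approximation CI: mean +/- z * sd / sqrt(n) (z = 1.96 at 95%)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    half = z * sd / math.sqrt(n)
    return SubgroupEstimate(group=group, n=n, mean=mean, sd=sd,
                            ci_low=mean - half, ci_high=mean + half)


def chi_square_test(
    table: Sequence[Sequence[float]], variable: str = "", yates: bool = False
) -> GroupComparison:
    """Pearson chi-square test of independence on a 2 x k count table."""
    obs = np.asarray(table, dtype=float)
    expected = stats.contingency.expected_freq(obs)
    if (expected <= 0).any():
        raise DataError(
            f"chi-square for {variable or 'table'}: zero expected cell; merge categories"
        )
    stat, p, _, _ = stats.chi2_contingency(obs, correction=yates)
    return GroupComparison(variable=variable, test="chi_square",
                           statistic=float(stat), p_value=float(p))


def t_test(x: Sequence[float], y: Sequence[float], variable: str = "") -> GroupComparison:
    """Welch two-sample t test, two-sided."""
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t_test requires >= 2 observations per group")
    res = stats.ttest_ind(x, y, equal_var=False)
    return GroupComparison(variable=variable, test="t_test",
                           statistic=float(res.statistic), p_value=float(res.pvalue))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], variable: str = ""
) -> GroupComparison:
    """Mann-Whitney U test, two-sided.

    For pooled samples of 10 or fewer, the exact permutation distribution
    of U is enumerated directly (ties handled through midranks); larger
    samples use the tie-corrected normal approximation with continuity
    correction.
    """
    if not len(x) or not len(y):
        raise ValueError("mann_whitney requires nonempty samples")
    nx, ny = len(x), len(y)
    if nx + ny <= 10:
        u, p = _mann_whitney_exact(list(x), list(y))
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(variable=variable, test="mann_whitney",
                           statistic=u, p_value=min(p, 1.0))


def _u_statistic(pooled: np.ndarray, idx_x: Tuple[int, ...]) -> float:
    ranks = stats.rankdata(pooled)
    nx = len(idx_x)
    rank_sum = ranks[list(idx_x)].sum()
    return rank_sum - nx * (nx + 1) / 2.0


def _mann_whitney_exact(x: List[float], y: List[float]) -> Tuple[float, float]:
    """Full enumeration of U over all assignments of the pooled sample."""
    pooled = np.asarray(x + y, dtype=float)
    nx = len(x)
    mu = nx * len(y) / 2.0
    u_obs = _u_statistic(pooled, tuple(range(nx)))
    dist = [
        _u_statistic(pooled, idx) for idx in combinations(range(len(pooled)), nx)
    ]
    extreme = sum(1 for u in dist if abs(u - mu) >= abs(u_obs - mu) - 1e-12)
    return u_obs, extreme / len(dist)


def fraud_proportion_series(
    timestamps: Mapping[str, pd.Timestamp],
    labels_by_method: Mapping[str, Mapping[str, Label]],
    window_days: int = 7,
) -> pd.DataFrame:
    """Daily fraud proportion per method over a centered moving window.

    Returns a DataFrame indexed by calendar day spanning the observed
    period, one column per method; a day whose window contains no
    responses yields NaN.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    idx = pd.DataFrame(
        {"date": pd.to_datetime([timestamps[rid] for rid in timestamps]).normalize()},
        index=list(timestamps),
    )
    days = pd.date_range(idx["date"].min(), idx["date"].max(), freq="D")
    out = {}
    for method, labels in labels_by_method.items():
        frame = idx.copy()
        frame["fraud"] = [labels[rid] is Label.FRAUD for rid in frame.index]
        daily = frame.groupby("date")["fraud"].agg(["sum", "count"]).reindex(days, fill_value=0)
        rolled = daily.rolling(window=window_days, center=True, min_periods=1).sum()
        out[method] = rolled["sum"] / rolled["count"].replace(0, np.nan)
    result = pd.DataFrame(out, index=days)
    result.index.name = "date"
    return result


def evaluate_by_subgroup(
    values: Mapping[str, float],
    groups: Mapping[str, str],
    confidence: float = 0.95,
) -> List[SubgroupEstimate]:
    """Per-group mean of a binary/continuous outcome with normal CIs."""
    frame = pd.DataFrame(
        {"value": pd.Series(values, dtype=float), "group": pd.Series(groups)}
    ).dropna()
    estimates = []
    for group, sub in frame.groupby("group", sort=True):
        v = sub["value"].to_numpy()
        estimates.append(
            mean_ci_normal(float(v.mean()), float(v.std(ddof=0)), len(v),
                           confidence, group=str(group))
        )
    return estimates
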