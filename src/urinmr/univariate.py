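"""Assumption-routed two-group testing of each metabolite.

Each variable is checked for normality (Shapiro–Wilk per group) and
homoscedasticity (median-centered Levene across groups) at a configurable
assumption level; when both groups pass both checks the equal-variance
two-sample t-test is used, otherwise the Wilcoxon rank-sum test (exact
when both groups have n ≤ 10 and no ties, else the normal approximation
with tie correction and continuity correction). Two-sided p-values,
significance at the 95% confidence level, direction from group medians.
Benjamini–Hochberg adjusted p-values are emitted alongside for
transparency but do not gate significance by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GROUP_CONTROL, GROUP_EXPOSED, ConcentrationMatrix

ALPHA_DEFAULT = 0.05


@dataclass
class UnivariateResult:
    metabolite: str
    test_used: str                     # "t" | "wilcoxon"
    statistic: float
    p_value: float
    direction: str                     # "up_in_exposed" | "down_in_exposed"
    significant: bool
    adjusted_p: float | None = None
    degenerate: bool = False           # constant data in both groups


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:                 # constant sample: not testably normal
        return False
    return stats.shapiro(x).pvalue >= alpha


def _is_homoscedastic(x: np.ndarray, y: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return True
    return stats.levene(x, y, center="median").pvalue >= alpha


def route_and_test(
    x_ctrl: np.ndarray,
    x_exposed: np.ndarray,
    alpha_assumptions: float = ALPHA_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    metabolite: str = "",
) -> UnivariateResult:
    """Assumption checks route one variable to a t-test or rank-sum test."""
    x_ctrl = np.asarray(x_ctrl, dtype=float)
    x_exposed = np.asarray(x_exposed, dtype=float)
    if x_ctrl.size < 3 or x_exposed.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.isnan(x_ctrl).any() or np.isnan(x_exposed).any():
        raise ValueError("missing values are not allowed")

    med_diff = np.median(x_exposed) - np.median(x_ctrl)
    if med_diff == 0:
        med_diff = x_exposed.mean() - x_ctrl.mean()
    direction = "up_in_exposed" if med_diff > 0 else "down_in_exposed"

    pooled = np.concatenate([x_ctrl, x_exposed])
    if np.ptp(pooled) == 0:            # test undefined on constant data
        return UnivariateResult(metabolite, "wilcoxon", 0.0, 1.0, direction,
                                False, degenerate=True)

    normal = (_is_normal(x_ctrl, alpha_assumptions)
              and _is_normal(x_exposed, alpha_assumptions))
    homoscedastic = _is_homoscedastic(x_ctrl, x_exposed, alpha_assumptions)

    if normal and homoscedastic:
        res = stats.ttest_ind(x_exposed, x_ctrl, equal_var=True)
        test_used, stat, p = "t", float(res.statistic), float(res.pvalue)
    else:
        has_ties = np.unique(pooled).size < pooled.size
        method = ("exact" if x_ctrl.size <= 10 and x_exposed.size <= 10
                  and not has_ties else "asymptotic")
        res = stats.mannwhitneyu(x_exposed, x_ctrl, alternative="two-sided",
                                 method=method, use_continuity=True)
        test_used, stat, p = "wilcoxon", float(res.statistic), float(res.pvalue)

    return UnivariateResult(metabolite, test_used, stat, p, direction,
                            significant=bool(p < alpha))


@dataclass
class UnivariateReport:
    results: list[UnivariateResult]

    @property
    def n_significant_up(self) -> int:
        return sum(r.significant and r.direction == "up_in_exposed"
                   for r in self.results)

    @property
    def n_significant_down(self) -> int:
        return sum(r.significant and r.direction == "down_in_exposed"
                   for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "metabolite": r.metabolite,
            "test_used": r.test_used,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "adjusted_p": r.adjusted_p,
            "direction": r.direction,
            "significant": r.significant,
        } for r in self.results]).set_index("metabolite")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def run_univariate(matrix: ConcentrationMatrix,
                   alpha_assumptions: float = ALPHA_DEFAULT,
                   alpha: float = ALPHA_DEFAULT) -> UnivariateReport:
    """Route-and-test every metabolite column, preserving column order.

    Benjamini–Hochberg adjusted p-values are attached to every result.
    """
    groups = matrix.groups
    present = set(groups.unique())
    if present != {GROUP_CONTROL, GROUP_EXPOSED}:
        raise ValueError(f"need both groups present, found {sorted(present)}")
    ctrl = matrix.values[groups == GROUP_CONTROL]
    expo = matrix.values[groups == GROUP_EXPOSED]
    results = [
        route_and_test(ctrl[m].to_numpy(), expo[m].to_numpy(),
                       alpha_assumptions=alpha_assumptions, alpha=alpha,
                       metabolite=m)
        for m in matrix.metabolites
    ]
    adjusted = stats.false_discovery_control(
        np.array([r.p_value for r in results]), method="bh")
    for r, ap in zip(results, adjusted):
        r.adjusted_p = float(ap)
    return UnivariateReport(results=results)
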