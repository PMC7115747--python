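"""Statistical tests on distance statistics and band/analyte data.

One-way ANOVA, Tukey HSD pairwise comparisons, ordinary least-squares
regression and Pearson correlation — the tests applied downstream of
the TPD/TSD/TCD reduction.  F statistics come from the classical sums
of squares; p-values from ``scipy.stats`` reference distributions
(``f``, ``studentized_range``); regression and correlation are thin
wrappers over ``scipy.stats.linregress`` / ``pearsonr``.  An optional
additive two-way layout (condition + replicate, no interaction) is
provided through statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .errors import InputError

ALPHA = 0.05  # threshold used only for summary significance flags


@dataclass(frozen=True)
class AnovaResult:
    factor: str
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False  # zero within-group variance

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass
class PairwiseResult:
    """Tukey HSD table: one row per unordered group pair."""

    table: pd.DataFrame  # columns: group1, group2, mean_diff, q, p_adj
    ms_within: float
    df_within: int

    def p(self, a, b) -> float:
        t = self.table
        row = t[((t.group1 == a) & (t.group2 == b)) | ((t.group1 == b) & (t.group2 == a))]
        if row.empty:
            raise InputError(f"no pair ({a!r}, {b!r}) in the Tukey table")
        return float(row.p_adj.iloc[0])


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p: float
    stderr: float


def _split_groups(values, groups):
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise InputError("values and groups must have equal length")
    levels = sorted(set(groups.tolist()))
    parts = [values[groups == g] for g in levels]
    if len(parts) < 2:
        raise InputError("need at least 2 groups")
    for g, part in zip(levels, parts):
        if part.size < 2:
            raise InputError(f"group {g!r} has fewer than 2 values")
    return levels, parts


def _sums_of_squares(parts):
    all_vals = np.concatenate(parts)
    grand = all_vals.mean()
    ssb = sum(p.size * (p.mean() - grand) ** 2 for p in parts)
    ssw = sum(float(np.sum((p - p.mean()) ** 2)) for p in parts)
    dfb = len(parts) - 1
    dfw = all_vals.size - len(parts)
    return ssb, ssw, dfb, dfw


def one_way_anova(values, groups, factor: str = "condition") -> AnovaResult:
    """Classical one-way F test.

    With zero within-group variance the result is flagged ``degenerate``
    and reported as ``F = inf, p = 0`` (the p-value is then only a
    machine-epsilon bound, not an exact tail probability).
    """
    _, parts = _split_groups(values, groups)
    ssb, ssw, dfb, dfw = _sums_of_squares(parts)
    msb = ssb / dfb
    msw = ssw / dfw
    if msw == 0.0:
        if msb == 0.0:  # all values identical everywhere
            return AnovaResult(factor, 0.0, dfb, dfw, 1.0, degenerate=True)
        return AnovaResult(factor, float("inf"), dfb, dfw, 0.0, degenerate=True)
    F = msb / msw
    p = float(scipy.stats.f.sf(F, dfb, dfw))
    return AnovaResult(factor, float(F), dfb, dfw, p, degenerate=False)


def tukey_hsd(values, groups) -> PairwiseResult:
    """Tukey's honest significant difference over all group pairs.

    ``q = |Δmean| / sqrt(MSW/2 · (1/n_i + 1/n_j))`` with the pooled
    within-group mean square; adjusted p from the studentized range
    distribution with ``k`` groups and the within dof (Tukey–Kramer for
    unequal sizes).
    """
    levels, parts = _split_groups(values, groups)
    _, ssw, _, dfw = _sums_of_squares(parts)
    msw = ssw / dfw
    k = len(levels)
    rows = []
    for (i, a), (j, b) in combinations(enumerate(levels), 2):
        diff = parts[i].mean() - parts[j].mean()
        se = np.sqrt(msw / 2.0 * (1.0 / parts[i].size + 1.0 / parts[j].size))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else float("inf")
            p = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p = float(np.clip(scipy.stats.studentized_range.sf(q, k, dfw), 0.0, 1.0))
        rows.append(
            {"group1": a, "group2": b, "mean_diff": float(diff), "q": float(q), "p_adj": p}
        )
    return PairwiseResult(table=pd.DataFrame(rows), ms_within=float(msw), df_within=dfw)


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x``; R is the Pearson
    correlation, R² its square."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    if x.size < 3:
        raise InputError("regression needs at least 3 points")
    if np.ptp(x) == 0.0:
        raise InputError("x is constant; slope undefined")
    if np.ptp(y) == 0.0:
        # a flat response: zero slope, correlation defined as 0
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r=0.0, r_squared=0.0,
            p=1.0, stderr=0.0,
        )
    res = scipy.stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        p=float(res.pvalue),
        stderr=float(res.stderr),
    )


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient in [−1, 1]."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    if x.size < 3:
        raise InputError("correlation needs at least 3 points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise InputError("correlation undefined for a constant input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def two_way_anova_additive(values, condition, replicate) -> list[AnovaResult]:
    """Additive two-factor ANOVA (condition + replicate, no interaction).

    Type-II sums of squares via statsmodels OLS; returns one
    :class:`AnovaResult` per factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "value": np.asarray(values, float),
            "condition": np.asarray(condition).astype(str),
            "replicate": np.asarray(replicate).astype(str),
        }
    )
    if df["condition"].nunique() < 2:
        raise InputError("need at least 2 condition levels")
    model = smf.ols("value ~ C(condition) + C(replicate)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    dfw = int(table.loc["Residual", "df"])
    out = []
    for factor, label in (("C(condition)", "condition"), ("C(replicate)", "replicate")):
        out.append(
            AnovaResult(
                factor=label,
                F=float(table.loc[factor, "F"]),
                df_between=int(table.loc[factor, "df"]),
                df_within=dfw,
                p=float(table.loc[factor, "PR(>F)"]),
            )
        )
    return out
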