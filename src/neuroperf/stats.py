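"""The study's statistical layer.

Covers the a-priori sample-size computation (noncentral-F power of a
fixed-effect omnibus one-way ANOVA), summary-statistic unpaired t-tests,
Shapiro-Wilk normality, fixed-effects two-way ANOVA with interaction
(Type III sums of squares, sum-to-zero contrasts, so unbalanced cells
are handled the way standard GUI statistics packages do), and
Tukey/Tukey-Kramer adjusted pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
from statsmodels.formula.api import ols


@dataclass(frozen=True)
class PowerSpec:
    """Design of a one-way ANOVA power computation.

    ``effect_f`` is Cohen's f (between-group SD over within-group SD);
    the noncentrality of the F test is f^2 times the total sample size.
    """

    k_groups: int = 4
    effect_f: float = 0.72
    alpha: float = 0.05
    target_power: float = 0.8

    def __post_init__(self) -> None:
        if self.k_groups < 2:
            raise ValueError("need >= 2 groups")
        if self.effect_f <= 0:
            raise ValueError("effect size must be > 0")
        if not 0 < self.alpha < 1 or not 0 < self.target_power < 1:
            raise ValueError("alpha and target power must lie in (0, 1)")


def oneway_anova_power(spec: PowerSpec, n_per_group: int) -> float:
    """Power of the one-way fixed-effect F test at n subjects per group.

    power = P( F'(df1 = k-1, df2 = k(n-1), ncp = f^2 k n) > F_crit(alpha) ).
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    k, n = spec.k_groups, n_per_group
    df1, df2 = k - 1, k * (n - 1)
    ncp = spec.effect_f**2 * k * n
    f_crit = sps.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(sps.ncf.sf(f_crit, df1, df2, ncp))


def min_n_per_group(spec: PowerSpec, n_max: int = 10_000) -> tuple[int, float]:
    """Smallest integer n per group achieving the target power.

    Exact upward search from n = 2; returns (n, achieved power).
    """
    for n in range(2, n_max + 1):
        power = oneway_anova_power(spec, n)
        if power >= spec.target_power:
            return n, power
    raise RuntimeError(f"target power not reached by n = {n_max}")


def ttest_unpaired_from_summary(
    m1: float, sd1: float, n1: int,
    m2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries: (t, df, two-sided p).

    ``variant`` is "pooled" (Student, the default: equal-variance with
    df = n1 + n2 - 2) or "welch".
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if m1 == m2:
            import warnings

            warnings.warn("both groups degenerate and equal; p = 1 by convention")
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    equal_var = {"pooled": True, "welch": False}[variant]
    t, p = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df), float(p)


def shapiro_wilk(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test: (W, p)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


@dataclass
class AnovaResult:
    """Per-term F tests of a fixed-effects ANOVA."""

    terms: dict[str, tuple[float, int, int, float]]  # term -> (F, df1, df2, p)
    model: str

    def f(self, term: str) -> float:
        return self.terms[term][0]

    def p(self, term: str) -> float:
        return self.terms[term][3]


def two_way_anova(
    table: pd.DataFrame,
    response: str = "value",
    factors: tuple[str, str] = ("genotype", "treatment"),
) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction on a long-format table.

    Type III sums of squares with sum-to-zero contrasts, so main effects
    are tested at the centre of an unbalanced design.  Every factor cell
    must be occupied.
    """
    fa, fb = factors
    counts = table.groupby([fa, fb], observed=True)[response].count()
    la = table[fa].unique()
    lb = table[fb].unique()
    for a in la:
        for b in lb:
            if (a, b) not in counts.index or counts.loc[(a, b)] == 0:
                raise ValueError(f"empty cell: {fa}={a!r}, {fb}={b!r}")
    data = table[[fa, fb, response]].rename(columns={response: "_y"})
    model = ols(f"_y ~ C({fa}, Sum) * C({fb}, Sum)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    df_resid = int(model.df_resid)
    terms = {}
    label = {f"C({fa}, Sum)": fa, f"C({fb}, Sum)": fb,
             f"C({fa}, Sum):C({fb}, Sum)": f"{fa}:{fb}"}
    for row_name, pretty in label.items():
        row = aov.loc[row_name]
        terms[pretty] = (float(row["F"]), int(row["df"]), df_resid, float(row["PR(>F)"]))
    return AnovaResult(terms, "two-way with interaction, Type III")


def oneway_anova(table: pd.DataFrame, response: str, group: str) -> AnovaResult:
    """One-way fixed-effects ANOVA (used for e.g. age comparisons)."""
    groups = [g[response].to_numpy() for _, g in table.groupby(group, observed=True)]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    f, p = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return AnovaResult({group: (float(f), df1, df2, float(p))}, "one-way")


def tukey_hsd(
    table: pd.DataFrame,
    response: str = "value",
    group: str = "group",
) -> pd.DataFrame:
    """All-pairs comparisons with studentized-range adjustment.

    Tukey-Kramer form for unequal group sizes: for groups i, j with means
    m_i, m_j and pooled error MSE on df_err degrees of freedom,

        q_ij = |m_i - m_j| / sqrt( MSE/2 * (1/n_i + 1/n_j) )

    and the adjusted p is the studentized-range tail probability of q_ij
    with k groups and df_err.  Confidence bounds are at the 95% family
    level.
    """
    g = table.groupby(group, observed=True)[response]
    means = g.mean()
    ns = g.count()
    k = len(means)
    if k < 2:
        raise ValueError("need >= 2 groups for pairwise comparisons")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2 to estimate within-group variance")
    df_err = int(ns.sum() - k)
    sse = float(((table[response] - table[group].map(means)) ** 2).sum())
    mse = sse / df_err
    if mse == 0:
        raise ValueError("zero within-group variance: comparisons undefined")
    q_crit = sps.studentized_range.ppf(0.95, k, df_err)
    rows = []
    for a, b in combinations(means.index, 2):
        diff = float(means[b] - means[a])
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, df_err))
        half = float(q_crit * se)
        rows.append(
            {"group1": a, "group2": b, "mean_diff": diff,
             "p_adj": min(p_adj, 1.0), "ci_low": diff - half, "ci_high": diff + half}
        )
    return pd.DataFrame(rows)
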