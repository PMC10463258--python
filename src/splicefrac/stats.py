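"""Comparison statistics: unpaired t-test, variance-ratio F-test, two-way ANOVA.

The t-test (Student by default, Welch optional) compares group means; the
F-test compares group *dispersions* — the variance ratio against the
F(n_x-1, n_y-1) distribution, reported two-tailed since no direction of the
dispersion change is assumed; the two-way ANOVA (Type II sums of squares,
valid for unbalanced designs) tests two crossed factors and their
interaction, as in a genotype x treatment layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05  # conventional significance level; reported, never hard-gated


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple
    p_value: float
    test_name: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        object.__setattr__(self, "df", tuple(float(d) for d in self.df))


def t_test_unpaired(x, y, welch: bool = False) -> TestResult:
    """Unpaired two-tailed t-test for a difference in means.

    Student's pooled-variance form by default; set ``welch=True`` for the
    unequal-variance (Welch) form.  Degenerate zero-variance inputs return
    p = 1 when the means agree and p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        equal = np.isclose(x.mean(), y.mean())
        return TestResult(
            statistic=0.0 if equal else np.inf,
            df=(x.size + y.size - 2,),
            p_value=1.0 if equal else 0.0,
            test_name="t_test",
        )
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TestResult(
        statistic=float(res.statistic),
        df=(float(res.df),),
        p_value=float(res.pvalue),
        test_name="t_test",
    )


def f_test_variance(x, y) -> TestResult:
    """Two-tailed variance-ratio F-test for a difference in dispersion.

    ``F = var(x) / var(y)`` with ``(n_x - 1, n_y - 1)`` degrees of freedom;
    the two-tailed p-value is ``2 * min(P(F <= f), P(F >= f))`` capped at
    1, and is invariant under swapping the samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vy = y.var(ddof=1)
    if vy == 0:
        raise ValueError("denominator sample has zero variance")
    f = x.var(ddof=1) / vy
    dfn, dfd = x.size - 1, y.size - 1
    cdf = sps.f.cdf(f, dfn, dfd)
    p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    return TestResult(
        statistic=float(f), df=(dfn, dfd), p_value=float(p), test_name="f_test"
    )


def two_way_anova(values, factor_a, factor_b) -> dict:
    """Two-way ANOVA with interaction, Type II sums of squares.

    Returns a dict mapping ``"factor_a"``, ``"factor_b"`` and
    ``"interaction"`` to :class:`TestResult`.  Every factor-level cell must
    contain at least one observation; an empty cell raises an error naming
    it.  Degenerate decompositions are resolved as: zero effect sum of
    squares gives F = 0, p = 1; a nonzero effect with zero residual
    variance gives F = inf, p = 0.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": np.asarray(factor_a),
            "b": np.asarray(factor_b),
        }
    )
    levels_a, levels_b = df["a"].unique(), df["b"].unique()
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least two levels")
    observed = set(df.groupby(["a", "b"], sort=True).size().index)
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in observed:
                raise ValueError(f"empty cell: a={la!r}, b={lb!r}")
    model = smf.ols("value ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    df_resid = float(table.loc["Residual", "df"])
    out = {}
    eps = 1e-12 * max(1.0, float(np.sum(df["value"] ** 2)))
    for key, row_name in (
        ("factor_a", "C(a)"),
        ("factor_b", "C(b)"),
        ("interaction", "C(a):C(b)"),
    ):
        ss = float(table.loc[row_name, "sum_sq"])
        df_eff = float(table.loc[row_name, "df"])
        if ss <= eps:
            stat, p = 0.0, 1.0
        elif ss_resid <= eps:
            stat, p = np.inf, 0.0
        else:
            stat = (ss / df_eff) / (ss_resid / df_resid)
            p = float(sps.f.sf(stat, df_eff, df_resid))
        out[key] = TestResult(
            statistic=stat, df=(df_eff, df_resid), p_value=p, test_name="two_way_anova"
        )
    return out
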