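"""Shared statistical machinery: t-tests, ANOVA with Bonferroni post-hoc,
Pearson correlation.

All comparisons are two-sided. The significance threshold (alpha = 0.05)
is carried as a reporting annotation on results; nothing is filtered by it.
Pooled-variance t is the default for two-group comparisons, with Welch's
correction available behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


@dataclass
class StatResult:
    """Outcome of a hypothesis test.

    ``p_adjusted`` is the Bonferroni-adjusted p (raw p times the number of
    comparisons in the family, capped at 1); it equals ``p`` when the test
    is not part of a multiple-comparison family. ``degenerate`` marks
    zero-variance edge cases where the t statistic is not finite.
    """

    test: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    p_adjusted: float | None = None
    groups: list[GroupSummary] = field(default_factory=list)
    alpha: float = ALPHA_DEFAULT
    degenerate: bool = False
    n_excluded: int = 0

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "df": self.df if np.isscalar(self.df) else list(self.df),
            "p": float(self.p),
            "p_adjusted": None if self.p_adjusted is None else float(self.p_adjusted),
            "groups": [vars(g) for g in self.groups],
            "alpha": self.alpha,
            "degenerate": self.degenerate,
            "n_excluded": self.n_excluded,
        }


@dataclass
class CorrelationResult:
    """Pearson correlation plus the least-squares line."""

    group: str
    n: int
    r: float
    r2: float
    slope: float
    intercept: float
    p: float

    def to_dict(self) -> dict:
        return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in vars(self).items()}


def _summaries(groups: dict[str, np.ndarray]) -> list[GroupSummary]:
    return [
        GroupSummary(label=k, n=len(v), mean=float(np.mean(v)),
                     sd=float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        for k, v in groups.items()
    ]


def t_test(
    x: Sequence[float],
    y: Sequence[float],
    *,
    paired: bool = False,
    welch: bool = False,
    labels: tuple[str, str] = ("group1", "group2"),
    alpha: float = ALPHA_DEFAULT,
) -> StatResult:
    """Two-sided t-test between two groups (or paired samples).

    Paired mode requires equal-length inputs in matching order. Zero
    variance of the differences (paired) or both groups (unpaired) is
    flagged ``degenerate``: an all-zero difference yields t=0, p=1, while
    a constant nonzero difference yields p=0 with an infinite statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired t-test requires equal-length samples")
        if len(x) < 2:
            raise ValueError("paired t-test requires at least 2 pairs")
        d = x - y
        sd = d.std(ddof=1)
        n = len(d)
        # constant differences up to float rounding count as zero variance
        if sd <= 1e-12 * max(np.abs(d).max(), 1.0):
            if np.allclose(d, 0):
                res = StatResult("paired t", 0.0, n - 1, 1.0, degenerate=True,
                                 alpha=alpha)
            else:
                res = StatResult("paired t", float(np.sign(d.mean()) * np.inf),
                                 n - 1, 0.0, degenerate=True, alpha=alpha)
        else:
            t = d.mean() / (sd / np.sqrt(n))
            p = 2 * sps.t.sf(abs(t), n - 1)
            res = StatResult("paired t", float(t), n - 1, float(p), alpha=alpha)
    else:
        if len(x) < 2 or len(y) < 2:
            raise ValueError("unpaired t-test requires n >= 2 per group")
        nx, ny = len(x), len(y)
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        if vx == 0 and vy == 0:
            if x.mean() == y.mean():
                res = StatResult("t", 0.0, nx + ny - 2, 1.0, degenerate=True,
                                 alpha=alpha)
            else:
                res = StatResult("t", float(np.sign(x.mean() - y.mean()) * np.inf),
                                 nx + ny - 2, 0.0, degenerate=True, alpha=alpha)
        elif welch:
            se = np.sqrt(vx / nx + vy / ny)
            t = (x.mean() - y.mean()) / se
            df = (vx / nx + vy / ny) ** 2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
            p = 2 * sps.t.sf(abs(t), df)
            res = StatResult("Welch t", float(t), float(df), float(p), alpha=alpha)
        else:
            sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
            se = np.sqrt(sp2 * (1 / nx + 1 / ny))
            t = (x.mean() - y.mean()) / se
            df = nx + ny - 2
            p = 2 * sps.t.sf(abs(t), df)
            res = StatResult("t", float(t), df, float(p), alpha=alpha)
    res.groups = _summaries({labels[0]: x, labels[1]: y})
    return res


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: p times the number of comparisons, capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def _is_balanced(df: pd.DataFrame, factors: list[str]) -> bool:
    counts = df.groupby(factors, observed=True).size()
    return counts.nunique() == 1


def anova_bonferroni(
    data: pd.DataFrame,
    value: str,
    factors: Sequence[str],
    *,
    alpha: float = ALPHA_DEFAULT,
) -> dict:
    """One- or two-way ANOVA with Bonferroni-adjusted pairwise post-hoc tests.

    Two-way designs include the interaction term only when balanced;
    unbalanced two-way input degrades to a main-effects (additive) model
    with a logged warning. Post-hoc pairwise t-tests are run per factor
    across its levels, each raw p multiplied by the number of comparisons
    in that family and capped at 1.

    Returns a dict with ``omnibus`` (factor -> StatResult) and ``posthoc``
    (factor -> list of StatResult).
    """
    factors = list(factors)
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two factors supported")
    for f in factors:
        levels = data[f].unique()
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
        if (data.groupby(f, observed=True)[value].size() < 2).any():
            raise ValueError(f"factor {f!r} needs >= 2 observations per level")

    omnibus: dict[str, StatResult] = {}
    if len(factors) == 1:
        f = factors[0]
        groups = [g[value].to_numpy(dtype=float)
                  for _, g in data.groupby(f, observed=True)]
        k = len(groups)
        n = sum(len(g) for g in groups)
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b, df_w = k - 1, n - k
        F = (ss_between / df_b) / (ss_within / df_w)
        p = sps.f.sf(F, df_b, df_w)
        omnibus[f] = StatResult("one-way ANOVA F", float(F), (df_b, df_w),
                                float(p), alpha=alpha)
    else:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        d = data[[value] + factors].copy()
        d.columns = ["y", "A", "B"]
        balanced = _is_balanced(d, ["A", "B"])
        formula = "y ~ C(A) * C(B)" if balanced else "y ~ C(A) + C(B)"
        if not balanced:
            logger.warning(
                "unbalanced two-way design: interaction dropped, "
                "reporting main effects only"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.ols(formula, data=d).fit()
            table = sm.stats.anova_lm(model, typ=2)
        name_map = {"C(A)": factors[0], "C(B)": factors[1],
                    "C(A):C(B)": f"{factors[0]}:{factors[1]}"}
        df_resid = float(table.loc["Residual", "df"])
        for row, label in name_map.items():
            if row in table.index:
                omnibus[label] = StatResult(
                    "two-way ANOVA F", float(table.loc[row, "F"]),
                    (float(table.loc[row, "df"]), df_resid),
                    float(table.loc[row, "PR(>F)"]), alpha=alpha)

    posthoc: dict[str, list[StatResult]] = {}
    for f in factors:
        levels = list(pd.unique(data[f]))
        pairs = list(combinations(levels, 2))
        m = len(pairs)
        results = []
        for a, b in pairs:
            xa = data.loc[data[f] == a, value].to_numpy(dtype=float)
            xb = data.loc[data[f] == b, value].to_numpy(dtype=float)
            res = t_test(xa, xb, labels=(str(a), str(b)), alpha=alpha)
            res.test = f"pairwise t ({f}: {a} vs {b})"
            res.p_adjusted = bonferroni(res.p, m)
            results.append(res)
        posthoc[f] = results
    return {"omnibus": omnibus, "posthoc": posthoc}


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    *,
    group: str = "",
) -> CorrelationResult:
    """Pearson r with two-sided p (t distribution, n-2 df) and OLS line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for correlation")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in input")
    r, p = sps.pearsonr(x, y)
    slope = float(np.cov(x, y, ddof=1)[0, 1] / x.var(ddof=1))
    intercept = float(y.mean() - slope * x.mean())
    return CorrelationResult(group=group, n=n, r=float(r), r2=float(r) ** 2,
                             slope=slope, intercept=intercept, p=float(p))
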