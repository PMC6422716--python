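"""Standard between-group comparisons: ANOVA / Kruskal-Wallis with checks.

The conventional first pass before any network analysis: per variable, a
one-way ANOVA across the three groups (or a Kruskal-Wallis test for
variables flagged nonnormal), with homogeneity of variance checked by
the Brown-Forsythe (median-centered Levene) test and Tukey HSD post-hoc
comparisons (Tukey-Kramer under unequal group sizes) when the omnibus
test rejects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupComparisonResult",
    "levene_test",
    "oneway_anova",
    "kruskal_wallis",
    "compare_groups",
]


@dataclass
class GroupComparisonResult:
    variable: str
    test: str  # "anova" | "kruskal_wallis"
    statistic: float
    df: tuple
    p_value: float
    levene_p: float | None = None
    posthoc: list[tuple[str, str, float, float]] = field(default_factory=list)


def _split(values, groups) -> tuple[list[np.ndarray], list]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 observations")
    return samples, levels


def levene_test(values, groups, center: str = "median") -> tuple[float, float]:
    """Brown-Forsythe homogeneity-of-variance test (median-centered).

    ``center="rank"`` runs the test on the rank-transformed data, the
    nonparametric variant used alongside rank-based omnibus tests.
    """
    if center == "rank":
        values = stats.rankdata(np.asarray(values, dtype=float))
        center = "median"
    samples, _ = _split(values, groups)
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("all groups are internally constant; Levene W is 0/0")
    with np.errstate(invalid="ignore", divide="ignore"):
        W, p = stats.levene(*samples, center=center)
    if not np.isfinite(W):
        raise ValueError("degenerate spread pattern; Levene W is 0/0")
    return float(W), float(p)


def _tukey(values, groups, alpha: float) -> list[tuple[str, str, float, float]]:
    res = pairwise_tukeyhsd(np.asarray(values, dtype=float), np.asarray(groups), alpha=alpha)
    out = []
    for row in res.summary().data[1:]:
        a, b, meandiff, p_adj = row[0], row[1], float(row[2]), float(row[3])
        out.append((str(a), str(b), meandiff, p_adj))
    return out


def oneway_anova(
    values, groups, variable: str = "", alpha: float = 0.05
) -> GroupComparisonResult:
    """Classical one-way F test with (k-1, N-k) df; Tukey HSD if p < alpha."""
    samples, _ = _split(values, groups)
    k = len(samples)
    N = sum(len(s) for s in samples)
    F, p = stats.f_oneway(*samples)
    try:
        _, lev_p = levene_test(values, groups)
    except ValueError:
        lev_p = None
    posthoc = _tukey(values, groups, alpha) if p < alpha else []
    return GroupComparisonResult(
        variable=variable,
        test="anova",
        statistic=float(F),
        df=(k - 1, N - k),
        p_value=float(p),
        levene_p=lev_p,
        posthoc=posthoc,
    )


def kruskal_wallis(values, groups, variable: str = "") -> GroupComparisonResult:
    """Rank-based H test with tie correction, chi-square reference, k-1 df."""
    samples, _ = _split(values, groups)
    k = len(samples)
    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            H, p = stats.kruskal(*samples)
        if not np.isfinite(H):
            raise ValueError("tie correction is 0/0")
    except ValueError:
        # all observations identical: tie correction degenerates; report H = 0
        warnings.warn("all observations identical; Kruskal-Wallis H reported as 0")
        H, p = 0.0, 1.0
    try:
        _, lev_p = levene_test(values, groups, center="rank")
    except ValueError:
        lev_p = None
    return GroupComparisonResult(
        variable=variable,
        test="kruskal_wallis",
        statistic=float(H),
        df=(k - 1,),
        p_value=float(p),
        levene_p=lev_p,
    )


def compare_groups(
    table: pd.DataFrame,
    variables: list[str],
    group_column: str = "group",
    nonnormal: set[str] | frozenset[str] = frozenset(),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable omnibus test; tidy report with post-hoc rows.

    Variables in ``nonnormal`` get the Kruskal-Wallis test, the rest a
    one-way ANOVA — mirroring the convention of testing nonnormal scores
    (e.g. time-ratio variables) by ranks.
    """
    rows = []
    for var in variables:
        sub = table[[group_column, var]].dropna()
        vals, grp = sub[var], sub[group_column]
        if var in nonnormal:
            res = kruskal_wallis(vals, grp, variable=var)
        else:
            res = oneway_anova(vals, grp, variable=var, alpha=alpha)
        rows.append(
            {
                "variable": var,
                "test": res.test,
                "statistic": res.statistic,
                "df": "/".join(str(d) for d in res.df),
                "p_value": res.p_value,
                "levene_p": res.levene_p,
            }
        )
        for a, b, diff, p_adj in res.posthoc:
            rows.append(
                {
                    "variable": var,
                    "test": "tukey_hsd",
                    "statistic": diff,
                    "df": f"{a} vs {b}",
                    "p_value": p_adj,
                    "levene_p": None,
                }
            )
    return pd.DataFrame(rows)
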