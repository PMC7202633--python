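"""Factorial group statistics: 2x2 ANOVA, Tukey post-hoc, group summaries.

The study design is a two-way factorial — genotype (Control vs leptin
receptor deficient Db/Db) crossed with diet (control vs Western) — analyzed
separately for each sex.  Outcomes are compared with a fixed-effects two-way
ANOVA with interaction (Type II sums of squares by default, which handles
mildly unbalanced cell counts) followed by Tukey's honestly-significant-
difference comparison among the four groups (Tukey–Kramer correction for
unequal n).  Sex is a stratifier, never a factor.  No multiplicity
correction is applied across outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .errors import DesignDegenerateError, ExactSeparationWarning

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "two_way_anova",
    "one_way_anova",
    "tukey_hsd",
    "summarize_groups",
]

_RESIDUAL_TOL = 1e-12


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, mean and sample SD (n-1 denominator)."""

    genotype: str
    diet: str
    n: int
    mean: float
    sd: float
    sex: str | None = None


@dataclass
class AnovaResult:
    """Two-way ANOVA table plus the per-effect F and p values.

    ``table`` is indexed by effect name (genotype, diet, genotype:diet,
    residual) with columns sum_sq, df, F, p.
    """

    table: pd.DataFrame
    ss_type: int

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["residual", "df"])


def _validate_cells(df: pd.DataFrame, factors):
    for factor in factors:
        levels = df[factor].unique()
        if len(levels) != 2:
            raise DesignDegenerateError(
                f"factor {factor!r} must have exactly two levels, got {list(levels)}"
            )
    counts = df.groupby(list(factors), observed=True).size()
    if len(counts) < 4:
        raise DesignDegenerateError("factorial design has an empty cell")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise DesignDegenerateError(f"cells with fewer than 2 observations: {bad}")


def _limit_pvalues(table: pd.DataFrame) -> pd.DataFrame:
    """Replace NaN F/p from a zero residual variance with limit values."""
    resid_ms = table.loc["residual", "sum_sq"] / max(table.loc["residual", "df"], 1)
    total_ss = table["sum_sq"].sum()
    if resid_ms > _RESIDUAL_TOL * max(total_ss, 1.0):
        return table
    warnings.warn(
        "residual variance is (numerically) zero; p values reported as limits",
        ExactSeparationWarning,
        stacklevel=3,
    )
    for effect in table.index[:-1]:
        if table.loc[effect, "sum_sq"] <= _RESIDUAL_TOL * max(total_ss, 1.0):
            table.loc[effect, ["F", "p"]] = [0.0, 1.0]
        else:
            table.loc[effect, ["F", "p"]] = [np.inf, 0.0]
    return table


def two_way_anova(outcomes, genotype, diet, *, ss_type: int = 2) -> AnovaResult:
    """Fixed-effects 2x2 ANOVA with interaction.

    Parameters are per-specimen outcome values and the two label sequences.
    Type II sums of squares by default (coincide with Type I on balanced
    designs).  Cells must be non-empty with >= 2 observations each.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(outcomes, dtype=float),
            "genotype": np.asarray(genotype, dtype=object),
            "diet": np.asarray(diet, dtype=object),
        }
    )
    if df["y"].isna().any():
        df = df.dropna(subset=["y"])
    _validate_cells(df, ("genotype", "diet"))

    model = ols("y ~ C(genotype) * C(diet)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 handled below
        raw = anova_lm(model, typ=ss_type)
    rename = {
        "C(genotype)": "genotype",
        "C(diet)": "diet",
        "C(genotype):C(diet)": "genotype:diet",
        "Residual": "residual",
    }
    table = raw.rename(index=rename)[["sum_sq", "df", "F", "PR(>F)"]]
    table = table.rename(columns={"PR(>F)": "p"})
    table = table.reindex(["genotype", "diet", "genotype:diet", "residual"])
    table = _limit_pvalues(table)
    return AnovaResult(table=table, ss_type=ss_type)


def one_way_anova(outcomes, labels) -> tuple:
    """Single-factor fixed-effects ANOVA; returns (F, p).

    Provided for collapsed comparisons; on a two-level factor the F statistic
    equals the square of the pooled two-sample t statistic.
    """
    df = pd.DataFrame(
        {"y": np.asarray(outcomes, dtype=float),
         "g": np.asarray(labels, dtype=object)}
    )
    if df["g"].nunique() < 2:
        raise DesignDegenerateError("need at least two groups")
    model = ols("y ~ C(g)", data=df).fit()
    raw = anova_lm(model, typ=1)
    return float(raw.loc["C(g)", "F"]), float(raw.loc["C(g)", "PR(>F)"])


def tukey_hsd(outcomes, groups) -> pd.DataFrame:
    """All-pairs Tukey HSD adjusted p values.

    Uses the studentized-range distribution with the Tukey–Kramer correction
    for unequal group sizes.  Returns a tidy frame with one row per pair:
    group1, group2, mean_diff, p_adj.  Adjusted p is monotone decreasing in
    |mean difference| at fixed variance.
    """
    y = np.asarray(outcomes, dtype=float)
    g = np.asarray(groups, dtype=object)
    if len(y) != len(g):
        raise ValueError("outcomes and groups must have equal length")
    names = sorted(pd.unique(g).tolist(), key=str)
    samples = [y[g == name] for name in names]
    if len(names) < 2:
        raise DesignDegenerateError("Tukey HSD needs at least two groups")
    if any(len(s) < 2 for s in samples):
        raise DesignDegenerateError("every group needs at least two observations")
    if all(np.allclose(s.var(ddof=1), 0) for s in samples):
        # zero pooled variance: identical-groups limit
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diff = samples[i].mean() - samples[j].mean()
                rows.append(
                    {"group1": names[i], "group2": names[j],
                     "mean_diff": diff, "p_adj": 1.0 if diff == 0 else 0.0}
                )
        warnings.warn("zero within-group variance; p values are limits",
                      ExactSeparationWarning, stacklevel=2)
        return pd.DataFrame(rows)
    res = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def summarize_groups(outcomes, genotype, diet, sex=None) -> pd.DataFrame:
    """Per-group n, mean and sample SD (displayed as mean ± SD).

    Groups of size 1 get ``sd = NaN`` and ``degenerate = True`` so downstream
    stages can refuse them explicitly.
    """
    data = {
        "y": np.asarray(outcomes, dtype=float),
        "genotype": np.asarray(genotype, dtype=object),
        "diet": np.asarray(diet, dtype=object),
    }
    keys = ["genotype", "diet"]
    if sex is not None:
        data["sex"] = np.asarray(sex, dtype=object)
        keys = ["sex"] + keys
    df = pd.DataFrame(data)
    out = (
        df.groupby(keys, observed=True)["y"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    out["degenerate"] = out["n"] < 2
    return out
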