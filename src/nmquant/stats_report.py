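"""Group statistics mirroring the study-style reporting: mean ± SEM,
one-way ANOVA with Tukey's HSD, and Type-II two-way ANOVA, with
figure-legend significance stars.

The star bands follow the figure legends verbatim (*: p ≤ 0.05,
**: p ≤ 0.0002, ***: p ≤ 0.002, ****: p ≤ 0.00002). Note these are
non-monotone as printed — the two-star band is stricter than the
three-star band; bands are checked from strictest to loosest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: legend star bands, checked in this order (strictest first)
STAR_BANDS: tuple[tuple[float, str], ...] = (
    (0.00002, "****"),
    (0.0002, "**"),
    (0.002, "***"),
    (0.05, "*"),
)


def star_for_p(p: float) -> str:
    """Significance mark for a p-value under the legend's band definitions."""
    if not np.isfinite(p):
        return ""
    for thresh, mark in STAR_BANDS:
        if p <= thresh:
            return mark
    return "ns"


def mean_sem(values: Sequence[float]) -> tuple[float, float, int]:
    """Mean, standard error of the mean (sample SD / sqrt(n)) and n.

    SEM is undefined (NaN) for n = 1.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("mean_sem requires at least one value")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, sem, n


@dataclass
class GroupStatsResult:
    """Outcome of a group comparison.

    ``table`` holds one row per effect (F, df, p, stars); ``tukey`` the
    pairwise Tukey-HSD table for one-way designs (None otherwise).
    """

    test_name: str
    factors: tuple[str, ...]
    table: pd.DataFrame
    tukey: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    @property
    def p_values(self) -> dict[str, float]:
        return dict(zip(self.table["effect"], self.table["p"]))


def one_way_anova_tukey(groups: Mapping[str, Sequence[float]]) -> GroupStatsResult:
    """One-way ANOVA with Tukey's HSD post-hoc over all group pairs.

    Requires at least two groups with n >= 2 each. The Tukey table covers
    every pair with mean difference, adjusted p and legend stars.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names = list(groups)
    if len(names) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {k!r} has n={arr.size} < 2")
    f_stat, p = sps.f_oneway(*arrays.values())
    k = len(names)
    n_total = sum(a.size for a in arrays.values())
    table = pd.DataFrame(
        [
            {
                "effect": "group",
                "F": float(f_stat),
                "df1": k - 1,
                "df2": n_total - k,
                "p": float(p),
                "stars": star_for_p(p),
            }
        ]
    )
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * arrays[k].size for k in names])
    res = pairwise_tukeyhsd(values, labels)
    tukey = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    tukey = tukey.rename(columns={"p-adj": "p_adj"})
    tukey["p_adj"] = res.pvalues
    tukey["stars"] = [star_for_p(pv) for pv in res.pvalues]
    return GroupStatsResult("one-way ANOVA + Tukey HSD", ("group",), table, tukey)


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
) -> GroupStatsResult:
    """Two-way ANOVA with Type-II sums of squares (statsmodels OLS).

    Type II is the documented choice for unbalanced layouts. Raises on a
    saturated design (no residual degrees of freedom).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    frame = data[[value, factor_a, factor_b]].rename(
        columns={value: "y", factor_a: "A", factor_b: "B"}
    )
    frame = frame.assign(A=frame["A"].astype(str), B=frame["B"].astype(str))
    formula = "y ~ C(A) + C(B)" + (" + C(A):C(B)" if interaction else "")
    model = smf.ols(formula, data=frame).fit()
    if model.df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    aov = sm.stats.anova_lm(model, typ=2)
    rename = {"C(A)": factor_a, "C(B)": factor_b, "C(A):C(B)": f"{factor_a}:{factor_b}"}
    rows = []
    for effect, row in aov.iterrows():
        rows.append(
            {
                "effect": rename.get(effect, effect),
                "F": float(row["F"]) if np.isfinite(row["F"]) else np.nan,
                "df1": float(row["df"]),
                "df2": float(model.df_resid),
                "p": float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else np.nan,
                "stars": star_for_p(row["PR(>F)"]),
            }
        )
    table = pd.DataFrame(rows)
    return GroupStatsResult(
        "two-way ANOVA (Type II)", (factor_a, factor_b), table, extras={"model": model}
    )


def unpaired_t_tests(
    groups_a: Mapping[str, Sequence[float]],
    groups_b: Mapping[str, Sequence[float]],
    sidak: bool = False,
) -> pd.DataFrame:
    """Multiple two-tailed unpaired t-tests over matched keys.

    Uncorrected by default; ``sidak=True`` applies a Šidák family
    correction across the comparisons.
    """
    keys = [k for k in groups_a if k in groups_b]
    rows = []
    for k in keys:
        t, p = sps.ttest_ind(np.asarray(groups_a[k], float), np.asarray(groups_b[k], float))
        rows.append({"comparison": k, "t": float(t), "p": float(p)})
    frame = pd.DataFrame(rows, columns=["comparison", "t", "p"])
    m = len(frame)
    if sidak and m:
        frame["p_adj"] = 1.0 - (1.0 - frame["p"]) ** m
        frame["stars"] = frame["p_adj"].map(star_for_p)
    else:
        frame["stars"] = frame["p"].map(star_for_p)
    return frame
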