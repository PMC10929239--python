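"""Group-comparison statistics for stage outputs.

Supports the designs used for this kind of data: unpaired two-tailed t-test,
one-way ANOVA, and two-way ANOVA with interaction, with Sidak- or
Tukey-adjusted pairwise contrasts after a significant omnibus test. Group
summaries are mean ± SEM over the stated unit of analysis (animal or cell).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["ComparisonSpec", "ComparisonResult", "Contrast", "compare_groups", "sidak_adjust", "group_summary"]

DESIGNS = ("t_test_two_tailed", "anova_1way", "anova_2way")


@dataclass(frozen=True)
class ComparisonSpec:
    design: str = "t_test_two_tailed"
    factors: tuple[str, ...] = ("group",)
    posthoc: str = "none"  # sidak | tukey | none
    alpha: float = 0.05

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if self.posthoc not in ("sidak", "tukey", "none"):
            raise ValueError("posthoc must be sidak, tukey or none")
        if self.posthoc != "none" and not self.design.startswith("anova"):
            raise ValueError("post-hoc contrasts apply to ANOVA designs only")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class Contrast:
    groups: tuple[str, str]
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class ComparisonResult:
    design: str
    statistic: float  # t or F (first effect for two-way)
    df: tuple[float, ...]
    p_value: float
    effects: dict[str, tuple[float, float]] = field(default_factory=dict)  # name -> (F, p)
    contrasts: tuple[Contrast, ...] = ()
    group_means: dict[str, float] = field(default_factory=dict)
    group_sems: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment for m comparisons: 1 − (1 − p)^m."""
    return float(1.0 - (1.0 - p) ** m)


def group_summary(groups: dict) -> tuple[dict, dict]:
    means = {str(k): float(np.mean(v)) for k, v in groups.items()}
    sems = {
        str(k): float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else math.nan
        for k, v in groups.items()
    }
    return means, sems


def _tidy(groups: dict, factors: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    for key, vals in groups.items():
        levels = (key,) if not isinstance(key, tuple) else key
        if len(levels) != len(factors):
            raise ValueError(f"group key {key!r} does not match factors {factors}")
        for v in vals:
            rows.append({**{f: str(l) for f, l in zip(factors, levels)}, "value": float(v)})
    return pd.DataFrame(rows)


def compare_groups(groups: dict, spec: ComparisonSpec) -> ComparisonResult:
    """Run the specified design on ``{group label: values}`` data.

    For two-way designs, keys are (level-of-factor-1, level-of-factor-2)
    tuples; main effects and the interaction are reported, with the first main
    effect as the headline statistic. All-identical data (zero variance
    everywhere) is flagged degenerate with statistic 0 and p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    lengths = {k: len(v) for k, v in groups.items()}
    if any(n < 2 for n in lengths.values()):
        raise ValueError("each group needs n >= 2 for variance-based tests")
    means, sems = group_summary(groups)
    allvals = np.concatenate([np.asarray(v, float) for v in groups.values()])
    if np.ptp(allvals) == 0:
        return ComparisonResult(
            design=spec.design, statistic=0.0, df=(len(allvals) - len(groups),),
            p_value=1.0, group_means=means, group_sems=sems, degenerate=True,
        )

    if spec.design == "t_test_two_tailed":
        if len(groups) != 2:
            raise ValueError("t-test requires exactly two groups")
        (ka, va), (kb, vb) = groups.items()
        va, vb = np.asarray(va, float), np.asarray(vb, float)
        if np.ptp(va) == 0 and np.ptp(vb) == 0:
            # distinct constants: infinite t, degenerate by contract
            return ComparisonResult(
                design=spec.design, statistic=math.inf, df=(len(va) + len(vb) - 2,),
                p_value=0.0, group_means=means, group_sems=sems, degenerate=True,
            )
        t, p = sps.ttest_ind(va, vb, equal_var=True)
        return ComparisonResult(
            design=spec.design, statistic=float(t), df=(float(len(va) + len(vb) - 2),),
            p_value=float(p), group_means=means, group_sems=sems,
        )

    df = _tidy(groups, spec.factors if spec.design == "anova_2way" else (spec.factors[0],))
    if spec.design == "anova_1way":
        factor = spec.factors[0]
        model = smf.ols(f"value ~ C({factor})", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        F = float(tab["F"].iloc[0])
        p = float(tab["PR(>F)"].iloc[0])
        dfs = (float(tab["df"].iloc[0]), float(tab["df"].iloc[1]))
        effects = {factor: (F, p)}
    else:
        f1, f2 = spec.factors[:2]
        model = smf.ols(f"value ~ C({f1}) * C({f2})", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        effects = {}
        for name in tab.index[:-1]:
            clean = name.replace("C(", "").replace(")", "").replace(":", " x ")
            effects[clean] = (float(tab.loc[name, "F"]), float(tab.loc[name, "PR(>F)"]))
        first = tab.index[0]
        F = float(tab.loc[first, "F"])
        p = float(tab.loc[first, "PR(>F)"])
        dfs = (float(tab.loc[first, "df"]), float(tab["df"].iloc[-1]))

    contrasts: tuple[Contrast, ...] = ()
    if spec.posthoc != "none":
        contrasts = _posthoc(groups, spec.posthoc)
    return ComparisonResult(
        design=spec.design, statistic=F, df=dfs, p_value=p, effects=effects,
        contrasts=contrasts, group_means=means, group_sems=sems,
    )


def _posthoc(groups: dict, method: str) -> tuple[Contrast, ...]:
    labels = [str(k) for k in groups]
    if method == "tukey":
        vals = np.concatenate([np.asarray(v, float) for v in groups.values()])
        labs = np.concatenate([[str(k)] * len(v) for k, v in groups.items()])
        res = pairwise_tukeyhsd(vals, labs)
        out = []
        for (a, b), p in zip(itertools.combinations(sorted(set(labs)), 2), res.pvalues):
            out.append(Contrast(groups=(a, b), p_raw=float(p), p_adjusted=float(p)))
        return tuple(out)
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        _, p = sps.ttest_ind(np.asarray(groups[_orig_key(groups, a)], float),
                             np.asarray(groups[_orig_key(groups, b)], float), equal_var=True)
        out.append(Contrast(groups=(a, b), p_raw=float(p), p_adjusted=min(1.0, sidak_adjust(float(p), m))))
    return tuple(out)


def _orig_key(groups: dict, label: str):
    for k in groups:
        if str(k) == label:
            return k
    raise KeyError(label)
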