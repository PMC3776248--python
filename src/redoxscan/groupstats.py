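"""Two group-comparison schemes for multi-section redox studies.

Method I — global averaging.  Each section statistic (a per-section index
mean or SD) is first averaged over an animal's sections to one value per
animal; the group estimate is the mean +/- SD over animals and groups are
compared by an unpaired two-tailed t-test on the animal values (Welch by
default, pooled-variance optional).  Averaging discards within-animal
heterogeneity and leaves very few degrees of freedom.

Method II — depth-covariate modelling.  Every section enters as one
observation of an ordinary least-squares linear model

    statistic ~ intercept + group + depth

(the one-factor one-covariate ANCOVA); the group effect and its two-sided
p-value come from the group coefficient, and the per-um depth slope is
reported.  Sections are treated as independent samples, matching the
original univariate-GLM treatment; no animal random effect is fitted.

No multiple-testing correction is applied; all raw p-values are reported
and the 0.05 threshold is reported, never enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .scan_io import INDEX_NAMES

__all__ = [
    "GroupComparison",
    "SIGNIFICANCE_THRESHOLD",
    "SUMMARY_STATISTICS",
    "FIT_STATISTICS",
    "method_one",
    "method_two",
    "run_full_comparison",
    "comparisons_to_frame",
]

SIGNIFICANCE_THRESHOLD = 0.05

#: The ten per-section summary statistics: five index means, five index SDs.
SUMMARY_STATISTICS: tuple[str, ...] = tuple(
    f"{idx}_{stat}" for stat in ("mean", "sd") for idx in INDEX_NAMES
)

#: The seven bi-Gaussian fit statistics compared between groups.
FIT_STATISTICS: tuple[str, ...] = ("a1", "a2", "b1", "b2", "c1", "c2", "a2_over_a1")


@dataclass
class GroupComparison:
    """One statistic compared between two groups by one method.

    ``effect`` is case-group minus reference-group: the difference of animal
    means for Method I, the fitted group coefficient for Method II.
    ``group_estimates`` maps group name to ``(mean, sd, n)`` where n counts
    animals (Method I) or sections (Method II).
    """

    statistic: str
    method: str  # "I" or "II"
    group_estimates: dict[str, tuple[float, float, int]]
    effect: float
    p_value: float
    n_units: int
    depth_coefficient: float | None = None
    flags: list[str] = field(default_factory=list)
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and np.isfinite(self.p_value):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_THRESHOLD


def _animal_values(
    data: pd.DataFrame, statistic: str
) -> pd.DataFrame:
    """Unweighted per-animal means of a per-section statistic."""
    if statistic not in data.columns:
        raise KeyError(f"statistic {statistic!r} not in the summary table")
    return (
        data.groupby(["group", "animal_id"], sort=True)[statistic]
        .mean()
        .reset_index()
    )


def _as_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    from .scan_io import summaries_to_frame

    return summaries_to_frame(summaries)


def _resolve_groups(data: pd.DataFrame, groups: tuple[str, str] | None) -> tuple[str, str]:
    if groups is None:
        present = sorted(data["group"].unique())
        if len(present) != 2:
            raise ValueError(f"need exactly two groups, found {present}")
        groups = (present[0], present[1])
    return groups


def method_one(
    summaries,
    statistic: str,
    *,
    groups: tuple[str, str] | None = None,
    ttest: str = "welch",
) -> GroupComparison:
    """Global averaging: animal means, group mean +/- SD, unpaired t-test.

    ``groups`` orders (reference, case); by default the two group labels in
    sorted order, so ``("control", "pten_null")`` for the standard design.
    With zero variance in both groups the t-test is degenerate: the result
    is flagged and the p-value reported as exactly 0 (different means) or 1
    (equal means).
    """
    if ttest not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test flavor {ttest!r}")
    data = _as_frame(summaries)
    ref, case = _resolve_groups(data, groups)
    animals = _animal_values(data, statistic)
    vals = {
        g: animals.loc[animals["group"] == g, statistic].to_numpy(dtype=float)
        for g in (ref, case)
    }
    for g, v in vals.items():
        if len(v) < 2:
            raise ValueError(
                f"group {g!r} has {len(v)} animal(s); the t-test needs >= 2"
            )
    estimates = {
        g: (float(v.mean()), float(v.std(ddof=1)), int(len(v))) for g, v in vals.items()
    }
    effect = estimates[case][0] - estimates[ref][0]
    flags: list[str] = []
    if vals[ref].var(ddof=1) == 0.0 and vals[case].var(ddof=1) == 0.0:
        flags.append("degenerate_variance")
        p = 1.0 if effect == 0.0 else 0.0
        t_stat = 0.0 if effect == 0.0 else float("inf")
        df = float("nan")
    else:
        res = stats.ttest_ind(vals[case], vals[ref], equal_var=(ttest == "pooled"))
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        statistic=statistic,
        method="I",
        group_estimates=estimates,
        effect=float(effect),
        p_value=p,
        n_units=int(len(vals[ref]) + len(vals[case])),
        flags=flags,
        detail={"t": t_stat, "df": df, "ttest": ttest},
    )


def method_two(
    summaries,
    statistic: str,
    *,
    groups: tuple[str, str] | None = None,
) -> GroupComparison:
    """Depth-covariate model: OLS of the statistic on group + depth over sections."""
    data = _as_frame(summaries)
    ref, case = _resolve_groups(data, groups)
    sub = data[data["group"].isin((ref, case))].copy()
    for g in (ref, case):
        if (sub["group"] == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 sections")
    if "depth_um" not in sub.columns or sub["depth_um"].isna().any():
        raise ValueError("every section needs a recorded depth")
    y = sub[statistic].to_numpy(dtype=float)
    indicator = (sub["group"] == case).astype(float).to_numpy()
    depth = sub["depth_um"].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([indicator, depth]))
    flags: list[str] = []
    # collinearity: all depth variation between groups leaves no within-group
    # information to separate the covariate from the factor
    within_var = sub.groupby("group")["depth_um"].var(ddof=0)
    if float(within_var.fillna(0.0).sum()) == 0.0:
        flags.append("depth_group_collinear")
    fit = sm.OLS(y, X).fit()
    estimates = {
        g: (
            float(sub.loc[sub["group"] == g, statistic].mean()),
            float(sub.loc[sub["group"] == g, statistic].std(ddof=1)),
            int((sub["group"] == g).sum()),
        )
        for g in (ref, case)
    }
    return GroupComparison(
        statistic=statistic,
        method="II",
        group_estimates=estimates,
        effect=float(fit.params[1]),
        p_value=float(fit.pvalues[1]),
        n_units=int(len(sub)),
        depth_coefficient=float(fit.params[2]),
        flags=flags,
        detail={
            "t": float(fit.tvalues[1]),
            "df": float(fit.df_resid),
            "depth_p": float(fit.pvalues[2]),
            "r_squared": float(fit.rsquared),
        },
    )


def run_full_comparison(
    summaries,
    fits: pd.DataFrame | None = None,
    *,
    groups: tuple[str, str] | None = None,
    ttest: str = "welch",
) -> list[GroupComparison]:
    """Both methods applied to every statistic: 10 summary statistics plus,
    when per-section fit coefficients are supplied, the 7 bi-Gaussian
    statistics — 2 x 17 = 34 comparisons for the full analysis."""
    out: list[GroupComparison] = []
    summary_frame = _as_frame(summaries)
    for statistic in SUMMARY_STATISTICS:
        out.append(method_one(summary_frame, statistic, groups=groups, ttest=ttest))
        out.append(method_two(summary_frame, statistic, groups=groups))
    if fits is not None:
        for statistic in FIT_STATISTICS:
            out.append(method_one(fits, statistic, groups=groups, ttest=ttest))
            out.append(method_two(fits, statistic, groups=groups))
    return out


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons into the tabular export shape."""
    rows = []
    for c in comparisons:
        rec = {
            "statistic": c.statistic,
            "method": c.method,
            "effect": c.effect,
            "p_value": c.p_value,
            "n_units": c.n_units,
            "depth_coefficient": c.depth_coefficient,
            "significant": c.significant,
            "flags": ";".join(c.flags),
        }
        for g, (mean, sd, n) in c.group_estimates.items():
            rec[f"{g}_mean"] = mean
            rec[f"{g}_sd"] = sd
            rec[f"{g}_n"] = n
        rows.append(rec)
    return pd.DataFrame(rows)
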