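"""Group comparisons, regression and figure-ready summaries.

Cell-level observations are treated as independent, mirroring common
practice for tissue-cytometry violin statistics; a per-section
aggregation option is available for a conservative analysis that avoids
pseudo-replication.  The default two-sample test is the equal-variance
Student's t; Welch's correction is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

#: significance stars at the conventional thresholds
STAR_THRESHOLDS: Tuple[Tuple[float, str], ...] = (
    (1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"),
)
STAR_LEGEND = "*p < 0.05, **p < 0.01, ***p < 0.001, ****p < 0.0001"


def stars_for(p: float) -> str:
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return "ns"


@dataclass
class ComparisonResult:
    group_labels: Tuple[str, str]
    n: Tuple[int, int]
    means: Tuple[float, float]
    t: float
    p: float
    stars: str
    test_name: str


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    stderr: float
    n: int
    x_grid: np.ndarray
    ci_lower: np.ndarray     # 95 % confidence band of the fitted mean
    ci_upper: np.ndarray


def compare_groups(
    table: pd.DataFrame,
    by: str,
    value: str = "activity_od",
    groups: Optional[Sequence[str]] = None,
    equal_var: bool = True,
    aggregate_by: Optional[str] = None,
) -> ComparisonResult:
    """Unpaired two-tailed t-test between two groups of cells.

    ``by`` names the grouping column (exactly two levels unless
    ``groups`` selects a pair).  With ``aggregate_by`` (e.g. a section or
    replicate column) the test runs on per-unit means instead of raw
    cells.
    """
    df = table
    if aggregate_by is not None:
        df = df.groupby([by, aggregate_by], observed=True)[value].mean().reset_index()
    levels = list(groups) if groups is not None else sorted(df[by].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a = df.loc[df[by] == levels[0], value].dropna().to_numpy(dtype=float)
    b = df.loc[df[by] == levels[1], value].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero pooled variance with unequal means")
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    name = "Student's t (unpaired, two-tailed)" if equal_var else "Welch's t"
    return ComparisonResult(
        group_labels=(str(levels[0]), str(levels[1])),
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        t=float(t), p=float(p), stars=stars_for(float(p)), test_name=name,
    )


# ---------------------------------------------------------------------------
# two-way ANOVA with Bonferroni-corrected contrasts
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    anova_table: pd.DataFrame
    contrasts: pd.DataFrame      # within-stratum pairwise condition contrasts
    n_contrasts: int


def anova_with_bonferroni(
    table: pd.DataFrame,
    value: str = "activity_od",
    factors: Tuple[str, str] = ("condition", "stratum"),
    alpha: float = 0.05,
) -> AnovaResult:
    """Two-way ANOVA (type II) plus Bonferroni-adjusted pairwise
    condition contrasts within each level of the second factor.

    Adjusted p-values are ``min(1, m * p_raw)`` with ``m`` the total
    number of contrasts.  Empty design cells raise an explicit error
    naming the cell.
    """
    fa, fb = factors
    df = table[[value, fa, fb]].dropna()
    la = sorted(df[fa].unique())
    lb = sorted(df[fb].unique())
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("both factors need at least 2 levels")
    for va in la:
        for vb in lb:
            if ((df[fa] == va) & (df[fb] == vb)).sum() == 0:
                raise ValueError(f"empty design cell: {fa}={va!r}, {fb}={vb!r}")
    model = smf.ols(f"Q('{value}') ~ C(Q('{fa}')) * C(Q('{fb}'))", data=df).fit()
    atable = anova_lm(model, typ=2)
    atable.index = [
        str(i).replace(f"C(Q('{fa}'))", fa).replace(f"C(Q('{fb}'))", fb)
        for i in atable.index
    ]
    rows = []
    pairs = [(la[i], la[j]) for i in range(len(la)) for j in range(i + 1, len(la))]
    m = len(pairs) * len(lb)
    for vb in lb:
        sub = df[df[fb] == vb]
        for va1, va2 in pairs:
            x = sub.loc[sub[fa] == va1, value].to_numpy(dtype=float)
            y = sub.loc[sub[fa] == va2, value].to_numpy(dtype=float)
            t, p = sps.ttest_ind(x, y)
            p_adj = min(1.0, m * float(p))
            rows.append({fb: vb, "group_a": va1, "group_b": va2,
                         "mean_a": x.mean(), "mean_b": y.mean(),
                         "t": float(t), "p_raw": float(p), "p_adj": p_adj,
                         "significant": p_adj < alpha,
                         "stars": stars_for(p_adj)})
    return AnovaResult(anova_table=atable, contrasts=pd.DataFrame(rows),
                       n_contrasts=m)


# ---------------------------------------------------------------------------
# regression of activity on DNA-damage signal
# ---------------------------------------------------------------------------

def regress_activity_vs_damage(
    table: pd.DataFrame,
    x: str = "gh2ax_nuc_mean",
    y: str = "activity_od",
    strata: Optional[Sequence[str]] = ("basal", "low_suprabasal"),
    n_grid: int = 50,
) -> RegressionResult:
    """OLS of activity on nuclear damage-marker intensity with 95 % CI band.

    By default restricted to the combined basal and low suprabasal
    strata, where UV-driven coupling between DNA damage and enzymatic
    activity is expected.
    """
    df = table if strata is None else table[table["stratum"].isin(strata)]
    df = df[[x, y]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 cells for regression")
    xv = df[x].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValueError(f"constant predictor {x!r}")
    model = sm.OLS(yv, sm.add_constant(xv)).fit()
    grid = np.linspace(xv.min(), xv.max(), n_grid)
    pred = model.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    r = float(np.corrcoef(xv, yv)[0, 1])
    return RegressionResult(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r=r, stderr=float(model.bse[1]), n=len(df),
        x_grid=grid,
        ci_lower=pred["mean_ci_lower"].to_numpy(),
        ci_upper=pred["mean_ci_upper"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# violin summaries
# ---------------------------------------------------------------------------

def violin_summary(
    table: pd.DataFrame,
    value: str = "activity_od",
    by: Sequence[str] = ("stratum",),
    n_grid: int = 128,
) -> Tuple[pd.DataFrame, Dict[str, Tuple[np.ndarray, np.ndarray]]]:
    """Per-group summary statistics plus kernel-density traces.

    The mean is the headline statistic (first column after the group
    keys).  Single-valued groups get a degenerate density: a unit spike
    at the value.  Summaries are invariant to the row order of the
    table.
    """
    by = list(by)
    df = table.dropna(subset=[value])
    rows = []
    traces: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for key, sub in df.groupby(by, observed=True, sort=True):
        vals = np.sort(sub[value].to_numpy(dtype=float))
        label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        rec = {c: k for c, k in zip(by, key if isinstance(key, tuple) else (key,))}
        rec.update({
            "mean": float(vals.mean()), "n": len(vals),
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
        })
        rows.append(rec)
        if len(vals) > 1 and np.ptp(vals) > 0:
            kde = sps.gaussian_kde(vals)
            grid = np.linspace(vals.min(), vals.max(), n_grid)
            traces[label] = (grid, kde(grid))
        else:
            traces[label] = (np.array([vals[0]]), np.array([1.0]))
    summary = pd.DataFrame(rows)
    order = by + ["mean", "n", "median", "q1", "q3"]
    return summary[order], traces
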