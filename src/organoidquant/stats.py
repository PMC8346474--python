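"""Statistical layer: normality-gated comparisons and variance components.

Implements the testing conventions used throughout the pipeline:

* Shapiro–Wilk normality gate routing to parametric (one-way ANOVA +
  post-hoc t) or nonparametric (Kruskal–Wallis + post-hoc Mann–Whitney)
  comparisons;
* an exact Mann–Whitney U test by full enumeration of the permutation
  distribution (two-sided p = 2·min(tail), capped at 1);
* a two-sided F-test for equality of variances;
* one-way ANOVA from raw data or reconstructed from printed summary
  statistics (mean, SEM, n);
* fold-change normalization against differentiation-batch averages and
  among-/within-line variance components;
* an OLS F-test for longitudinal growth (time effect and time × line
  interaction).

Reproducibility metrics compare cell lines after fold-change
normalization: "among" mode divides each well by its batch average
across all lines (so among-line variance is the variance of line means),
"within" mode divides by the per-line batch average (so within-line
variance measures replicate scatter alone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TestResult",
    "VarianceReport",
    "fold_change_normalize",
    "among_line_variance",
    "within_line_variance",
    "anova_oneway",
    "anova_from_summary",
    "variance_ratio_test",
    "mann_whitney_exact",
    "mann_whitney_p_from_u",
    "kruskal_wallis",
    "normality_gate",
    "longitudinal_growth_test",
]

DEFAULT_SEED = 20210806
EXACT_ENUMERATION_LIMIT = 200_000


@dataclass
class TestResult:
    """Named test statistic with degrees of freedom and two-sided p."""

    name: str
    statistic: float
    p_value: float
    df: tuple[float, ...] = ()
    exact: bool = False
    extra: dict = field(default_factory=dict)


@dataclass
class VarianceReport:
    mode: str  # "among" or "within"
    normalized: pd.DataFrame
    line_stats: pd.DataFrame
    group_values: dict[str, np.ndarray]
    test: TestResult


# ---------------------------------------------------------------------------
# normalization and variance components


def fold_change_normalize(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Fold change from the batch average.

    ``among``: each well is divided by the mean of all wells in its
    batch (across lines); ``within``: by the mean of its own line's
    wells in that batch.  Requires columns line_id, batch_id, value.
    """
    if mode not in ("among", "within"):
        raise ValueError("mode must be 'among' or 'within'")
    out = table.copy()
    keys = ["batch_id"] if mode == "among" else ["batch_id", "line_id"]
    denom = out.groupby(keys)["value"].transform("mean")
    if (denom == 0).any():
        raise ValueError("zero batch mean")
    out["value_normalized"] = out["value"] / denom
    return out


def variance_ratio_test(var1: float, n1: int, var2: float, n2: int) -> TestResult:
    """Two-sided F-test for equality of two variances.

    F = var1/var2 with (n1−1, n2−1) degrees of freedom; two-sided p is
    twice the smaller tail probability, capped at 1.  A zero denominator
    variance yields the limiting p with a flag.
    """
    df1, df2 = n1 - 1, n2 - 1
    if var2 == 0:
        warnings.warn("zero variance in denominator group; p reported as limit")
        p = 1.0 if var1 == 0 else 0.0
        return TestResult("F", float("inf") if var1 else 1.0, max(p, np.nextafter(0, 1)),
                          (df1, df2), extra={"degenerate": True})
    F = var1 / var2
    p = 2.0 * min(sps.f.sf(F, df1, df2), sps.f.cdf(F, df1, df2))
    return TestResult("F", float(F), float(min(p, 1.0)), (df1, df2))


def among_line_variance(
    table: pd.DataFrame,
    group_map: dict[str, str],
    normalized: bool = False,
) -> VarianceReport:
    """Among-line variance comparison between two line groups.

    Wells are fold-change normalized in "among" mode (unless already
    normalized), per-line means are computed, and the sample variances
    of line means in the two groups are compared with a two-sided
    F-test.  ``group_map`` assigns each line_id to one of exactly two
    group labels; the first group sorted alphabetically is the F
    numerator.
    """
    norm = table if normalized else fold_change_normalize(table, "among")
    col = "value_normalized" if "value_normalized" in norm else "value"
    line_means = norm.groupby("line_id")[col].mean()
    groups = sorted(set(group_map.values()))
    if len(groups) != 2:
        raise ValueError("group_map must define exactly two groups")
    vals = {
        g: line_means[[l for l in line_means.index if group_map[l] == g]].to_numpy()
        for g in groups
    }
    if any(len(v) < 2 for v in vals.values()):
        raise ValueError("need >= 2 lines per group")
    v1, v2 = (np.var(vals[g], ddof=1) for g in groups)
    test = variance_ratio_test(v1, len(vals[groups[0]]), v2, len(vals[groups[1]]))
    line_stats = pd.DataFrame(
        {
            "line_id": line_means.index,
            "line_mean": line_means.to_numpy(),
            "group": [group_map[l] for l in line_means.index],
        }
    )
    test.extra.update({"variances": {groups[0]: float(v1), groups[1]: float(v2)}})
    return VarianceReport("among", norm, line_stats, vals, test)


def within_line_variance(
    table: pd.DataFrame,
    group_map: dict[str, str],
    normalized: bool = False,
) -> VarianceReport:
    """Within-line variance comparison between two line groups.

    Wells are fold-change normalized in "within" mode, the per-line
    sample variance (n−1 denominator) of normalized values is computed
    (lines with a single well are excluded and logged), and the groups
    of per-line variances are compared by one-way ANOVA.  The raw sum
    of squared deviations is also reported per line.
    """
    norm = table if normalized else fold_change_normalize(table, "within")
    col = "value_normalized" if "value_normalized" in norm else "value"
    rows = []
    for line, sub in norm.groupby("line_id"):
        v = sub[col].to_numpy()
        if len(v) < 2:
            warnings.warn(f"line {line!r} has a single well; excluded")
            continue
        rows.append(
            {
                "line_id": line,
                "n_wells": len(v),
                "within_variance": float(np.var(v, ddof=1)),
                "sum_sq_dev": float(((v - v.mean()) ** 2).sum()),
                "group": group_map[line],
            }
        )
    line_stats = pd.DataFrame(rows)
    groups = sorted(line_stats["group"].unique())
    vals = {
        g: line_stats.loc[line_stats["group"] == g, "within_variance"].to_numpy()
        for g in groups
    }
    test = anova_oneway(list(vals.values()))
    return VarianceReport("within", norm, line_stats, vals, test)


# ---------------------------------------------------------------------------
# ANOVA


def anova_oneway(groups: list[np.ndarray], posthoc: bool = False) -> TestResult:
    """One-way ANOVA: F = MS_between / MS_within with (k−1, N−k) df.

    Optionally appends unadjusted pairwise two-tailed pooled-variance
    t-tests in ``extra["posthoc"]``.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    ns = np.array([len(g) for g in groups], float)
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, int(ns.sum()) - k
    if ss_within == 0:
        if ss_between == 0:
            return TestResult("F", 0.0, 1.0, (df_b, df_w))
        raise ValueError("degenerate groups: zero within-group variability")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w)) if ss_between > 0 else 1.0
    result = TestResult("F", float(F), max(p, np.nextafter(0, 1)), (df_b, df_w))
    if posthoc:
        pairs = {}
        for i in range(k):
            for j in range(i + 1, k):
                t, pt = sps.ttest_ind(groups[i], groups[j], equal_var=True)
                pairs[(i, j)] = {"t": float(t), "p": float(pt)}
        result.extra["posthoc"] = pairs
    return result


def anova_from_summary(means, sems, ns) -> TestResult:
    """One-way ANOVA reconstructed from per-group mean, SEM and n.

    Group SD = SEM·√n; SS_between is taken about the size-weighted grand
    mean and SS_within = Σ(nᵢ−1)·SDᵢ², reproducing the raw-data ANOVA
    exactly when the summaries are exact.
    """
    means = np.asarray(means, float)
    sems = np.asarray(sems, float)
    ns = np.asarray(ns, float)
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    sds = sems * np.sqrt(ns)
    grand = float((ns * means).sum() / ns.sum())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_b, df_w = len(ns) - 1, int(ns.sum()) - len(ns)
    if ss_within == 0:
        if ss_between == 0:
            return TestResult("F", 0.0, 1.0, (df_b, df_w))
        raise ValueError("zero within-group variability")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w)) if ss_between > 0 else 1.0
    return TestResult("F", float(F), max(p, np.nextafter(0, 1)), (df_b, df_w))


# ---------------------------------------------------------------------------
# exact Mann–Whitney


@lru_cache(maxsize=64)
def _mw_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution counts of U = 0 … n1·n2 by exact enumeration.

    Uses the classical recurrence N(a, b, u) = N(a−1, b, u−b) +
    N(a, b−1, u) with exact integer arithmetic; the counts sum to
    C(n1+n2, n1), the number of equally likely group assignments.
    """
    table = np.zeros((n1 + 1, n2 + 1, n1 * n2 + 1), dtype=object)
    table[0, :, 0] = 1
    table[:, 0, 0] = 1
    for a in range(1, n1 + 1):
        for b in range(1, n2 + 1):
            for u in range(a * b + 1):
                c = table[a, b - 1, u]
                if u >= b:
                    c += table[a - 1, b, u - b]
                table[a, b, u] = c
    return table[n1, n2]


def mann_whitney_p_from_u(u: float, n1: int, n2: int) -> TestResult:
    """Exact two-sided p for a given U by full enumeration.

    p = 2·min(P(U ≤ u), P(U ≥ u)), capped at 1, over all
    C(n1+n2, n1) equally likely group assignments.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("empty group")
    if comb(n1 + n2, n1) > EXACT_ENUMERATION_LIMIT:
        raise ValueError("enumeration limit exceeded; use the approximate path")
    counts = _mw_counts(n1, n2)
    total = comb(n1 + n2, n1)
    u_int = int(round(u))
    lower = sum(counts[: u_int + 1])
    upper = sum(counts[u_int:])
    p = 2.0 * min(lower, upper) / total
    return TestResult("U", float(u), float(min(p, 1.0)), (n1, n2), exact=True)


def mann_whitney_exact(x, y) -> TestResult:
    """Mann–Whitney U test, exact when feasible.

    With no ties and C(n1+n2, n1) within the enumeration limit the full
    permutation distribution is used (``exact=True``).  With ties, or
    beyond the limit, midranks with the tie-corrected normal
    approximation are used and the result is flagged approximate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    has_ties = len(np.unique(combined)) < len(combined)
    if not has_ties and comb(n1 + n2, n1) <= EXACT_ENUMERATION_LIMIT:
        res = mann_whitney_p_from_u(u1, n1, n2)
        res.statistic = float(u1)
        return res
    # tie-corrected normal approximation on midranks
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return TestResult("U", float(u1), 1.0, (n1, n2), exact=False,
                          extra={"ties": True, "degenerate": True})
    z = (u1 - mu) / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("U", float(u1), float(min(p, 1.0)), (n1, n2), exact=False,
                      extra={"ties": bool(has_ties), "z": float(z)})


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal–Wallis H with tie correction; p from χ² with k−1 df."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    combined = np.concatenate(groups)
    if np.all(combined == combined[0]):
        return TestResult("H", 0.0, 1.0, (len(groups) - 1,))
    h, p = sps.kruskal(*groups)
    return TestResult("H", float(h), float(p), (len(groups) - 1,))


def normality_gate(groups: list[np.ndarray], alpha: float = 0.05) -> dict:
    """Shapiro–Wilk gate: parametric iff every group passes at alpha.

    Groups with n < 3 or constant values cannot be tested and force the
    nonparametric route with a warning.
    """
    results = []
    route = "parametric"
    for g in groups:
        g = np.asarray(g, float)
        if len(g) < 3 or np.all(g == g[0]):
            warnings.warn("group untestable for normality; nonparametric route")
            results.append(TestResult("W", float("nan"), float("nan"),
                                      extra={"untestable": True}))
            route = "nonparametric"
            continue
        w, p = sps.shapiro(g)
        results.append(TestResult("W", float(w), float(p)))
        if p < alpha:
            route = "nonparametric"
    return {"route": route, "shapiro": results}


def longitudinal_growth_test(data: pd.DataFrame) -> tuple[TestResult, TestResult]:
    """OLS F-tests for a time effect and a time × line interaction.

    ``data`` needs columns well_id, line_id, time, value (fold-change
    areas); wells are treated as independent observations at each time
    point.  The time effect is the F for the ``time`` slope in
    ``value ~ time``; the interaction F compares ``value ~ time *
    C(line_id)`` against the no-interaction model.
    """
    required = {"line_id", "time", "value"}
    if not required <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    if data["line_id"].nunique() < 2 or data["time"].nunique() < 3:
        raise ValueError("need >= 2 lines and >= 3 time points")
    base = smf.ols("value ~ time", data=data).fit()
    time_F = float(base.fvalue)
    time_p = float(base.f_pvalue)
    additive = smf.ols("value ~ time + C(line_id)", data=data).fit()
    full = smf.ols("value ~ time * C(line_id)", data=data).fit()
    cmp = sm.stats.anova_lm(additive, full)
    inter_F = float(cmp["F"].iloc[1])
    inter_p = float(cmp["Pr(>F)"].iloc[1])
    return (
        TestResult("F", time_F, time_p, (1, int(base.df_resid))),
        TestResult("F", inter_F, inter_p,
                   (int(cmp["df_diff"].iloc[1]), int(full.df_resid))),
    )
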