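"""Assay statistics: rank-sum comparisons, one-way ANOVA with Tukey HSD,
normality checking and group summaries.

The comparisons mirror common screening practice for per-cell and
per-spheroid measurements: an unpaired two-sample Wilcoxon (Mann–Whitney)
rank-sum test for two-arm drug assays, one-way ANOVA with post-hoc Tukey HSD
across cell lines, and a one-sample Kolmogorov–Smirnov normality check with
estimated parameters (Lilliefors-corrected via seeded Monte Carlo, since the
textbook KS null distribution is invalid when mean and sd come from the
sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    p_value: float | None
    group_sizes: tuple[int, ...]
    method: str
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def significance_stars(p: float | None) -> str:
    """Conventional significance markers: *, **, *** at 0.05, 0.01, 0.001."""
    if p is None:
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Unpaired two-sample Wilcoxon (Mann–Whitney U) rank-sum test.

    The p-value is exact (full enumeration of rank assignments) when
    ``min(n, m) <= 8`` and there are no ties; otherwise the normal
    approximation with tie and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires both groups to be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = min(x.size, y.size) <= 8 and not has_ties
    res = sps.mannwhitneyu(
        x, y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        name="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=(x.size, y.size),
        method="exact" if exact else "normal approximation, tie + continuity corrected",
    )


def anova_tukey(groups) -> tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA F test plus Tukey HSD pairwise adjusted p-values.

    Returns the omnibus :class:`TestResult` and a table of pairwise
    comparisons with studentized-range adjusted p-values at the pooled
    within-group degrees of freedom. Zero within-group variance flags the
    result degenerate with no p-value.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("anova_tukey requires at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    sizes = tuple(g.size for g in groups)
    grand = np.concatenate(groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfw = grand.size - len(groups)
    ssb = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in groups)
    dfb = len(groups) - 1
    if ssw <= 0:
        result = TestResult(
            name="anova", statistic=float("nan"), p_value=None,
            group_sizes=sizes, method="one-way F", degenerate=True,
        )
        return result, pd.DataFrame(columns=["group_a", "group_b", "diff", "p_adj"])
    f_stat = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f_stat, dfb, dfw))
    tukey = sps.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append({
                "group_a": i,
                "group_b": j,
                "diff": float(groups[i].mean() - groups[j].mean()),
                "p_adj": float(tukey.pvalue[i, j]),
            })
    result = TestResult(
        name="anova",
        statistic=float(f_stat),
        p_value=p,
        group_sizes=sizes,
        method="one-way F + Tukey HSD (studentized range)",
    )
    return result, pd.DataFrame(rows)


@lru_cache(maxsize=32)
def _lilliefors_null_table(n: int, n_resamples: int, seed: int) -> tuple[float, ...]:
    """Null distribution of the KS D statistic with estimated mean/sd."""
    rng = np.random.default_rng(seed)
    ds = np.empty(n_resamples)
    # sorted-uniform formulation of the one-sample KS statistic
    grid = np.arange(1, n + 1)
    for i in range(n_resamples):
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std(ddof=1)
        cdf = sps.norm.cdf(np.sort(z))
        ds[i] = max((grid / n - cdf).max(), (cdf - (grid - 1) / n).max())
    return tuple(np.sort(ds))


def ks_normality(x, n_resamples: int = 2000, seed: int = 0) -> TestResult:
    """One-sample KS test against a normal with the sample's mean and sd.

    The p-value comes from a seeded Monte-Carlo null (Lilliefors correction):
    the D statistic is recomputed on ``n_resamples`` standard-normal samples
    with re-estimated parameters, and the p-value is the exceedance fraction.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError(f"ks_normality needs n >= 5, got n = {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        return TestResult(
            name="ks_normality", statistic=float("nan"), p_value=None,
            group_sizes=(x.size,), method="Lilliefors MC", degenerate=True,
        )
    d = float(sps.kstest(x, "norm", args=(x.mean(), sd)).statistic)
    null = np.asarray(_lilliefors_null_table(x.size, n_resamples, seed))
    # add-one correction keeps p in (0, 1]
    p = float((np.sum(null >= d) + 1) / (n_resamples + 1))
    return TestResult(
        name="ks_normality",
        statistic=d,
        p_value=p,
        group_sizes=(x.size,),
        method=f"Lilliefors Monte-Carlo ({n_resamples} resamples, seed {seed})",
    )


def summarize(rows: pd.DataFrame, group_keys: list[str], value: str) -> pd.DataFrame:
    """Group summary: n, median, quartiles, mean, sd and CV (%).

    CV is the sample standard deviation over the mean, reported as a
    percentage; single-observation groups get ``NaN`` CV with
    ``cv_defined = False``.
    """
    if rows.empty:
        raise ValueError("summarize requires a nonempty table")
    for key in group_keys:
        if key not in rows.columns:
            raise KeyError(f"unknown group key {key!r}; columns are {list(rows.columns)}")
    if value not in rows.columns:
        raise KeyError(f"unknown value column {value!r}")

    def _one(g: pd.Series) -> pd.Series:
        v = g.to_numpy(dtype=float)
        sd = v.std(ddof=1) if v.size > 1 else np.nan
        mean = v.mean()
        cv = 100.0 * sd / mean if v.size > 1 and mean != 0 else np.nan
        return pd.Series({
            "n": v.size,
            "median": np.median(v),
            "q1": np.percentile(v, 25),
            "q3": np.percentile(v, 75),
            "mean": mean,
            "sd": sd,
            "cv_percent": cv,
            "cv_defined": bool(v.size > 1 and mean != 0),
        })

    if group_keys:
        out = rows.groupby(group_keys)[value].apply(_one).unstack().reset_index()
    else:
        out = _one(rows[value]).to_frame().T
    out["n"] = out["n"].astype(int)
    return out


def assay_report(control, treated, label_control: str = "control",
                 label_treated: str = "treated") -> tuple[pd.DataFrame, str]:
    """Two-arm assay comparison: summaries, normality check and rank-sum test.

    Returns a tidy result table and a human-readable text block with
    significance stars.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    ks = ks_normality(np.concatenate([control, treated])) if control.size + treated.size >= 5 else None
    mw = mann_whitney(control, treated)
    fold = np.median(treated) / np.median(control) if np.median(control) != 0 else np.nan
    table = pd.DataFrame([{
        "arm_a": label_control,
        "arm_b": label_treated,
        "n_a": control.size,
        "n_b": treated.size,
        "median_a": np.median(control),
        "median_b": np.median(treated),
        "fold_change_median": fold,
        "ks_p": ks.p_value if ks else np.nan,
        "mw_U": mw.statistic,
        "mw_p": mw.p_value,
        "significance": significance_stars(mw.p_value),
    }])
    text = (
        f"{label_treated} vs {label_control}: median {np.median(treated):.3g} vs "
        f"{np.median(control):.3g} (fold {fold:.3g}); Mann-Whitney U = {mw.statistic:.4g}, "
        f"p = {mw.p_value:.3g} {significance_stars(mw.p_value)} "
        f"(normality KS p = {ks.p_value:.3g})" if ks else ""
    )
    return table, text
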