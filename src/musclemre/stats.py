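"""Test-retest and longitudinal reliability statistics.

The reliability layer mirrors the study design it serves: intraclass
correlation for absolute agreement of single measurements under a two-way
mixed model (ICC(A,1)), Pearson or Spearman correlations gated on
Shapiro-Wilk normality, Holm step-down control of the familywise error
over the muscles of one report, paired/two-sample location tests with the
same normality gate, and the standardized response mean (SRM) as the
longitudinal effect size.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "IccResult",
    "CorrelationResult",
    "ComparisonResult",
    "icc_a1",
    "icc_band",
    "gated_correlation",
    "holm_adjust",
    "compare_groups",
    "srm",
    "reliability_report",
    "longitudinal_report",
]

#: Sample size below which the tests fall back to small-sample exact
#: null distributions for the rank tests.
EXACT_N_MAX = 25


@dataclasses.dataclass
class IccResult:
    icc: float
    p: float
    n: int
    k: int
    degenerate: bool = False


@dataclasses.dataclass
class CorrelationResult:
    kind: str | None  # "pearson" | "spearman" | None when undefined
    r: float
    p: float
    n: int
    flags: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class ComparisonResult:
    test: str
    statistic: float
    p: float
    flags: list[str] = dataclasses.field(default_factory=list)


def icc_a1(data) -> IccResult:
    """ICC(A,1): absolute agreement of single ratings, two-way model.

    ``data`` is an (n subjects x k sessions) matrix; rows containing any
    missing value are dropped. From the two-way ANOVA mean squares (rows =
    subjects, columns = sessions),

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    and the p-value comes from the subject-effect F test MSR/MSE with
    (n-1, (n-1)(k-1)) degrees of freedom. A matrix with zero total
    variance is perfect agreement by convention (ICC 1, flagged
    degenerate).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2D subjects-by-sessions matrix")
    complete = ~np.isnan(data).any(axis=1)
    data = data[complete]
    n, k = data.shape
    if n < 3:
        raise ValueError(f"need at least 3 complete subjects, got {n}")
    if k < 2:
        raise ValueError("need at least 2 sessions")
    grand = data.mean()
    if np.allclose(data, grand):
        return IccResult(icc=1.0, p=np.nan, n=n, k=k, degenerate=True)
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    if mse > 0:
        f_stat = msr / mse
        p = float(sps.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0  # perfect within-subject agreement with real spread
    return IccResult(icc=float(icc), p=p, n=n, k=k)


def icc_band(icc: float) -> str:
    """Qualitative reliability band: >0.90 excellent, >0.75 good,
    0.50-0.75 moderate, <0.50 poor."""
    if np.isnan(icc):
        return "undefined"
    if icc > 0.90:
        return "excellent"
    if icc > 0.75:
        return "good"
    if icc >= 0.50:
        return "moderate"
    return "poor"


def gated_correlation(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson when both variables pass Shapiro-Wilk, else Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            kind=None, r=np.nan, p=np.nan, n=x.size, flags=["constant_input"]
        )
    normal = (
        sps.shapiro(x).pvalue > alpha and sps.shapiro(y).pvalue > alpha
    )
    if normal:
        res = sps.pearsonr(x, y)
        kind = "pearson"
    else:
        res = sps.spearmanr(x, y)
        kind = "spearman"
    return CorrelationResult(
        kind=kind, r=float(res.statistic), p=float(res.pvalue), n=x.size
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    Sorted ascending, ``adj_(i) = max_{j<=i} (m - j + 1) p_(j)`` (1-based),
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be a 1D vector")
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def _normal(values: np.ndarray, alpha: float) -> bool:
    if np.ptp(values) == 0:
        return False
    return sps.shapiro(values).pvalue > alpha


def compare_groups(
    x, y, paired: bool = False, alpha: float = 0.05
) -> ComparisonResult:
    """Location comparison with a Shapiro-Wilk normality gate.

    Paired data: t-test on differences when they look normal, else a
    Wilcoxon signed-rank test. Independent groups: Welch t-test when both
    groups look normal, else a Wilcoxon rank-sum (Mann-Whitney) test.
    Rank-test null distributions are exact for n <= 25 without ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired and x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if min(x.size, y.size) < 3:
        raise ValueError("need at least 3 observations per group")
    flags: list[str] = []
    if paired:
        diffs = y - x
        if np.ptp(diffs) == 0 and diffs[0] == 0:
            return ComparisonResult(
                test="degenerate", statistic=np.nan, p=1.0,
                flags=["zero_variance_differences"],
            )
        if np.ptp(diffs) == 0:
            flags.append("constant_nonzero_differences")
        if _normal(diffs, alpha):
            res = sps.ttest_rel(y, x)
            return ComparisonResult("paired_t", float(res.statistic),
                                    float(res.pvalue), flags)
        exact = diffs.size <= EXACT_N_MAX and _no_wilcoxon_ties(diffs)
        res = sps.wilcoxon(y, x, method="exact" if exact else "approx")
        return ComparisonResult("wilcoxon_signed_rank",
                                float(res.statistic), float(res.pvalue),
                                flags)
    if _normal(x, alpha) and _normal(y, alpha):
        res = sps.ttest_ind(x, y, equal_var=False)
        return ComparisonResult("welch_t", float(res.statistic),
                                float(res.pvalue), flags)
    both_small = max(x.size, y.size) <= EXACT_N_MAX
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if both_small and no_ties else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult("wilcoxon_rank_sum", float(res.statistic),
                            float(res.pvalue), flags)


def _no_wilcoxon_ties(diffs: np.ndarray) -> bool:
    nz = diffs[diffs != 0]
    return nz.size == diffs.size and np.unique(np.abs(nz)).size == nz.size


def srm(baseline, followup) -> float:
    """Standardized response mean: mean(change) / sd(change) (sample sd).

    Missing (NaN) when the changes have zero spread.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if baseline.shape != followup.shape or baseline.ndim != 1:
        raise ValueError("baseline and followup must be paired 1D vectors")
    if baseline.size < 2:
        raise ValueError("need at least 2 pairs")
    change = followup - baseline
    sd = change.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float(change.mean() / sd)


# ---------------------------------------------------------------------------
# Report assembly


def _pivot_sessions(
    table: pd.DataFrame, sessions: tuple[str, str]
) -> pd.DataFrame:
    wide = table.pivot_table(
        index="subject_id", columns="session", values="value", aggfunc="first"
    )
    missing = [s for s in sessions if s not in wide.columns]
    if missing:
        raise ValueError(f"sessions missing from table: {missing}")
    return wide[list(sessions)].dropna()


def reliability_report(
    table: pd.DataFrame,
    sessions: tuple[str, str] = ("baseline", "week1"),
    alpha: float = 0.05,
    holm: bool = True,
) -> pd.DataFrame:
    """Test-retest report per (metric, side, muscle).

    For each muscle the two sessions enter ICC(A,1) and a normality-gated
    correlation; Holm correction runs over the muscles within one
    (metric, side) family, matching per-table reporting. Muscles with
    fewer than 3 complete subjects are skipped.
    """
    rows = []
    for (metric, side, muscle), sub in table.groupby(
        ["metric", "side", "muscle"]
    ):
        try:
            wide = _pivot_sessions(sub, sessions)
        except ValueError:
            continue
        if wide.shape[0] < 3:
            continue
        data = wide.to_numpy()
        icc = icc_a1(data)
        corr = gated_correlation(data[:, 0], data[:, 1], alpha=alpha)
        rows.append(
            {
                "metric": metric,
                "side": side,
                "muscle": muscle,
                "n": icc.n,
                "icc": icc.icc,
                "icc_p": icc.p,
                "icc_band": icc_band(icc.icc),
                "correlation_type": corr.kind,
                "correlation": corr.r,
                "correlation_p": corr.p,
            }
        )
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    if holm:
        report["holm_adjusted_p"] = np.nan
        for _, idx in report.groupby(["metric", "side"]).groups.items():
            fam = report.loc[idx, "correlation_p"].to_numpy()
            ok = np.isfinite(fam)
            adj = np.full(fam.shape, np.nan)
            if ok.any():
                adj[ok] = holm_adjust(fam[ok])
            report.loc[idx, "holm_adjusted_p"] = adj
    return report


def longitudinal_report(
    table: pd.DataFrame,
    baseline: str = "baseline",
    followup: str = "month18",
    metric: str = "stiffness_kPa",
    alpha: float = 0.05,
    holm: bool = True,
) -> pd.DataFrame:
    """Within-group change report per (group, muscle) for one metric.

    Left/right observations are averaged per subject first; each muscle
    gets a paired baseline-vs-followup comparison (normality-gated), an
    SRM, and Holm correction over the muscles within each group.
    """
    sub = table[table["metric"] == metric]
    rows = []
    for (group, muscle), block in sub.groupby(["group", "muscle"]):
        per_subject = (
            block.groupby(["subject_id", "session"])["value"]
            .mean()
            .unstack("session")
        )
        if baseline not in per_subject.columns or (
            followup not in per_subject.columns
        ):
            continue
        paired = per_subject[[baseline, followup]].dropna()
        if paired.shape[0] < 3:
            continue
        base = paired[baseline].to_numpy()
        post = paired[followup].to_numpy()
        comp = compare_groups(base, post, paired=True, alpha=alpha)
        change = post - base
        rows.append(
            {
                "group": group,
                "muscle": muscle,
                "n": paired.shape[0],
                "baseline_mean": base.mean(),
                "baseline_sd": base.std(ddof=1),
                "change_mean": change.mean(),
                "change_sd": change.std(ddof=1),
                "test": comp.test,
                "p": comp.p,
                "srm": srm(base, post),
            }
        )
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    if holm:
        report["holm_adjusted_p"] = np.nan
        for _, idx in report.groupby("group").groups.items():
            fam = report.loc[idx, "p"].to_numpy()
            ok = np.isfinite(fam)
            adj = np.full(fam.shape, np.nan)
            if ok.any():
                adj[ok] = holm_adjust(fam[ok])
            report.loc[idx, "holm_adjusted_p"] = adj
    return report
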