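"""Nonparametric and categorical statistics used throughout the analysis.

Group comparisons follow the reporting conventions of small-cohort clinical
studies: Shapiro-Wilk gates the choice of summary, non-normal variables are
reported as median and quartiles in the format ``Me (Q1; Q3)`` and compared
with the Mann-Whitney U test (exact for small untied samples), categorical
variables use Pearson's chi-square, correlation uses Spearman's rank
coefficient with a Fisher-z confidence interval, and multiplicity is
handled with Benjamini-Hochberg step-up adjustment. p-values below 0.001
are displayed as "<0.001".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import StatisticsError, ValidationError

#: Largest "smaller sample" size for which the exact Mann-Whitney null
#: distribution is used (covers all group sizes of the emulated cohort
#: whose smaller arm is <= 8).
EXACT_MW_MAX_N = 8

SIGNIFICANCE_LEVEL = 0.05


def format_p(p: float) -> str:
    """Display convention: values below 0.001 print as ``<0.001``."""
    if not np.isfinite(p):
        return "NA"
    if p < 0.001:
        return "<0.001"
    return f"{p:.4g}"


@dataclass
class MannWhitneyResult:
    u: float          # U statistic of the first sample
    p: float          # two-sided
    method: str       # "exact" | "normal-approximation"


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    The exact null distribution (full enumeration over labelings) is used
    when the smaller sample has at most :data:`EXACT_MW_MAX_N` values and
    there are no ties; otherwise the normal approximation with tie and
    continuity correction. U is reported for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatisticsError("mann_whitney needs >= 2 values per sample")
    if np.isnan(x).any() or np.isnan(y).any():
        raise StatisticsError("mann_whitney received NaN values")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= EXACT_MW_MAX_N and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method="exact")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return MannWhitneyResult(
        u=float(res.statistic), p=float(res.pvalue), method="normal-approximation"
    )


@dataclass
class GroupSummary:
    median: float
    q1: float
    q3: float

    @property
    def formatted(self) -> str:
        return f"{self.median:.2f} ({self.q1:.2f}; {self.q3:.2f})"


def summarize(values) -> GroupSummary:
    """Median and linear-interpolation quartiles, ``Me (Q1; Q3)``."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise StatisticsError("summarize needs at least one value")
    q1, me, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    return GroupSummary(median=float(me), q1=float(q1), q3=float(q3))


@dataclass
class SpearmanResult:
    rho: float
    p: float
    ci_low: float
    ci_high: float
    degenerate: bool  # |rho| = 1: the Fisher-z interval collapses


def spearman_with_ci(x, y, conf: float = 0.95) -> SpearmanResult:
    """Spearman rank correlation with a Fisher-z confidence interval.

    ``CI = tanh(atanh(rho) +/- z * sqrt(1/(n-3)))``. Perfect correlations
    give a degenerate interval equal to rho (flagged).

    Raises
    ------
    StatisticsError
        For n < 4, non-finite input, or a constant sample (undefined rho).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise StatisticsError("spearman_with_ci needs paired samples with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatisticsError("spearman_with_ci needs finite values")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise StatisticsError("correlation undefined for a constant sample")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    n = x.size
    if abs(rho) >= 1.0 - 1e-15:
        return SpearmanResult(rho=rho, p=float(p), ci_low=rho, ci_high=rho, degenerate=True)
    z = sps.norm.ppf(0.5 + conf / 2.0)
    half = z / np.sqrt(n - 3)
    lo, hi = np.tanh(np.arctanh(rho) - half), np.tanh(np.arctanh(rho) + half)
    return SpearmanResult(rho=rho, p=float(p), ci_low=float(lo), ci_high=float(hi), degenerate=False)


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    significant: pd.DataFrame  # boolean mask

    def __post_init__(self):
        assert (self.rho.values.diagonal() == 1).all()


def correlation_matrix(
    data: pd.DataFrame, conf: float = 0.95, alpha: float = SIGNIFICANCE_LEVEL,
    adjust: bool = False,
) -> CorrelationMatrix:
    """Pairwise Spearman correlations between the columns of ``data``.

    Pairs are computed on their complete observations. The significance
    mask uses raw p < alpha by default (the display convention of the
    emulated study); ``adjust=True`` switches to BH-adjusted p.
    """
    cols = list(data.columns)
    k = len(cols)
    rho = np.eye(k)
    p = np.zeros((k, k))
    lo = np.eye(k).astype(float)
    hi = np.eye(k).astype(float)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            sub = data[[cols[i], cols[j]]].dropna()
            r = spearman_with_ci(sub.iloc[:, 0], sub.iloc[:, 1], conf=conf)
            rho[i, j] = rho[j, i] = r.rho
            p[i, j] = p[j, i] = r.p
            lo[i, j] = lo[j, i] = r.ci_low
            hi[i, j] = hi[j, i] = r.ci_high
            pairs.append((i, j))
    pvec = np.array([p[i, j] for i, j in pairs]) if pairs else np.array([])
    crit = bh_adjust(pvec) if adjust else pvec
    sig = np.zeros((k, k), dtype=bool)
    for (i, j), c in zip(pairs, crit):
        sig[i, j] = sig[j, i] = c < alpha
    wrap = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return CorrelationMatrix(
        rho=wrap(rho), p=wrap(p), ci_low=wrap(lo), ci_high=wrap(hi),
        significant=wrap(sig),
    )


def chi_square(table, yates: bool = False) -> tuple[float, float, int]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns (statistic, p, degrees of freedom). No continuity correction by
    default; set ``yates=True`` for the corrected 2x2 statistic.

    Raises
    ------
    ValidationError
        If any expected count is zero (zero marginal).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("chi_square needs an r x c table with r, c >= 2")
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("zero marginal: expected counts would be zero")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=yates)
    return float(stat), float(p), int(dof)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.isnan(pvals).any() or (pvals < 0).any() or (pvals > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


@dataclass
class ShapiroVerdict:
    p: float
    normal: bool  # False steers reporting to Me (Q1; Q3) + Mann-Whitney
    degenerate: bool = False


def shapiro_gate(values, alpha: float = SIGNIFICANCE_LEVEL) -> ShapiroVerdict:
    """Shapiro-Wilk normality gate.

    Constant input yields a degenerate non-normal verdict instead of a
    crash; n < 3 raises.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 3:
        raise StatisticsError("shapiro_gate needs n >= 3")
    if np.ptp(values) == 0:
        return ShapiroVerdict(p=float("nan"), normal=False, degenerate=True)
    _, p = sps.shapiro(values)
    return ShapiroVerdict(p=float(p), normal=bool(p >= alpha))


@dataclass
class GroupComparison:
    """One Me (Q1; Q3) + Mann-Whitney comparison of two groups."""

    variable: str
    group_a: str
    group_b: str
    summary_a: GroupSummary
    summary_b: GroupSummary
    u: float
    p: float
    method: str

    @property
    def formatted_p(self) -> str:
        return format_p(self.p)


def compare_groups(
    values: pd.Series, groups: pd.Series, group_a: str, group_b: str,
    variable: str = "",
) -> GroupComparison:
    """Compare one variable between two groups, study-style."""
    a = values[groups == group_a].dropna()
    b = values[groups == group_b].dropna()
    res = mann_whitney(a, b)
    return GroupComparison(
        variable=variable or (values.name or ""),
        group_a=group_a,
        group_b=group_b,
        summary_a=summarize(a),
        summary_b=summarize(b),
        u=res.u,
        p=res.p,
        method=res.method,
    )
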