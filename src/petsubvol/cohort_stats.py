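"""Group-level statistics for baseline PET quantifiers.

Reporting follows the clinical convention: quantities are summarized as
mean +/- SD, adding median and range when a D'Agostino-Pearson omnibus
test rejects normality (or the sample is too small to test).  Group
differences (complete response vs. local recurrence/residual disease) are
assessed with a two-sided Mann-Whitney U test at alpha = 0.05; p-values
are reported unadjusted (no multiple-testing correction is applied across
the MTV / TLG / SUVmax comparisons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "NormalityResult",
    "SampleSummary",
    "GroupComparison",
    "dagostino_pearson",
    "mann_whitney",
    "summarize",
    "compare_groups",
    "ALPHA",
    "EXACT_MW_LIMIT",
]

ALPHA = 0.05
#: exact Mann-Whitney enumeration is used when n1*n2 <= this and there are no ties
EXACT_MW_LIMIT = 400
_MIN_N_NORMALITY = 8


@dataclass(frozen=True)
class NormalityResult:
    """D'Agostino-Pearson K^2 omnibus result; unavailable below n = 8."""

    available: bool
    statistic: float | None = None
    p: float | None = None

    @property
    def rejects_normality(self) -> bool:
        return bool(self.available and self.p is not None and self.p < ALPHA)


@dataclass(frozen=True)
class SampleSummary:
    n: int
    mean: float
    sd: float | None           # None (undefined) for n = 1
    median: float
    range: tuple[float, float]
    normality: NormalityResult
    report_range: bool         # True when normality rejected or untestable


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_a: str
    group_b: str
    summary_a: SampleSummary
    summary_b: SampleSummary
    u_statistic: float
    p_value: float
    significant: bool
    method: str                # "exact" or "asymptotic"

    def as_dict(self) -> dict:
        d = {
            "variable": self.variable,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_a": self.summary_a.n,
            "n_b": self.summary_b.n,
            "mean_a": self.summary_a.mean,
            "sd_a": self.summary_a.sd,
            "median_a": self.summary_a.median,
            "range_a_lo": self.summary_a.range[0],
            "range_a_hi": self.summary_a.range[1],
            "mean_b": self.summary_b.mean,
            "sd_b": self.summary_b.sd,
            "median_b": self.summary_b.median,
            "range_b_lo": self.summary_b.range[0],
            "range_b_hi": self.summary_b.range[1],
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "method": self.method,
        }
        return d


def dagostino_pearson(values: np.ndarray) -> NormalityResult:
    """D'Agostino-Pearson omnibus normality test (K^2, chi^2 with 2 dof).

    Combines the skewness and kurtosis z-scores; requires n >= 8 (below
    that the result is flagged unavailable and callers fall back to range
    reporting).  A constant sample is rejected as untestable.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D sample")
    if v.size < _MIN_N_NORMALITY:
        return NormalityResult(available=False)
    if np.ptp(v) == 0:
        raise ValueError("normality test undefined for a constant sample")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*kurtosistest.*")
        k2, p = stats.normaltest(v)
    return NormalityResult(available=True, statistic=float(k2), p=float(p))


def mann_whitney(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test; returns (U of group_a, p, method).

    Midranks are used for ties.  The p-value comes from exact enumeration
    when n1*n2 <= 400 and the pooled sample is tie-free, otherwise from the
    normal approximation with tie and continuity corrections.  If every
    value in both groups is identical the test is degenerate and p = 1 is
    returned with U at its null mean.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return a.size * b.size / 2.0, 1.0, "degenerate"
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size * b.size <= EXACT_MW_LIMIT) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), method


def summarize(values: np.ndarray) -> SampleSummary:
    """Mean +/- SD always; median + range added when not demonstrably normal."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    try:
        norm = dagostino_pearson(v) if np.ptp(v) > 0 or v.size < _MIN_N_NORMALITY \
            else NormalityResult(available=False)
    except ValueError:
        norm = NormalityResult(available=False)
    sd = float(v.std(ddof=1)) if v.size > 1 else None
    report_range = (not norm.available) or norm.rejects_normality
    return SampleSummary(
        n=int(v.size),
        mean=float(v.mean()),
        sd=sd,
        median=float(np.median(v)),
        range=(float(v.min()), float(v.max())),
        normality=norm,
        report_range=report_range,
    )


def compare_groups(
    variable: str,
    values_a: np.ndarray,
    values_b: np.ndarray,
    name_a: str = "CR",
    name_b: str = "LRRD",
) -> GroupComparison:
    """Full two-group comparison of one quantifier (summaries + Mann-Whitney)."""
    u, p, method = mann_whitney(values_a, values_b)
    return GroupComparison(
        variable=variable,
        group_a=name_a,
        group_b=name_b,
        summary_a=summarize(values_a),
        summary_b=summarize(values_b),
        u_statistic=u,
        p_value=p,
        significant=bool(p < ALPHA),
        method=method,
    )
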