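"""Group-comparison statistics for slice-level metrics.

The study's scheme: Shapiro–Wilk routes each genotype comparison to a pooled
two-sample (Student) t-test when both groups are normal, otherwise to the
Mann–Whitney U test; gamma power is log10-transformed first; effect sizes are
Cohen's d with a 95% CI.  Because published tables give mean ± SEM and n only,
the pooled t and d are also computable directly from those summaries
(SD = SEM·√n), which reproduces the printed test statistics.

Per-phase-bin comparisons of unit firing-probability profiles use Welch
t-tests bin by bin without multiplicity correction, mirroring the study's
"multiple t-test comparison ... without assuming a similar standard
deviation"; a Holm correction is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

from .mua_phase import PhaseProfile

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class TestKind(str, Enum):
    STUDENT_T = "student_t"
    MANN_WHITNEY = "mann_whitney"


@dataclass(frozen=True)
class GroupSummary:
    """Published-style group summary: mean ± SEM with group size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sem <= 0:
            raise ValueError("SEM must be positive")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)

    @classmethod
    def from_samples(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()),
                   sem=float(x.std(ddof=1) / np.sqrt(x.size)),
                   n=int(x.size))


@dataclass
class TestResult:
    statistic: float
    df: Optional[float]
    p: float
    d: Optional[float] = None
    d_ci: Optional[tuple[float, float]] = None
    test_name: TestKind = TestKind.STUDENT_T


def pooled_t_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Pooled-variance two-sample t-test from mean ± SEM summaries.

    SDs are reconstructed as SEM·√n; df = n₁ + n₂ − 2; two-tailed p.
    The sign convention is (a − b): a negative statistic means group a is
    below group b.
    """
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / (a.n + b.n - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    t = (a.mean - b.mean) / se
    df = a.n + b.n - 2
    p = 2.0 * sstats.t.sf(abs(t), df)
    d, lo, hi = cohens_d_ci(a, b)
    return TestResult(statistic=float(t), df=float(df), p=float(p),
                      d=d, d_ci=(lo, hi), test_name=TestKind.STUDENT_T)


def pooled_t(samples_a: Sequence[float], samples_b: Sequence[float]) -> TestResult:
    """Pooled two-sample t from raw samples (same convention as the
    summary path; the two agree exactly when the summaries are realized)."""
    return pooled_t_from_summary(GroupSummary.from_samples(samples_a),
                                 GroupSummary.from_samples(samples_b))


def cohens_d_ci(a: GroupSummary, b: GroupSummary, level: float = 0.95
                ) -> tuple[float, float, float]:
    """Cohen's d = (mean_a − mean_b)/pooled SD with a normal-approximation CI.

    SE(d) = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))); CI = d ± z·SE.  This
    approximation reproduces published effect-size intervals to two
    decimals and is antisymmetric under swapping the groups.
    """
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / (a.n + b.n - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    d = (a.mean - b.mean) / np.sqrt(sp2)
    n1, n2 = a.n, b.n
    se = np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2.0 * (n1 + n2)))
    z = sstats.norm.ppf(0.5 + level / 2.0)
    return float(d), float(d - z * se), float(d + z * se)


def route_test(samples_a: Sequence[float], samples_b: Sequence[float],
               alpha: float = 0.05) -> TestKind:
    """Choose Student t vs Mann–Whitney by Shapiro–Wilk normality of both
    groups at α = 0.05 (the study's blanket routing rule)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 samples per group for routing")
    normal = (sstats.shapiro(a).pvalue > alpha
              and sstats.shapiro(b).pvalue > alpha)
    return TestKind.STUDENT_T if normal else TestKind.MANN_WHITNEY


def compare_groups(samples_a: Sequence[float], samples_b: Sequence[float]
                   ) -> TestResult:
    """Normality-routed comparison: pooled t or Mann–Whitney U (two-tailed)."""
    kind = route_test(samples_a, samples_b)
    if kind is TestKind.STUDENT_T:
        return pooled_t(samples_a, samples_b)
    u = sstats.mannwhitneyu(samples_a, samples_b, alternative="two-sided")
    a = GroupSummary.from_samples(samples_a)
    b = GroupSummary.from_samples(samples_b)
    d, lo, hi = cohens_d_ci(a, b)
    return TestResult(statistic=float(u.statistic), df=None,
                      p=float(u.pvalue), d=d, d_ci=(lo, hi),
                      test_name=TestKind.MANN_WHITNEY)


def binwise_welch(profiles_a: Sequence[PhaseProfile],
                  profiles_b: Sequence[PhaseProfile],
                  alpha: float = 0.05,
                  holm: bool = False):
    """Per-phase-bin Welch t-tests across slices between two groups.

    Returns (p-values per bin, list of contiguous significant bin-index
    ranges [start, stop) — the display analogue of the "colored patches").
    No multiplicity correction by default; ``holm=True`` applies Holm.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need at least 2 profiles per group")
    mat_a = np.vstack([p.firing_prob for p in profiles_a])
    mat_b = np.vstack([p.firing_prob for p in profiles_b])
    if mat_a.shape[1] != mat_b.shape[1]:
        raise ValueError("phase-bin count mismatch between groups")
    res = sstats.ttest_ind(mat_a, mat_b, axis=0, equal_var=False)
    pvals = np.asarray(res.pvalue)
    if holm:
        order = np.argsort(pvals)
        m = pvals.size
        adj = np.empty_like(pvals)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
        pvals_eff = adj
    else:
        pvals_eff = pvals
    sig = pvals_eff < alpha
    ranges = []
    i = 0
    while i < sig.size:
        if sig[i]:
            j = i
            while j < sig.size and sig[j]:
                j += 1
            ranges.append((i, j))
            i = j
        else:
            i += 1
    return pvals_eff, ranges


def log_power(x: float | np.ndarray) -> float | np.ndarray:
    """Base-10 log of a power value in µV² (the transform applied to gamma
    power before group comparison); rejects non-positive input."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("power must be strictly positive for log transform")
    out = np.log10(arr)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out
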