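"""Cohort statistics: position-wise two-sample KS testing and the
KS-normality-then-t-test protocol for group means.

Two cuticle cohorts are compared position by position on the normalized
0-100 coordinate: at each position the per-line optical densities of cohort
A and cohort B form two samples, and the two-sample Kolmogorov-Smirnov test
asks whether their distributions differ. Raw p-values are reported against
a fixed significance threshold (default 1e-2) with no multiplicity
correction, matching how such profile comparisons are conventionally
plotted; a Benjamini-Hochberg option is available.

Group-mean comparisons (e.g. cell areas at two timepoints) use a Student
t-test, preceded by an advisory one-sample KS normality check of each
group against a normal with its estimated mean and standard deviation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .exceptions import InputError
from .profile_densitometry import CohortProfileSet

POSITIONS = np.arange(101)


@dataclass
class DensityComparison:
    """Per-position KS comparison of two cuticle cohorts."""

    statistic: np.ndarray  # KS D at positions 0..100
    p_values: np.ndarray
    alpha: float
    significant: np.ndarray  # boolean mask, p < alpha (after any correction)
    n_a: int
    n_b: int
    correction: str | None = None

    @property
    def positions(self) -> np.ndarray:
        return POSITIONS

    def to_records(self) -> list[dict]:
        return [
            {
                "position": int(i),
                "ks_statistic": float(self.statistic[i]),
                "p_value": float(self.p_values[i]),
                "significant": bool(self.significant[i]),
            }
            for i in POSITIONS
        ]


@dataclass
class GroupComparison:
    """Two-group mean comparison with its advisory normality checks."""

    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    normality_p_a: float
    normality_p_b: float
    t_statistic: float
    p_value: float
    equal_var: bool = True


@dataclass
class MeanSem:
    mean: float
    sem: float
    n: int


# ---------------------------------------------------------------------------


def ks_two_sample(
    sample_a, sample_b, method: str = "auto"
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum over x of the absolute ECDF difference, computed by a
    direct sweep over all sample points. The p-value uses the asymptotic
    Kolmogorov distribution with effective size ``n_a*n_b/(n_a+n_b)``;
    ``method="exact"`` (automatic when either side has <= 10 observations)
    uses the exact small-sample distribution instead.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be non-empty")
    if method not in ("auto", "asymp", "exact"):
        raise InputError(f"unknown method {method!r}")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))

    use_exact = method == "exact" or (method == "auto" and min(a.size, b.size) <= 10)
    if use_exact:
        p = float(stats.ks_2samp(a, b, method="exact").pvalue)
    else:
        # Kolmogorov tail with the classical finite-sample argument
        # correction (the form used by common KS-test implementations,
        # including the one the original profile comparisons were run with)
        ne = a.size * b.size / (a.size + b.size)
        lam = (np.sqrt(ne) + 0.12 + 0.11 / np.sqrt(ne)) * d
        p = float(special.kolmogorov(lam))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return d, p


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def positionwise_comparison(
    cohort_a: CohortProfileSet,
    cohort_b: CohortProfileSet,
    alpha: float = 0.01,
    correction: str | None = None,
    method: str = "auto",
) -> DensityComparison:
    """KS test of cohort A vs cohort B at each of the 101 positions.

    Raw p-values are reported and masked at *alpha* by default;
    ``correction="bh"`` masks Benjamini-Hochberg adjusted p-values instead.
    """
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise InputError("each cohort needs at least 2 profiles")
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    mat_a = cohort_a.od_matrix()
    mat_b = cohort_b.od_matrix()
    d = np.empty(101)
    p = np.empty(101)
    for i in range(101):
        d[i], p[i] = ks_two_sample(mat_a[:, i], mat_b[:, i], method=method)
    if correction is None:
        significant = p < alpha
    elif correction == "bh":
        significant = benjamini_hochberg(p) < alpha
    else:
        raise InputError(f"unknown correction {correction!r}")
    return DensityComparison(
        statistic=d,
        p_values=p,
        alpha=alpha,
        significant=significant,
        n_a=len(cohort_a),
        n_b=len(cohort_b),
        correction=correction,
    )


def compare_groups(
    group_a, group_b, equal_var: bool = True, normality_alpha: float = 0.05
) -> GroupComparison:
    """Student t-test of two group means after an advisory normality check.

    Each group is checked against a normal distribution with its own
    estimated mean and standard deviation by a one-sample KS test; failure
    (p below *normality_alpha*) raises a warning but does not gate the
    t-test. The t-test pools variances by default (Welch with
    ``equal_var=False``). Two zero-variance groups with equal means give
    t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 values")

    def _normality_p(x):
        sd = x.std(ddof=1)
        if sd == 0:
            return 0.0  # a point mass is maximally non-normal
        return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)

    p_norm_a, p_norm_b = _normality_p(a), _normality_p(b)
    for label, p_norm in (("A", p_norm_a), ("B", p_norm_b)):
        if p_norm < normality_alpha:
            warnings.warn(
                f"group {label} fails the KS normality check "
                f"(p = {p_norm:.3g}); t-test reported anyway",
                stacklevel=2,
            )

    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat = np.inf if a.mean() > b.mean() else -np.inf
            p_value = float(np.finfo(float).tiny)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p_value = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
        normality_p_a=p_norm_a,
        normality_p_b=p_norm_b,
        t_statistic=t_stat,
        p_value=p_value,
        equal_var=equal_var,
    )


def mean_sem(values) -> MeanSem:
    """Arithmetic mean and standard error (n-1 sd / sqrt(n); 0 when n=1)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InputError("mean_sem of an empty sample")
    sem = 0.0 if x.size == 1 else float(x.std(ddof=1) / np.sqrt(x.size))
    return MeanSem(mean=float(x.mean()), sem=sem, n=int(x.size))
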