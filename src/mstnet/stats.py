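"""Group comparisons, multiple-testing control, and brain-behaviour correlations.

Two-group contrasts use the nonparametric Mann-Whitney test (exact
enumeration for small tie-free samples, normal approximation with tie
and continuity corrections otherwise). Families of four band-wise
p-values are controlled by Benjamini-Hochberg FDR. Associations with
the disability score (48 - ALSFRS-R; 0 = healthy, 48 = maximal
disability) use Spearman rank correlation, computed on patients only,
at subject or single-epoch granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "disability_score",
    "mann_whitney",
    "fdr_bh",
    "spearman",
    "cohens_d",
    "epoch_level_correlation",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int | None = None
    effect_size: float | None = None
    fdr_significant: bool | None = None
    rank_sum_w: float | None = None
    method: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def disability_score(alsfrs_r: int) -> int:
    """Convert an ALSFRS-R functional score (0-48, higher = better) to
    a disability score 48 - ALSFRS-R (0 = healthy)."""
    alsfrs_r = int(alsfrs_r)
    if not 0 <= alsfrs_r <= 48:
        raise ValueError(f"ALSFRS-R must lie in [0, 48], got {alsfrs_r}")
    return 48 - alsfrs_r


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def mann_whitney(a, b, exact_threshold: int = 8) -> TestResult:
    """Two-sided Mann-Whitney U test of group ``a`` versus group ``b``.

    Uses the exact null distribution when ``min(n) <= exact_threshold``
    and the pooled sample is tie-free, otherwise the normal approximation
    with continuity and tie corrections. The U statistic of the first
    sample is reported together with its rank-sum W = U + n1(n1+1)/2;
    Cohen's d (pooled SD) is attached when defined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    exact = min(a.size, b.size) <= exact_threshold and not _has_ties(a, b)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    try:
        d = cohens_d(a, b)
    except ValueError:
        d = None
    return TestResult(
        statistic_name="U",
        statistic=u,
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(a.size),
        n2=int(b.size),
        effect_size=d,
        rank_sum_w=u + a.size * (a.size + 1) / 2,
        method=method,
    )


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``.

    Flags the k smallest p-values where k is the largest index with
    p(k) <= k*q/m; order of the input is preserved in the output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return np.asarray(reject, dtype=bool)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero-variance ranks: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return TestResult(
        statistic_name="rho",
        statistic=float(rho),
        p_value=float(min(p, 1.0)),
        n1=int(x.size),
        method="spearman",
    )


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean a - mean b) / pooled SD.

    Pooled SD uses n-1 denominators:
    s_p = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Cohen's d needs at least 2 observations per group")
    s1 = a.var(ddof=1)
    s2 = b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * s1 + (b.size - 1) * s2) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation: Cohen's d undefined")
    return float((a.mean() - b.mean()) / pooled)


def epoch_level_correlation(
    epoch_values: list[np.ndarray],
    disability: np.ndarray,
) -> TestResult:
    """Spearman correlation over all (epoch value, subject disability) pairs.

    ``epoch_values[i]`` holds subject i's per-epoch outcome values; each
    epoch contributes one point at the subject's disability score. When
    subjects contribute multiple epochs the points are not independent,
    so the p-value is computed at an inflated n; the result carries an
    explicit caveat note in that case.
    """
    disability = np.asarray(disability, dtype=float)
    if len(epoch_values) != disability.size:
        raise ValueError("one disability score per subject is required")
    if len(epoch_values) < 3:
        raise ValueError("need at least 3 subjects")
    xs: list[float] = []
    ys: list[float] = []
    multi = False
    for vals, d in zip(epoch_values, disability):
        vals = np.atleast_1d(np.asarray(vals, dtype=float))
        if vals.size > 1:
            multi = True
        xs.extend(vals.tolist())
        ys.extend([float(d)] * vals.size)
    res = spearman(np.array(ys), np.array(xs))
    res.statistic_name = "rho"
    if multi:
        res.notes = (
            "epochs within subjects are not independent; "
            "p-value computed at inflated n"
        )
    return res
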