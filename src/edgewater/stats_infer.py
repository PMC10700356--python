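"""The study's statistical procedures.

Two-sided Mann-Whitney U for two unpaired groups (exact for small tie-free
samples, normal approximation with tie and continuity corrections otherwise),
Kruskal-Wallis for more than two groups of non-normal data, Pearson
correlation with a least-squares line, and multiple-comparison correction by
the two-stage step-up false-discovery-rate procedure (the adaptive method of
Benjamini, Krieger & Yekutieli: a first Benjamini-Hochberg pass estimates the
number of true nulls m0, then a second step-up pass runs at the inflated level
alpha*m/m0).  q < 0.05 is the discovery cut-off throughout.

ANOVA and mixed-effects fits are routine and are expected to be delegated to
a general statistics backend; they are deliberately not re-implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "QValueSet",
    "mann_whitney_u",
    "kruskal_wallis",
    "two_stage_fdr",
    "pearson_test",
    "linear_fit",
]


@dataclass
class TestResult:
    statistic: float
    p_two_sided: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class QValueSet:
    """q-values and discovery flags from the two-stage step-up FDR."""

    pvalues: np.ndarray
    qvalues: np.ndarray
    discoveries: np.ndarray  # boolean, aligned with pvalues
    alpha: float
    m0: int  # estimated number of true nulls
    stage1_rejections: int


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test for two unpaired groups.

    The p-value is exact (full enumeration of the U null distribution) when
    the smaller group has at most 8 observations and the pooled data are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction is used.  The statistic is U of the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    exact = (min(x.size, y.size) <= 8) and not ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(float(res.statistic), float(res.pvalue),
                      "mann-whitney-exact" if exact else "mann-whitney-normal",
                      (x.size, y.size))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction, chi-square p (k-1 df).

    All-identical data are a degenerate but valid input: H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    ns = tuple(a.size for a in arrays)
    if np.unique(pooled).size == 1:
        return TestResult(0.0, 1.0, "kruskal-wallis", ns)
    h, p = stats.kruskal(*arrays)
    return TestResult(float(h), float(p), "kruskal-wallis", ns)


def _bh_rejections(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the Benjamini-Hochberg step-up at ``level``."""
    m = p_sorted.size
    thresh = level * np.arange(1, m + 1) / m
    below = np.nonzero(p_sorted <= thresh)[0]
    return int(below[-1] + 1) if below.size else 0


def two_stage_fdr(pvals, alpha: float = 0.05) -> QValueSet:
    """Two-stage step-up FDR correction, producing q-values.

    Stage 1 runs a Benjamini-Hochberg step-up at the deflated level
    alpha' = alpha/(1+alpha); its rejection count r1 estimates the number of
    true nulls as m0 = m - r1.  Stage 2 re-runs the step-up at the inflated
    level alpha*m/m0.  q-values are the adaptive BH q with m0
    (q_i = min_{j>=i} m0*p_(j)/j, capped at 1, monotone by construction), so
    the stage-2 discoveries are exactly the hypotheses with q <= alpha.
    m0 = 0 (stage 1 rejects everything) makes every hypothesis a discovery.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]

    r1 = _bh_rejections(p_sorted, alpha / (1.0 + alpha))
    m0 = m - r1

    if m0 == 0:
        q_sorted = np.zeros(m)
    else:
        q_raw = m0 * p_sorted / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_raw[::-1])[::-1]
        q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    discoveries = q <= alpha
    return QValueSet(p, q, discoveries, alpha, m0, r1)


def pearson_test(x, y) -> TestResult:
    """Pearson correlation; two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson", (x.size,))


def linear_fit(x, y) -> tuple[float, float]:
    """Ordinary least-squares line; returns (slope, intercept)."""
    res = stats.linregress(np.asarray(x, float), np.asarray(y, float))
    return float(res.slope), float(res.intercept)
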