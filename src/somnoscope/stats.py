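"""Non-parametric group statistics and effect sizes.

Rank tests (Mann-Whitney U, Wilcoxon signed rank), bootstrap percentile CIs
for medians, AUROC effect sizes with bootstrap CIs and classifier labels,
and Benjamini-Hochberg FDR control.

The AUROC here is the common-language effect size: ``auroc(A, B)`` is the
probability that a random value from A exceeds one from B (ties counted
half), computed with midranks, so ``auroc(A, B) == U_A / (n_A * n_B)``
exactly.  An effect is labelled a *good* classifier when AUC > 0.7 or
AUC < 0.3, and a *strong* classifier when, additionally, the bootstrap 95%
CI excludes 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "bootstrap_median_ci",
    "auroc",
    "auroc_effect",
    "classifier_label",
    "benjamini_hochberg",
]


@dataclass
class EffectResult:
    """AUROC effect size with bootstrap CI, label and (adjusted) p-values."""

    auc: float
    ci_lo: float
    ci_hi: float
    label: str  # "strong" | "good" | "none"
    p_raw: float = float("nan")
    p_adjusted: float = float("nan")
    n_a: int = 0
    n_b: int = 0


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U for independent groups.

    Returns (U of group A, p).  Exact null distribution when both groups
    have at most 8 values and no ties occur across groups; otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_signed_rank(differences: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; the exact distribution is used for up to
    15 non-zero differences without tied magnitudes.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 15 and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bootstrap_median_ci(
    values: Sequence[float],
    n_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> Tuple[float, float, float]:
    """Median with bootstrap percentile 95% CI (2.5th/97.5th of resampled
    medians over ``n_iter`` resamples with replacement)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values for a bootstrap CI")
    rng = _rng(seed)
    idx = rng.integers(0, v.size, size=(n_iter, v.size))
    meds = np.median(v[idx], axis=1)
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return float(np.median(v)), float(lo), float(hi)


def auroc(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """P(a > b) + 0.5 P(a == b) via the midrank (Mann-Whitney) formulation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_a = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u_a / (a.size * b.size))


def _auroc_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise AUROC for stacked resamples (a: (m, nA), b: (m, nB))."""
    na = a.shape[1]
    ranks = sps.rankdata(np.concatenate([a, b], axis=1), axis=1)
    u_a = ranks[:, :na].sum(axis=1) - na * (na + 1) / 2.0
    return u_a / (na * b.shape[1])


def auroc_effect(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
    p_raw: float | None = None,
) -> EffectResult:
    """AUROC with bootstrap 95% CI and strong/good/none classifier label.

    Each group is resampled independently with replacement (group sizes
    preserved); degenerate resamples are kept.  ``p_raw`` defaults to the
    Mann-Whitney p for the same comparison.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two values")
    rng = _rng(seed)
    point = auroc(a, b)
    ia = rng.integers(0, a.size, size=(n_iter, a.size))
    ib = rng.integers(0, b.size, size=(n_iter, b.size))
    boots = _auroc_matrix(a[ia], b[ib])
    lo, hi = (float(q) for q in np.percentile(boots, [2.5, 97.5]))
    lo, hi = min(lo, point), max(hi, point)
    if p_raw is None:
        p_raw = mann_whitney(a, b)[1]
    return EffectResult(
        auc=point,
        ci_lo=lo,
        ci_hi=hi,
        label=classifier_label(point, lo, hi),
        p_raw=float(p_raw),
        n_a=a.size,
        n_b=b.size,
    )


def classifier_label(auc: float, ci_lo: float, ci_hi: float) -> str:
    if auc > 0.7 or auc < 0.3:
        if not (ci_lo <= 0.5 <= ci_hi):
            return "strong"
        return "good"
    return "none"


def benjamini_hochberg(
    p_values: Sequence[float], q: float = 0.05
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Benjamini-Hochberg FDR control.

    Sorts the m p-values ascending, finds the largest rank k with
    P(k) <= (k/m) * q, and rejects ranks 1..k.  Adjusted p-values are the
    step-up values min_{j >= i} (m/j) P(j), capped at 1, returned in the
    original order.  Returns (rejected flags, adjusted p, k).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0), 0
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    thresh_ok = ranked <= (np.arange(1, m + 1) / m) * q
    k = int(np.max(np.nonzero(thresh_ok)[0]) + 1) if np.any(thresh_ok) else 0
    rejected_sorted = np.zeros(m, dtype=bool)
    rejected_sorted[:k] = True
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    rejected = np.empty(m, dtype=bool)
    adjusted = np.empty(m)
    rejected[order] = rejected_sorted
    adjusted[order] = adj_sorted
    return rejected, adjusted, k
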