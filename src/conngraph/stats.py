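"""Permutation-based group inference on network metrics.

Three-group comparisons use the one-way ANOVA F statistic with the null
distribution obtained by uniformly permuting group labels (default 10000
permutations); post-hoc pairwise comparisons permute the absolute mean
difference.  P-values use the add-one convention
p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm), so p in (0, 1].
Metric–symptom association uses Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "CorrelationResult",
    "one_way_f",
    "permutation_anova",
    "permutation_pairwise",
    "spearman_correlation",
]

_EPS = 1e-12


@dataclass(frozen=True)
class GroupTestResult:
    metric: str
    f_obs: float
    p_perm: float
    pairwise: dict[str, float] = field(default_factory=dict)
    n_perm: int = 0
    seed: int | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    metric: str
    rho: float
    p: float
    n: int
    degenerate: bool = False


def _group_masks(labels: np.ndarray) -> list[np.ndarray]:
    groups = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    return [np.asarray(labels) == g for g in groups]


def one_way_f(values: np.ndarray, masks: list[np.ndarray]) -> float:
    """Closed-form one-way ANOVA F = MS_between / MS_within."""
    values = np.asarray(values, dtype=float)
    n = values.size
    k = len(masks)
    grand = values.mean()
    ssb = sum(m.sum() * (values[m].mean() - grand) ** 2 for m in masks)
    sst = ((values - grand) ** 2).sum()
    ssw = sst - ssb
    if ssw <= _EPS * max(sst, 1.0):
        return np.inf if ssb > _EPS * max(sst, 1.0) else 0.0
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def _permuted_f(
    values: np.ndarray, masks: list[np.ndarray], n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized F over label permutations (equivalently, value permutations)."""
    n = values.size
    k = len(masks)
    perms = rng.permuted(np.broadcast_to(values, (n_perm, n)).copy(), axis=1)
    grand = values.mean()
    sst = ((values - grand) ** 2).sum()
    ssb = np.zeros(n_perm)
    for m in masks:
        ssb += m.sum() * (perms[:, m].mean(axis=1) - grand) ** 2
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / np.where(ssw > 0, ssw / (n - k), np.inf)
    return f


def permutation_anova(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    metric: str = "",
) -> GroupTestResult:
    """Permutation one-way ANOVA across the groups present in ``labels``."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(values)):
        raise ValueError("metric values must be finite")
    masks = _group_masks(labels)
    if len(masks) < 2 or any(m.sum() < 2 for m in masks):
        raise ValueError("each group needs at least 2 subjects")
    f_obs = one_way_f(values, masks)
    if not np.isfinite(f_obs):
        # zero within-group variance: no permutation can be computed sensibly
        p = 1.0 / (n_perm + 1)
        return GroupTestResult(metric, f_obs, p, {}, n_perm, seed, degenerate=True)
    if f_obs == 0.0 and np.ptp(values) <= _EPS:
        return GroupTestResult(metric, 0.0, 1.0, {}, n_perm, seed, degenerate=True)
    rng = np.random.default_rng(seed)
    f_perm = _permuted_f(values, masks, n_perm, rng)
    p = float((1 + (f_perm >= f_obs - _EPS).sum()) / (1 + n_perm))
    return GroupTestResult(metric, f_obs, p, {}, n_perm, seed)


def permutation_pairwise(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> float:
    """Two-group permutation p for the absolute difference of group means."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    masks = _group_masks(labels)
    if len(masks) != 2 or any(m.sum() < 2 for m in masks):
        raise ValueError("pairwise test needs exactly 2 groups with >= 2 subjects")
    m1, m2 = masks
    d_obs = abs(values[m1].mean() - values[m2].mean())
    rng = np.random.default_rng(seed)
    n = values.size
    perms = rng.permuted(np.broadcast_to(values, (n_perm, n)).copy(), axis=1)
    d_perm = np.abs(perms[:, m1].mean(axis=1) - perms[:, m2].mean(axis=1))
    return float((1 + (d_perm >= d_obs - _EPS).sum()) / (1 + n_perm))


def spearman_correlation(
    x: np.ndarray, y: np.ndarray, metric: str = ""
) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    p comes from the large-sample t approximation (as implemented in
    scipy); constant inputs are reported as degenerate rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("spearman correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(metric, np.nan, np.nan, x.size, degenerate=True)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(metric, float(rho), float(p), x.size)
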