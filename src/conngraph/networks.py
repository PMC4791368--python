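"""Construction of weighted functional and structural brain networks.

Functional edges: positive Pearson correlations between ROI time series
whose two-tailed significance survives the chosen threshold scheme
(default P < 0.05 Bonferroni over the 4005 unique region pairs; the looser
P < 0.001 uncorrected and stricter P < 0.01 Bonferroni schemes are also
supported), with the correlation coefficient as edge weight.

Structural edges: region pairs connected by at least ``min_fibers``
streamlines (default 3), with the fiber count as edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .metrics import WeightedGraph
from .preprocess import SubjectTimeSeries

__all__ = [
    "CorrelationMatrix",
    "ThresholdScheme",
    "DEFAULT_SCHEMES",
    "correlation_matrix",
    "threshold_functional",
    "threshold_structural",
    "validate_fiber_counts",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson r with two-tailed p (t distribution, df = n - 2)."""

    r: np.ndarray
    p: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if r.shape != p.shape or r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("r and p must be equal-shape square matrices")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class ThresholdScheme:
    """Significance threshold for functional edges.

    ``bonferroni`` divides alpha by ``n_tests`` (4005 = 90*89/2 unique
    pairs); ``none`` applies alpha directly.
    """

    alpha: float
    correction: str = "bonferroni"
    n_tests: int = 4005

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")

    @property
    def effective_alpha(self) -> float:
        if self.correction == "bonferroni":
            return self.alpha / self.n_tests
        return self.alpha

    @property
    def name(self) -> str:
        return f"p{self.alpha:g}_{self.correction}"


#: The three schemes used for the functional networks, strictest last.
DEFAULT_SCHEMES = (
    ThresholdScheme(0.05, "bonferroni"),
    ThresholdScheme(0.001, "none"),
    ThresholdScheme(0.01, "bonferroni"),
)


def correlation_matrix(ts: SubjectTimeSeries) -> CorrelationMatrix:
    """Pearson correlations between all ROI pairs with two-tailed p-values."""
    if ts.n_volumes < 3:
        raise ValueError("correlation requires at least 3 volumes")
    sd = ts.values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance ROI(s) at index {dead.tolist()}: "
            "correlation undefined"
        )
    r = np.corrcoef(ts.values)
    r = np.clip(r, -1.0, 1.0)
    df = ts.n_volumes - 2
    off = ~np.eye(r.shape[0], dtype=bool)
    p = np.zeros_like(r)
    with np.errstate(divide="ignore"):
        t = r[off] * np.sqrt(df / np.maximum(1.0 - r[off] ** 2, 1e-300))
    p[off] = 2.0 * stats.t.sf(np.abs(t), df)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, p, ts.n_volumes)


def threshold_functional(
    corr: CorrelationMatrix, scheme: ThresholdScheme
) -> WeightedGraph:
    """Retain positive correlations whose p survives the scheme; weight = r."""
    mask = (corr.r > 0) & (corr.p < scheme.effective_alpha)
    np.fill_diagonal(mask, False)
    weights = np.where(mask, corr.r, 0.0)
    # symmetry is inherited from r, but enforce exactly
    weights = np.maximum(weights, weights.T) * np.maximum(mask, mask.T)
    return WeightedGraph(weights, modality="functional")


def validate_fiber_counts(fn: np.ndarray) -> np.ndarray:
    fn = np.asarray(fn)
    if fn.ndim != 2 or fn.shape[0] != fn.shape[1]:
        raise ValueError("fiber-count matrix must be square")
    if not np.array_equal(fn, fn.T):
        raise ValueError("fiber-count matrix must be symmetric")
    if np.any(fn < 0) or not np.array_equal(fn, np.round(fn)):
        raise ValueError("fiber counts must be non-negative integers")
    if np.any(np.diag(fn) != 0):
        raise ValueError("fiber-count matrix must have a zero diagonal")
    return fn.astype(float)


def threshold_structural(fn: np.ndarray, min_fibers: int = 3) -> WeightedGraph:
    """Retain pairs with at least ``min_fibers`` streamlines; weight = count."""
    fnm = validate_fiber_counts(fn)
    weights = np.where(fnm >= min_fibers, fnm, 0.0)
    return WeightedGraph(weights, modality="structural")
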