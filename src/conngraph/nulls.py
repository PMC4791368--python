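"""Degree-preserving null ensembles and normalized small-world metrics.

Matched random networks preserve node count, edge count and the full degree
sequence via repeated double-edge swaps (Maslov–Sneppen rewiring); edge
weights travel with their edges, so the weight multiset is preserved
exactly (and with it the max weight used for normalization).  The observed
metrics are scaled by the null-ensemble means:

    gamma = Cp / <Cp_null>,  lambda = Lp / <Lp_null>,  sigma = gamma/lambda,
    nEg = Eg / <Eg_null>,    nEloc = Eloc / <Eloc_null>.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .metrics import GlobalMetrics, WeightedGraph, global_metrics

__all__ = [
    "NullEnsembleSpec",
    "NormalizedMetrics",
    "rewire_preserving_degrees",
    "null_ensemble_metrics",
    "normalized_metrics",
]

_METRICS = ("cp", "lp", "eg", "eloc")


@dataclass(frozen=True)
class NullEnsembleSpec:
    """Ensemble size, rewiring intensity (attempted swaps per edge), seed."""

    n_null: int = 1000
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


@dataclass(frozen=True)
class NormalizedMetrics:
    gamma: float
    lam: float
    sigma: float
    neg: float
    neloc: float
    null_means: dict[str, float] = field(default_factory=dict)
    null_sds: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "gamma": self.gamma,
            "lam": self.lam,
            "sigma": self.sigma,
            "neg": self.neg,
            "neloc": self.neloc,
        }


def rewire_preserving_degrees(
    g: WeightedGraph, swaps_per_edge: int = 10, seed: int | None = None
) -> WeightedGraph:
    """One matched random network via double-edge swaps.

    Attempts ``swaps_per_edge * n_edges`` swaps; swaps creating self-loops
    or duplicate edges are rejected.  Node count, edge count, degree
    sequence and the multiset of edge weights are preserved exactly.
    """
    u, v, w = g.edge_list()
    n_edges = u.size
    if n_edges < 2:
        warnings.warn("graph has < 2 edges; returned unchanged", stacklevel=2)
        return WeightedGraph(g.weights.copy(), g.labels, g.modality)
    rng = np.random.default_rng(seed)
    attempts = swaps_per_edge * n_edges
    pick = rng.integers(0, n_edges, size=(attempts, 2))
    flip = rng.random(attempts) < 0.5
    present = {(int(a), int(b)) for a, b in zip(u, v)}
    u, v = u.copy(), v.copy()
    successes = 0
    for t in range(attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = u[e1], v[e1]
        c, d = (v[e2], u[e2]) if flip[t] else (u[e2], v[e2])
        if a == c or a == d or b == c or b == d:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in present or new2 in present:
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard((min(c, d), max(c, d)))
        present.add(new1)
        present.add(new2)
        u[e1], v[e1] = new1
        u[e2], v[e2] = new2
        successes += 1
    if successes == 0:
        warnings.warn(
            "no valid double-edge swap found; graph returned unchanged",
            stacklevel=2,
        )
    weights = np.zeros_like(g.weights)
    weights[u, v] = w
    weights[v, u] = w
    return WeightedGraph(weights, g.labels, g.modality)


def null_ensemble_metrics(
    g: WeightedGraph, spec: NullEnsembleSpec
) -> dict[str, np.ndarray]:
    """Cp/Lp/Eg/Eloc samples over ``spec.n_null`` rewired graphs."""
    children = np.random.SeedSequence([spec.seed]).spawn(spec.n_null)
    samples = {m: np.empty(spec.n_null) for m in _METRICS}
    for i, child in enumerate(children):
        null = rewire_preserving_degrees(g, spec.swaps_per_edge, child)
        gm = global_metrics(null)
        for m in _METRICS:
            samples[m][i] = getattr(gm, m)
    return samples


def normalized_metrics(
    g: WeightedGraph,
    spec: NullEnsembleSpec,
    observed: GlobalMetrics | None = None,
) -> NormalizedMetrics:
    """Observed metrics scaled by the matched-random-ensemble means.

    ``observed`` may pass pre-computed global metrics for the real graph;
    otherwise they are computed here.  Deterministic given ``spec.seed``.
    """
    gm = observed if observed is not None else global_metrics(g)
    samples = null_ensemble_metrics(g, spec)
    means = {m: float(samples[m].mean()) for m in _METRICS}
    sds = {m: float(samples[m].std(ddof=1)) if spec.n_null > 1 else 0.0 for m in _METRICS}
    for m, mu in means.items():
        if mu == 0:
            raise ValueError(f"null-ensemble mean of {m} is zero; cannot normalize")
    gamma = gm.cp / means["cp"]
    lam = gm.lp / means["lp"]
    return NormalizedMetrics(
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        neg=gm.eg / means["eg"],
        neloc=gm.eloc / means["eloc"],
        null_means=means,
        null_sds=sds,
    )
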