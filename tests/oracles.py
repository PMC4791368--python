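"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's code paths: distances come from
exhaustive enumeration of simple paths, clustering from a literal triple
loop, and efficiencies from the definitions applied to those quantities.
Only feasible for small graphs (<= ~8 nodes).
"""

from __future__ import annotations

import itertools

import numpy as np


def bf_clustering(weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Triple-loop geometric-mean clustering on max-normalized weights."""
    w = np.asarray(weights, dtype=float)
    mx = w.max()
    if mx == 0:
        return np.zeros(w.shape[0]), 0.0
    wn = w / mx
    n = w.shape[0]
    c = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                total += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1))
    return c, float(c.mean())


def bf_distances(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by exhaustive simple-path enumeration."""
    w = np.asarray(weights, dtype=float)
    mx = w.max()
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    if mx == 0:
        return d
    lengths = np.where(w > 0, mx / np.where(w > 0, w, 1.0), np.inf)

    def paths(src: int, dst: int) -> float:
        best = np.inf
        stack = [(src, {src}, 0.0)]
        while stack:
            node, seen, dist = stack.pop()
            if dist >= best:
                continue
            for nxt in range(n):
                if lengths[node, nxt] == np.inf or nxt in seen:
                    continue
                nd = dist + lengths[node, nxt]
                if nxt == dst:
                    best = min(best, nd)
                elif nd < best:
                    stack.append((nxt, seen | {nxt}, nd))
        return best

    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = paths(i, j)
    return d


def bf_components(weights: np.ndarray) -> list[set[int]]:
    n = weights.shape[0]
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            u = frontier.pop()
            for v in range(n):
                if weights[u, v] > 0 and v not in comp:
                    comp.add(v)
                    frontier.append(v)
        comps.append(comp)
        seen |= comp
    return comps


def bf_lp(weights: np.ndarray) -> float:
    comps = bf_components(weights)
    big = max(comps, key=len)
    if len(big) < 2:
        raise ValueError("no component with >= 2 nodes")
    d = bf_distances(weights)
    members = sorted(big)
    vals = [
        d[i, j] for i in members for j in members if i != j
    ]
    return float(np.mean(vals))


def bf_eg(weights: np.ndarray) -> float:
    n = weights.shape[0]
    if n < 2:
        return 0.0
    d = bf_distances(weights)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def bf_eloc(weights: np.ndarray) -> float:
    n = weights.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        total += bf_eg(sub)
    return total / n if n else 0.0


def bf_midrank(x: np.ndarray) -> np.ndarray:
    """Mid-ranks with ties averaged, computed by literal sorting."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks
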