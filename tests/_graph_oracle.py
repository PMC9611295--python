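"""Brute-force graph-metric oracle for small weighted networks.

Everything here is exhaustive enumeration — simple paths for shortest
paths, direct triple loops for triangles — deliberately independent of
the Dijkstra/vectorized implementations it is used to check.  Only
feasible for graphs of ≲ 8 nodes.
"""

from __future__ import annotations

import math

import numpy as np


def all_simple_path_lengths(w: np.ndarray, src: int, dst: int) -> list[float]:
    """Lengths (sum of 1/weight) of every simple src→dst path."""
    n = w.shape[0]
    out: list[float] = []

    def walk(node: int, visited: set[int], acc: float) -> None:
        if node == dst:
            out.append(acc)
            return
        for nxt in range(n):
            if w[node, nxt] > 0 and nxt not in visited:
                walk(nxt, visited | {nxt}, acc + 1.0 / w[node, nxt])

    walk(src, {src}, 0.0)
    return out


def brute_shortest_paths(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    lengths = np.full((n, n), np.inf)
    np.fill_diagonal(lengths, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            paths = all_simple_path_lengths(w, i, j)
            if paths:
                lengths[i, j] = min(paths)
    return lengths


def _components(w: np.ndarray) -> list[list[int]]:
    n = w.shape[0]
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], []
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.append(u)
            stack.extend(v for v in range(n) if w[u, v] > 0)
        comps.append(sorted(comp))
    return comps


def brute_characteristic_path_length(w: np.ndarray) -> float:
    """Mean shortest path over ordered pairs; largest component if split."""
    lengths = brute_shortest_paths(w)
    n = w.shape[0]
    if n < 2:
        return 0.0
    if np.isfinite(lengths[~np.eye(n, dtype=bool)]).all():
        return float(lengths[~np.eye(n, dtype=bool)].mean())
    giant = max(_components(w), key=len)
    if len(giant) < 2:
        return 0.0
    vals = [lengths[i, j] for i in giant for j in giant if i != j]
    return float(np.mean(vals))


def brute_clustering(w: np.ndarray) -> float:
    n = w.shape[0]
    if n == 0:
        return 0.0
    acc = 0.0
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        acc += 2.0 * (t / 2.0) / (k * (k - 1))
    return acc / n


def brute_global_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2:
        return 0.0
    lengths = brute_shortest_paths(w)
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(lengths[i, j]) and lengths[i, j] > 0:
                acc += 1.0 / lengths[i, j]
    return acc / (n * (n - 1))


def brute_local_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    acc = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        l_sub = brute_shortest_paths(sub)
        term = 0.0
        for a, j in enumerate(nbrs):
            for b, h in enumerate(nbrs):
                if j == h:
                    continue
                l = l_sub[a, b]
                if math.isfinite(l) and l > 0:
                    term += (w[i, j] * w[i, h] / l) ** (1.0 / 3.0)
        acc += term / (k * (k - 1))
    return acc / n if n else 0.0


def random_weighted_graph(rng: np.random.Generator, n_nodes: int,
                          density: float = 0.6) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.05, 1.0)
    return w
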