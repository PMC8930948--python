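"""Independent brute-force reference implementations for the graph metrics.

Everything here is deliberately naive — explicit loops, exhaustive path and
partition enumeration — and shares no code with the package's vectorized /
library-backed implementations.
"""

from __future__ import annotations

import numpy as np

INF = float("inf")


def bf_binary_distances(adj: np.ndarray) -> np.ndarray:
    """Floyd-Warshall on link counts."""
    n = adj.shape[0]
    d = np.full((n, n), INF)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_weighted_distances(weights: np.ndarray) -> np.ndarray:
    """Floyd-Warshall on edge lengths 1/weight (weight 0 = no traversable edge)."""
    n = weights.shape[0]
    d = np.full((n, n), INF)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_cpl(d: np.ndarray) -> float:
    """Mean over nodes of the mean finite distance to other nodes."""
    n = d.shape[0]
    terms = []
    for i in range(n):
        row = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        if row:
            terms.append(sum(row) / len(row))
    return sum(terms) / len(terms) if terms else float("nan")


def bf_efficiency(dw: np.ndarray) -> float:
    n = dw.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dw[i, j]) and dw[i, j] > 0:
                total += 1.0 / dw[i, j]
    return total / (n * (n - 1))


def bf_clustering(adj: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Directed clustering by direct evaluation of the triangle formula."""
    n = adj.shape[0]
    w = adj.astype(float) if weights is None else np.cbrt(weights)
    vals = []
    for i in range(n):
        num = 0.0
        for j in range(n):
            for h in range(n):
                num += (w[i, j] + w[j, i]) * (w[i, h] + w[h, i]) * (w[j, h] + w[h, j])
        num *= 0.5
        k_tot = int(adj[i, :].sum() + adj[:, i].sum())
        recip = int(sum(adj[i, j] * adj[j, i] for j in range(n)))
        den = k_tot * (k_tot - 1) - 2 * recip
        vals.append(num / den if den > 0 else 0.0)
    return float(np.mean(vals))


def _all_shortest_paths(adj: np.ndarray, h: int, j: int, d: np.ndarray) -> list[list[int]]:
    """Every shortest directed path from h to j, by depth-limited enumeration."""
    if not np.isfinite(d[h, j]) or h == j:
        return []
    target_len = int(d[h, j])
    paths = []

    def extend(path: list[int]) -> None:
        last = path[-1]
        if last == j:
            if len(path) - 1 == target_len:
                paths.append(path)
            return
        if len(path) - 1 >= target_len:
            return
        for nxt in range(adj.shape[0]):
            if adj[last, nxt] and nxt not in path:
                extend(path + [nxt])

    extend([h])
    return paths


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    """rho_hj(i)/rho_hj summed over pairs, normalized by (N-1)(N-2)."""
    n = adj.shape[0]
    d = bf_binary_distances(adj)
    b = np.zeros(n)
    for h in range(n):
        for j in range(n):
            if h == j:
                continue
            paths = _all_shortest_paths(adj, h, j, d)
            if not paths:
                continue
            for i in range(n):
                if i == h or i == j:
                    continue
                through = sum(1 for p in paths if i in p[1:-1])
                b[i] += through / len(paths)
    if n > 2:
        b /= (n - 1) * (n - 2)
    return b


def bf_modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    n = adj.shape[0]
    l = float(adj.sum())
    k_out = adj.sum(axis=1).astype(float)
    k_in = adj.sum(axis=0).astype(float)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - k_out[i] * k_in[j] / l
    return q / l


def _set_partitions(n: int):
    """All partitions of range(n) as label vectors (restricted growth strings)."""

    def grow(labels: list[int], k: int):
        if len(labels) == n:
            yield list(labels)
            return
        for lab in range(k + 1):
            labels.append(lab)
            yield from grow(labels, max(k, lab + 1))
            labels.pop()

    yield from grow([0], 1)


def bf_best_partition(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive max-modularity partition search (feasible for n <= 8)."""
    best_q, best = -np.inf, None
    for labels in _set_partitions(adj.shape[0]):
        q = bf_modularity(adj, np.array(labels))
        if q > best_q:
            best_q, best = q, np.array(labels)
    return best, float(best_q)


def bf_vulnerability(weights: np.ndarray) -> np.ndarray:
    e_full = bf_efficiency(bf_weighted_distances(weights))
    n = weights.shape[0]
    v = np.zeros(n)
    for i in range(n):
        keep = [k for k in range(n) if k != i]
        sub = weights[np.ix_(keep, keep)]
        v[i] = (e_full - bf_efficiency(bf_weighted_distances(sub))) / e_full
    return v


def bf_kappa(spikes: np.ndarray) -> float:
    """Mean pairwise Cohen's kappa over ordered cell pairs, frame count T."""
    n, T = spikes.shape
    vals = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            s_i, s_j = spikes[i].sum(), spikes[j].sum()
            c = int((spikes[i] * spikes[j]).sum())
            p_o = (2 * c + T - s_i - s_j) / T
            p_e = (s_i * s_j + (T - s_i) * (T - s_j)) / T**2
            vals.append((p_o - p_e) / (1 - p_e) if p_e < 1 else 0.0)
    return float(np.mean(vals))
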