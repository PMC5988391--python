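"""Independent brute-force oracles for graph diagnostics.

Everything here is deliberately naive and self-contained: Floyd-Warshall
distances, direct formula evaluation, and exhaustive partition search.
These implementations share no code with the package and exist only to
cross-check it on small graphs.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n <= 1:
        return 0.0
    dist = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                out[i] += 1.0 / dist[i, j]
        out[i] /= max(n - 1, 1)
    return out


def local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency(sub)
    return out


def modularity_q(adj: np.ndarray, labels) -> float:
    labels = np.asarray(labels)
    m2 = adj.sum()  # twice the edge count
    if m2 == 0:
        return 0.0
    k = adj.sum(axis=1)
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - k[i] * k[j] / m2
    return q / m2


def set_partitions(items):
    """All partitions of a list (Bell-number many; keep n small)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_partition_exhaustive(adj: np.ndarray):
    """Exhaustive maximum-modularity partition (n <= 8 or so)."""
    n = adj.shape[0]
    best_q, best_labels = -np.inf, None
    for part in set_partitions(range(n)):
        labels = np.empty(n, dtype=int)
        for ci, block in enumerate(part):
            for node in block:
                labels[node] = ci
        q = modularity_q(adj, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_labels, best_q


def within_module_z(adj: np.ndarray, labels) -> np.ndarray:
    labels = np.asarray(labels)
    n = adj.shape[0]
    kappa = np.array(
        [sum(adj[i, j] for j in range(n) if labels[j] == labels[i]) for i in range(n)],
        dtype=float,
    )
    z = np.zeros(n)
    for m in set(labels.tolist()):
        idx = [i for i in range(n) if labels[i] == m]
        mu = kappa[idx].mean()
        sd = kappa[idx].std()
        for i in idx:
            z[i] = (kappa[i] - mu) / sd if sd > 0 else 0.0
    return z


def participation(adj: np.ndarray, labels) -> np.ndarray:
    labels = np.asarray(labels)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = adj[i].sum()
        if k == 0:
            continue
        s = 0.0
        for m in set(labels.tolist()):
            kim = sum(adj[i, j] for j in range(n) if labels[j] == m)
            s += (kim / k) ** 2
        out[i] = 1.0 - s
    return out


def random_binary_graph(n: int, p: float, rng) -> np.ndarray:
    adj = (rng.random((n, n)) < p).astype(np.int8)
    adj = np.triu(adj, 1)
    return adj + adj.T
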