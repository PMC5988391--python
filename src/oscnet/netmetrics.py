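"""Fixed-density binary brain graphs and graph-theoretical diagnostics.

Per trial, the symmetric envelope-correlation matrix is reduced to a
binary undirected graph by keeping the top ``floor(density * N(N-1)/2)``
edges ranked by absolute correlation (default density 10%, alternative
5%).  Whole-brain diagnostics capture integration and segregation at
three topological scales:

* **global efficiency** — mean inverse shortest-path length over all
  ordered node pairs (disconnected pairs contribute 0);
* **mean local efficiency** — global efficiency of each node's
  neighbor-induced subgraph, averaged over nodes;
* **modularity Q** — Newman modularity of the best partition found by
  seeded Louvain with restarts.

Nodal diagnostics (strength, local efficiency, within-module z-score,
nodal efficiency, participation coefficient) localize the same
integration/segregation axes to single sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

DENSITY_DEFAULT = 0.10
DENSITY_ALTERNATIVE = 0.05


@dataclass
class BinaryGraph:
    """Binary undirected graph with the correlation weights of kept edges."""

    adjacency: np.ndarray  # (N, N) int8, symmetric, zero diagonal
    density: float
    retained_weights: np.ndarray  # correlation values of kept edges
    edges: np.ndarray  # (m, 2) upper-triangle indices of kept edges

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.retained_weights)


def _as_adj(g) -> np.ndarray:
    if isinstance(g, BinaryGraph):
        return g.adjacency
    a = np.asarray(g)
    return (a != 0).astype(np.int8)


def threshold_density(corr: np.ndarray, density: float = DENSITY_DEFAULT) -> BinaryGraph:
    """Keep the top ``floor(density * N(N-1)/2)`` edges by absolute correlation.

    Ties at the threshold boundary are broken deterministically by
    lexicographic (row, column) index order.

    Parameters
    ----------
    corr : ndarray (N, N)
        Symmetric correlation matrix; the diagonal is ignored.
    density : float
        Target edge density in (0, 1].
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("corr must be square")
    if not np.allclose(corr, corr.T, atol=1e-10, equal_nan=True):
        raise ValueError("corr must be symmetric")
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    n = corr.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = corr[iu, ju]
    m = int(np.floor(density * n * (n - 1) / 2))
    order = np.argsort(-np.abs(vals), kind="stable")[:m]
    order = np.sort(order)  # edges listed in lexicographic order
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[order], ju[order]] = 1
    adj |= adj.T
    return BinaryGraph(
        adjacency=adj,
        density=density,
        retained_weights=vals[order],
        edges=np.column_stack([iu[order], ju[order]]),
    )


def mean_fc(g: BinaryGraph) -> float:
    """Mean of the retained upper-triangle correlation values."""
    if g.n_edges == 0:
        raise ValueError("graph has no edges")
    return float(np.mean(g.retained_weights))


def strength(g) -> np.ndarray:
    """Nodal degree (binary strength)."""
    return _as_adj(g).sum(axis=1).astype(float)


def _distances(adj: np.ndarray) -> np.ndarray:
    if adj.shape[0] <= 1:
        return np.zeros(adj.shape, dtype=float)
    return shortest_path(csr_matrix(adj), method="D", unweighted=True)


def _efficiency_from_dist(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n <= 1:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(g) -> float:
    """Mean inverse shortest-path length over all ordered node pairs."""
    return _efficiency_from_dist(_distances(_as_adj(g)))


def nodal_efficiency(g) -> np.ndarray:
    """Per node, the mean inverse distance to every other node.

    The average of nodal efficiencies equals the global efficiency.
    """
    adj = _as_adj(g)
    n = adj.shape[0]
    if n <= 1:
        return np.zeros(n)
    dist = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(g) -> tuple[np.ndarray, float]:
    """Global efficiency of each node's neighbor-induced subgraph.

    Nodes with fewer than two neighbors score 0.

    Returns
    -------
    (per_node, mean) : (ndarray, float)
    """
    adj = _as_adj(g)
    n = adj.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if len(nbrs) < 2:
            continue
        per_node[i] = global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return per_node, float(per_node.mean()) if n else 0.0


def modularity(g, seed: int = 0, n_restarts: int = 10) -> tuple[np.ndarray, float]:
    """Community partition maximizing Newman modularity via seeded Louvain.

    Louvain is run ``n_restarts`` times with consecutive seeds and the
    partition with the highest Q is returned.

    Returns
    -------
    (labels, Q) : (ndarray of int, float)
        ``labels[i]`` is the community index of node i; Q is evaluated on
        the returned partition.
    """
    adj = _as_adj(g)
    if adj.sum() == 0:
        raise ValueError("modularity requires at least one edge")
    G = nx.from_numpy_array(adj.astype(float))
    best_q, best = -np.inf, None
    for k in range(n_restarts):
        communities = nx.community.louvain_communities(G, seed=seed + k)
        q = nx.community.modularity(G, communities)
        if q > best_q:
            best_q, best = q, communities
    labels = np.empty(adj.shape[0], dtype=int)
    for ci, comm in enumerate(best):
        for node in comm:
            labels[node] = ci
    return labels, float(best_q)


def within_module_z(g, labels: np.ndarray) -> np.ndarray:
    """Within-module degree z-score per node.

    ``z_i = (kappa_i - mean kappa in module) / sd kappa in module`` with
    kappa the within-module degree; modules with zero spread give z = 0.
    """
    adj = _as_adj(g)
    labels = np.asarray(labels)
    if len(labels) != adj.shape[0]:
        raise ValueError("partition must cover all nodes")
    same = labels[:, None] == labels[None, :]
    kappa = (adj * same).sum(axis=1).astype(float)
    z = np.zeros(len(labels))
    for m in np.unique(labels):
        sel = labels == m
        mu, sd = kappa[sel].mean(), kappa[sel].std()
        if sd > 0:
            z[sel] = (kappa[sel] - mu) / sd
    return z


def participation(g, labels: np.ndarray) -> np.ndarray:
    """Participation coefficient ``P_i = 1 - sum_m (kappa_im / k_i)**2``.

    Isolated nodes score 0.
    """
    adj = _as_adj(g)
    labels = np.asarray(labels)
    if len(labels) != adj.shape[0]:
        raise ValueError("partition must cover all nodes")
    k = adj.sum(axis=1).astype(float)
    p = np.zeros(len(labels))
    nz = k > 0
    acc = np.zeros(len(labels))
    for m in np.unique(labels):
        kim = adj[:, labels == m].sum(axis=1).astype(float)
        acc[nz] += (kim[nz] / k[nz]) ** 2
    p[nz] = 1.0 - acc[nz]
    return p


WHOLE_BRAIN_METRICS = (
    "mean_fc",
    "local_efficiency",
    "modularity",
    "global_efficiency",
)


def trial_metrics(
    corr: np.ndarray,
    density: float = DENSITY_DEFAULT,
    metrics=WHOLE_BRAIN_METRICS,
    seed: int = 0,
    n_restarts: int = 10,
) -> dict:
    """Whole-brain diagnostics of one trial's correlation matrix."""
    g = threshold_density(corr, density)
    out = {}
    for name in metrics:
        if name == "mean_fc":
            out[name] = mean_fc(g)
        elif name == "global_efficiency":
            out[name] = global_efficiency(g)
        elif name == "local_efficiency":
            out[name] = local_efficiency(g)[1]
        elif name == "modularity":
            out[name] = modularity(g, seed=seed, n_restarts=n_restarts)[1]
        else:
            raise ValueError(f"unknown whole-brain metric {name!r}")
    return out


def network_series(
    conn,
    density: float = DENSITY_DEFAULT,
    metrics=WHOLE_BRAIN_METRICS,
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """Per-trial whole-brain metric series for a :class:`ConnectivityStack`.

    Parameters
    ----------
    conn : ConnectivityStack or ndarray (trials, N, N)
    density : float
    metrics : sequence of str
        Subset of ``WHOLE_BRAIN_METRICS``.
    seed : int
        Base seed for Louvain (offset per trial for reproducibility).

    Returns
    -------
    pandas.DataFrame with one row per trial and one column per metric.
    """
    stack = conn.corr if hasattr(conn, "corr") else np.asarray(conn)
    rows = [
        trial_metrics(
            stack[t], density=density, metrics=metrics, seed=seed + 101 * t,
            n_restarts=n_restarts,
        )
        for t in range(stack.shape[0])
    ]
    return pd.DataFrame(rows)


def nodal_metrics(
    corr: np.ndarray,
    density: float = DENSITY_DEFAULT,
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """All nodal diagnostics of one trial's correlation matrix."""
    g = threshold_density(corr, density)
    labels, _ = modularity(g, seed=seed, n_restarts=n_restarts)
    return pd.DataFrame(
        {
            "strength": strength(g),
            "local_efficiency": local_efficiency(g)[0],
            "within_module_z": within_module_z(g, labels),
            "nodal_efficiency": nodal_efficiency(g),
            "participation": participation(g, labels),
        }
    )
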