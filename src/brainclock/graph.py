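"""Global and local efficiency of binarized connectivity networks.

Global efficiency E (integration) is the mean inverse shortest-path length,

    E = (1/n) sum_i E_i,   E_i = sum_{j != i} d_ij^{-1} / (n - 1),

with 1/inf = 0 for disconnected pairs, so E in [0, 1] with the upper bound
attained by the complete graph. Local efficiency L (segregation) averages,
over nodes with degree >= 2, the efficiency of the subgraph induced by each
node's neighborhood:

    L = (1/n) sum_i [1 / (k_i (k_i - 1))] sum_{j != h in G(i)} 1 / d_jh,

where d_jh is the shortest path between neighbors j, h computed inside the
induced neighborhood subgraph. Nodes with k_i < 2 contribute 0. FC matrices
are binarized at proportional thresholds (default 0.02-0.10 in steps of
0.01) and the metrics are averaged over the threshold range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import ConnectivityMatrix, proportional_threshold

DEFAULT_RHO_GRID = tuple(np.round(np.arange(0.02, 0.101, 0.01), 2))


def _binary(adj) -> np.ndarray:
    if isinstance(adj, ConnectivityMatrix):
        if adj.kind != "binary":
            raise ValueError("expected a binary matrix")
        return adj.values
    a = np.asarray(adj, float)
    if not np.isin(a, (0.0, 1.0)).all() or np.any(np.diag(a) != 0):
        raise ValueError("expected a 0/1 adjacency matrix with zero diagonal")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    return a


def shortest_paths(adj) -> np.ndarray:
    """Hop-count shortest-path matrix (inf for unreachable pairs)."""
    a = _binary(adj)
    return _csgraph_shortest_path(a, method="D", unweighted=True)


def global_efficiency(adj) -> float:
    a = _binary(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    d = shortest_paths(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(adj) -> float:
    a = _binary(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(a[i])
        k = nb.size
        if k < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        d = _csgraph_shortest_path(sub, method="D", unweighted=True)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        total += inv.sum() / (k * (k - 1))
    return total / n


@dataclass
class GraphMetricsResult:
    per_threshold: list  # of dicts {rho, global_eff, local_eff}
    mean_global_eff: float
    mean_local_eff: float


def efficiency_over_thresholds(
    fc: ConnectivityMatrix, rho_values=DEFAULT_RHO_GRID
) -> GraphMetricsResult:
    """Binarize at each proportional threshold and average the metrics."""
    rho_values = list(rho_values)
    if not rho_values:
        raise ValueError("rho_values must be nonempty")
    rows = []
    for rho in rho_values:
        b = proportional_threshold(fc, rho)
        rows.append({
            "rho": float(rho),
            "global_eff": global_efficiency(b),
            "local_eff": local_efficiency(b),
        })
    return GraphMetricsResult(
        rows,
        float(np.mean([r["global_eff"] for r in rows])),
        float(np.mean([r["local_eff"] for r in rows])),
    )
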