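"""Weighted-network integration and segregation metrics.

Each subject's FC matrix defines a weighted undirected graph (negative
correlations zeroed, diagonal removed).  The graph is thresholded at a
sweep of sparsity levels — the proportion of strongest edges retained,
by default 5% to 50% in 5% steps — and at each level two efficiency
metrics are computed with edge lengths 1/w:

* global efficiency, the mean inverse weighted shortest path length
  over all node pairs (integration);
* local efficiency, the mean over nodes i of
  sum_{j!=h} (w_ij w_ih / d_jh(N_i))^(1/3) / (k_i (k_i - 1)), where
  d_jh(N_i) is the shortest path between neighbors j and h restricted
  to the subgraph induced by i's neighbors (segregation).

The trapezoidal area under each metric's sparsity curve summarizes it
independently of any single threshold, and AUCs are compared between
groups with a pooled-variance two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

#: Default sparsity sweep: 5% to 50% in 5% increments.
DEFAULT_SPARSITIES = tuple(np.round(np.arange(1, 11) * 0.05, 2))


@dataclass
class WeightedGraph:
    """Nonnegative symmetric adjacency with zero diagonal."""

    adjacency: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.adjacency, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if np.abs(w - w.T).max(initial=0.0) > 1e-10:
            raise ValueError("adjacency must be symmetric")
        if (w < 0).any():
            raise ValueError("adjacency weights must be nonnegative")
        if np.abs(np.diag(w)).max(initial=0.0) != 0:
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = w

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int((self.adjacency[np.triu_indices(self.n_nodes, 1)] > 0).sum())


@dataclass
class EfficiencyCurve:
    """Efficiency metrics across the sparsity sweep and their AUCs."""

    sparsities: np.ndarray
    eg_values: np.ndarray
    eloc_values: np.ndarray
    eg_auc: float
    eloc_auc: float


@dataclass
class GroupComparison:
    """Pooled-variance two-sample t-test summary."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float


def prepare_weighted_graph(
    matrix: ConnectivityMatrix | np.ndarray,
    negative: str = "zero",
) -> WeightedGraph:
    """Weighted undirected graph from a correlation matrix.

    Zeroes the diagonal and, by default, sets negative correlations to
    zero (the efficiency formulas need nonnegative weights);
    ``negative="absolute"`` takes magnitudes instead.
    """
    if isinstance(matrix, ConnectivityMatrix):
        values, labels = matrix.values, list(matrix.roi_labels)
    else:
        values = np.asarray(matrix, dtype=float)
        labels = [f"roi_{i + 1}" for i in range(values.shape[0])]
    if np.abs(values - values.T).max(initial=0.0) > 1e-10:
        raise ValueError("connectivity matrix must be symmetric")
    if negative == "zero":
        w = np.where(values > 0, values, 0.0)
    elif negative == "absolute":
        w = np.abs(values)
    else:
        raise ValueError("negative must be 'zero' or 'absolute'")
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(adjacency=w, node_labels=labels)


def threshold_by_sparsity(graph: WeightedGraph, sparsity: float) -> WeightedGraph:
    """Retain the strongest edges at a given sparsity level.

    Keeps exactly ``round(sparsity * n(n-1)/2)`` edges (round half away
    from zero), ranked by descending weight with ties broken by
    ascending node-pair index; all other weights are zeroed.  If fewer
    nonzero edges exist than requested, all are kept with a warning.
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must lie in (0, 1]; got {sparsity}")
    n = graph.n_nodes
    n_possible = n * (n - 1) // 2
    target = int(np.floor(sparsity * n_possible + 0.5))
    iu, ju = np.triu_indices(n, k=1)
    weights = graph.adjacency[iu, ju]
    nonzero = np.flatnonzero(weights > 0)
    if nonzero.size < target:
        warnings.warn(
            f"only {nonzero.size} nonzero edges available for target {target}; "
            "keeping all",
            stacklevel=2,
        )
        keep = nonzero
    else:
        order = np.lexsort((nonzero, -weights[nonzero]))
        keep = nonzero[order[:target]]
    out = np.zeros_like(graph.adjacency)
    out[iu[keep], ju[keep]] = weights[keep]
    out += out.T
    return WeightedGraph(adjacency=out, node_labels=list(graph.node_labels))


def _length_matrix(adjacency: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(adjacency > 0, 1.0 / adjacency, 0.0)
    return lengths


def weighted_shortest_paths(graph: WeightedGraph | np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest path lengths with edge length 1/w.

    Unreachable pairs get +inf; the diagonal is 0.
    """
    adjacency = graph.adjacency if isinstance(graph, WeightedGraph) else np.asarray(graph, float)
    if adjacency.shape[0] == 0:
        return np.zeros((0, 0))
    return shortest_path(_length_matrix(adjacency), method="D", directed=False)


def global_efficiency(graph: WeightedGraph) -> float:
    """Mean inverse weighted shortest path length over all node pairs.

    Unreachable pairs contribute 0; a complete unit-weight graph gives
    exactly 1.
    """
    n = graph.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    d = weighted_shortest_paths(graph)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(graph: WeightedGraph) -> float:
    """Mean nodal efficiency of each node's neighbor subgraph.

    For node i with neighbors N_i (k_i of them), paths between
    neighbors may not leave N_i; nodes with fewer than two neighbors
    contribute 0.
    """
    w = graph.adjacency
    n = graph.n_nodes
    if n < 2:
        raise ValueError("local efficiency needs at least 2 nodes")
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        # Floyd-Warshall beats Dijkstra's per-call overhead on the many
        # small dense neighbor subgraphs this loop visits.
        d = shortest_path(_length_matrix(sub), method="FW", directed=False)
        with np.errstate(divide="ignore"):
            invd = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
        np.fill_diagonal(invd, 0.0)
        wi = w[i, nbrs]
        terms = np.cbrt(np.outer(wi, wi) * invd)
        total += terms.sum() / (k * (k - 1))
    return float(total / n)


def trapezoid_auc(x: np.ndarray, y: np.ndarray) -> float:
    """Trapezoidal area under y(x); units are metric x axis-width."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need matching x/y with at least 2 points")
    return float(np.trapezoid(y, x))


def efficiency_curve(
    matrix: ConnectivityMatrix | np.ndarray | WeightedGraph,
    sparsities=DEFAULT_SPARSITIES,
    negative: str = "zero",
) -> EfficiencyCurve:
    """Global/local efficiency across the sparsity sweep, plus AUCs."""
    sparsities = np.asarray(sparsities, dtype=float)
    if sparsities.size < 2 or np.any(np.diff(sparsities) <= 0):
        raise ValueError("sparsities must be strictly increasing with >= 2 values")
    if np.any((sparsities <= 0) | (sparsities > 1)):
        raise ValueError("sparsities must lie in (0, 1]")
    graph = matrix if isinstance(matrix, WeightedGraph) else prepare_weighted_graph(matrix, negative)
    eg = np.empty(sparsities.size)
    eloc = np.empty(sparsities.size)
    for s, sparsity in enumerate(sparsities):
        thresholded = threshold_by_sparsity(graph, float(sparsity))
        eg[s] = global_efficiency(thresholded)
        eloc[s] = local_efficiency(thresholded)
    return EfficiencyCurve(
        sparsities=sparsities,
        eg_values=eg,
        eloc_values=eloc,
        eg_auc=trapezoid_auc(sparsities, eg),
        eloc_auc=trapezoid_auc(sparsities, eloc),
    )


def compare_groups(values_a, values_b) -> GroupComparison:
    """Pooled-variance two-sample t-test (df = n1 + n2 - 2), two-sided."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance; t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        t_statistic=float(t),
        degrees_of_freedom=a.size + b.size - 2,
        p_value=float(p),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
    )
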