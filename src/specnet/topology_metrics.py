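"""Threshold sweep and topological metric extraction for weighted cliques.

Each subject's weighted clique is binarized at a grid of thresholds (edge
present iff w > tau, strictly, so tau = 1 always yields the empty graph)
and a fixed vector of topological metrics is computed from each resulting
unweighted graph.  The metric vector spans micro-scale structure (triangle
and open-triad motif counts, clustering), meso-scale structure (greedy
modularity), and macro-scale structure (efficiency, diameter of the
largest component, component counts) so that both the dense-graph and
sparse-graph classification regimes are covered.

Degenerate graphs use fixed conventions so the downstream feature matrix
stays finite: clustering is 0 without open triads, the diameter is 0 for
edgeless graphs, assortativity is 0 when the degree variance at edge
endpoints is 0, and modularity is 0 for edgeless graphs.

Implementation notes: metric extraction sits in the inner loop of
cross-validated evaluation (subjects x thresholds x folds graphs), so the
metrics are computed with dense numpy linear algebra and
``scipy.sparse.csgraph`` rather than per-graph networkx calls; community
detection uses igraph's deterministic fast-greedy modularity maximization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

METRIC_NAMES = (
    "link_density",
    "mean_degree",
    "degree_std",
    "clustering_coefficient",
    "assortativity",
    "efficiency",
    "diameter_lcc",
    "n_components",
    "largest_component_fraction",
    "modularity",
    "triangle_count",
    "open_triad_count",
)

N_METRICS = len(METRIC_NAMES)


@dataclass
class ThresholdGrid:
    """Strictly increasing binarization thresholds in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("grid must be a non-empty 1-D sequence")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("thresholds must lie in [0, 1]")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def default_grid() -> ThresholdGrid:
    """0.00 to 1.00 in steps of 0.05 (21 values)."""
    return ThresholdGrid(np.round(np.linspace(0.0, 1.0, 21), 2))


@dataclass
class MetricVector:
    """Named topological metrics for one (subject, threshold) graph."""

    subject_id: object
    threshold: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_METRICS,):
            raise ValueError(f"expected {N_METRICS} metric values")

    def as_dict(self) -> dict:
        return dict(zip(METRIC_NAMES, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[METRIC_NAMES.index(name)])


def threshold_network(net, tau: float) -> np.ndarray:
    """Boolean adjacency of the clique binarized at tau (edge iff w > tau)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    w = net.weight_matrix()
    adj = w > tau
    np.fill_diagonal(adj, False)
    return adj


def greedy_modularity(adj: np.ndarray) -> tuple[float, np.ndarray]:
    """Deterministic fast-greedy (CNM) modularity and community membership.

    Edgeless graphs return modularity 0 with every node its own community.
    """
    a = np.asarray(adj, dtype=bool)
    k = a.shape[0]
    ii, jj = np.nonzero(np.triu(a, 1))
    if len(ii) == 0:
        return 0.0, np.arange(k)
    import igraph as ig

    g = ig.Graph(n=k, edges=list(zip(ii.tolist(), jj.tolist())))
    clustering = g.community_fastgreedy().as_clustering()
    membership = np.asarray(clustering.membership)
    return float(g.modularity(membership)), membership


def compute_metrics(adjacency: np.ndarray, subject_id=None, tau=np.nan) -> MetricVector:
    """Extract the fixed metric vector from one binarized graph.

    ``adjacency`` is a symmetric boolean/0-1 matrix with empty diagonal on
    the k selected nodes.  All metrics follow their standard undirected,
    unweighted definitions; see the module docstring for degenerate-graph
    conventions.
    """
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    a = a.astype(bool)
    if np.any(a != a.T) or np.any(np.diag(a)):
        raise ValueError("adjacency must be symmetric with empty diagonal")
    k = a.shape[0]
    af = a.astype(float)
    deg = af.sum(axis=0)
    n_edges = int(round(deg.sum() / 2))

    density = (2 * n_edges / (k * (k - 1))) if k > 1 else 0.0
    mean_degree = float(deg.mean()) if k else 0.0
    degree_std = float(deg.std()) if k else 0.0

    triangles = float(np.trace(af @ af @ af)) / 6.0
    triads_total = float(np.sum(deg * (deg - 1)) / 2.0)  # paths of length 2
    clustering = 3.0 * triangles / triads_total if triads_total > 0 else 0.0
    open_triads = triads_total - 3.0 * triangles

    if n_edges > 0:
        ii, jj = np.nonzero(np.triu(a, 1))
        x = np.concatenate([deg[ii], deg[jj]])
        y = np.concatenate([deg[jj], deg[ii]])
        if x.std() > 0:
            assortativity = float(np.corrcoef(x, y)[0, 1])
            if not np.isfinite(assortativity):
                assortativity = 0.0
        else:
            assortativity = 0.0
    else:
        assortativity = 0.0

    n_comp, comp_labels = connected_components(csr_matrix(a), directed=False)
    comp_sizes = np.bincount(comp_labels)
    largest_fraction = float(comp_sizes.max() / k) if k else 0.0

    if n_edges > 0 and k > 1:
        dist = shortest_path(csr_matrix(af), method="D", unweighted=True)
        off = ~np.eye(k, dtype=bool)
        finite = np.isfinite(dist) & off
        inv = np.zeros_like(dist)
        inv[finite] = 1.0 / dist[finite]
        efficiency = float(inv[off].sum() / (k * (k - 1)))
        # diameter of the largest component; ties broken by the component
        # containing the smallest node index (bincount argmax)
        lcc = comp_labels == int(np.argmax(comp_sizes))
        sub = dist[np.ix_(lcc, lcc)]
        diameter = float(sub[np.isfinite(sub)].max())
    else:
        efficiency = 0.0
        diameter = 0.0

    modularity, _ = greedy_modularity(a)

    values = np.array(
        [
            density,
            mean_degree,
            degree_std,
            clustering,
            assortativity,
            efficiency,
            diameter,
            float(n_comp),
            largest_fraction,
            modularity,
            triangles,
            open_triads,
        ]
    )
    return MetricVector(subject_id=subject_id, threshold=float(tau), values=values)


def sweep(net, grid: ThresholdGrid | None = None) -> list[MetricVector]:
    """One metric vector per threshold, in grid order."""
    if grid is None:
        grid = default_grid()
    w = net.weight_matrix()
    out = []
    for tau in grid:
        adj = w > tau
        np.fill_diagonal(adj, False)
        out.append(compute_metrics(adj, subject_id=net.subject_id, tau=tau))
    return out


def metrics_frame(vectors) -> "pd.DataFrame":
    """Long-format table: subject_id, threshold, one column per metric."""
    import pandas as pd

    rows = [
        {"subject_id": v.subject_id, "threshold": v.threshold, **v.as_dict()}
        for v in vectors
    ]
    return pd.DataFrame(rows)
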