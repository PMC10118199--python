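"""Node- and graph-level topology descriptors, and their PCA reduction.

Node strengths are absolute-weight degree sums: instrength of gene i is
sum_j |w_ij| (how strongly it is regulated), outstrength of gene j is
sum_i |w_ij| (how strongly it regulates).  Graph-level descriptors are
computed on the unweighted directed edge set (edge iff w != 0).  A panel of
12 descriptors per network is reduced to two synthetic axes by PCA on the
correlation matrix; the axes are sign-oriented so that diameter loads
positively on PC1 ("synthetic diameter and centralization") and average
degree positively on PC2 ("synthetic average degree").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .topology import WeightedDigraph

__all__ = [
    "node_strengths",
    "graph_metrics",
    "synthetic_axes",
    "GRAPH_METRIC_COLUMNS",
]

GRAPH_METRIC_COLUMNS = [
    "diameter",
    "mean_path_distance",
    "indegree_centralization",
    "outdegree_centralization",
    "closeness_centralization",
    "betweenness_centralization",
    "average_degree",
    "average_indegree",
    "average_outdegree",
    # configurable extras completing the 12-descriptor panel
    "reciprocity",
    "clustering",
    "mean_betweenness",
]


def node_strengths(graph: WeightedDigraph) -> pd.DataFrame:
    """Per-gene instrength and outstrength (absolute-weight sums)."""
    absw = np.abs(graph.weights)
    return pd.DataFrame(
        {
            "gene": np.arange(graph.n_genes),
            "instrength": absw.sum(axis=1),
            "outstrength": absw.sum(axis=0),
        }
    )


def _centralization(scores: np.ndarray, denominator: float) -> float:
    return float((scores.max() - scores).sum() / denominator)


def graph_metrics(graph: WeightedDigraph, extras: bool = True) -> pd.Series:
    """Graph-level descriptors of the unweighted directed edge set.

    Distances are directed shortest-path lengths; unreachable ordered pairs
    are excluded from the diameter and the mean path distance, and closeness
    uses the harmonic form (unreachable pairs contribute 0), so every value
    is finite on weakly connected graphs.  Centralizations are Freeman-style
    (sum of max-minus-score over nodes) normalized by a documented
    theoretical maximum: (n-1)^2 for in/out-degree (a directed star),
    (n-1) for harmonic closeness normalized to [0, 1], and (n-1)^2 (n-2)
    for directed betweenness.
    """
    g = graph.to_networkx()
    n = graph.n_genes
    if not graph.skeleton_connected():
        raise ValueError("graph_metrics requires a connected skeleton")
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    finite = [d for src, dd in lengths.items() for dst, d in dd.items() if src != dst]
    diameter = float(max(finite)) if finite else 0.0
    mean_path = float(np.mean(finite)) if finite else 0.0
    indeg = np.array([d for _, d in g.in_degree()], dtype=float)
    outdeg = np.array([d for _, d in g.out_degree()], dtype=float)
    harm = np.array([nx.harmonic_centrality(g)[v] for v in range(n)]) / (n - 1)
    btw = np.array([nx.betweenness_centrality(g, normalized=False)[v] for v in range(n)])
    metrics = {
        "diameter": diameter,
        "mean_path_distance": mean_path,
        "indegree_centralization": _centralization(indeg, (n - 1) ** 2),
        "outdegree_centralization": _centralization(outdeg, (n - 1) ** 2),
        "closeness_centralization": _centralization(harm, n - 1),
        "betweenness_centralization": _centralization(btw, (n - 1) ** 2 * (n - 2)),
        "average_degree": float((indeg + outdeg).mean()),
        "average_indegree": float(indeg.mean()),
        "average_outdegree": float(outdeg.mean()),
    }
    if extras:
        metrics["reciprocity"] = float(nx.reciprocity(g) or 0.0)
        metrics["clustering"] = float(nx.transitivity(g.to_undirected()))
        metrics["mean_betweenness"] = float(btw.mean())
    return pd.Series(metrics)


@dataclass
class SyntheticAxes:
    scores: pd.DataFrame  # per-network PC1, PC2
    loadings: pd.DataFrame  # metric x (PC1, PC2)
    explained_variance_ratio: np.ndarray  # all components, non-increasing


def synthetic_axes(metrics_table: pd.DataFrame) -> SyntheticAxes:
    """Reduce a per-network metrics table to two synthetic axes.

    Columns are standardized to zero mean and unit variance (constant
    columns are dropped with a warning) and the correlation matrix is
    eigendecomposed.  Signs are oriented so diameter loads positively on
    PC1 and average_degree positively on PC2, matching the convention of
    reporting PC1 as "synthetic diameter and centralization" and PC2 as
    "synthetic average degree".
    """
    if len(metrics_table) < 3:
        raise ValueError("need at least 3 networks for a PCA")
    x = metrics_table.select_dtypes(include=[np.number]).copy()
    std = x.std(axis=0, ddof=1)
    constant = std[std == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping zero-variance metric column(s): {constant}")
        x = x.drop(columns=constant)
        std = std.drop(index=constant)
    if x.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant metric columns; no axes")
    z = (x - x.mean(axis=0)) / std
    corr = np.cov(z.to_numpy(), rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    ratio = evals / evals.sum()
    load = evecs[:, :2].copy()
    cols = list(x.columns)
    for pc, anchor in enumerate(("diameter", "average_degree")):
        if anchor in cols and load[cols.index(anchor), pc] < 0:
            load[:, pc] = -load[:, pc]
    scores = z.to_numpy() @ load
    score_df = pd.DataFrame(scores, columns=["PC1", "PC2"], index=metrics_table.index)
    load_df = pd.DataFrame(load, columns=["PC1", "PC2"], index=cols)
    return SyntheticAxes(scores=score_df, loadings=load_df,
                         explained_variance_ratio=ratio)
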