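"""Weighted directed network topologies founding each simulated population.

A topology is a signed, weighted regulatory matrix W where entry ``(i, j)``
is the effect of gene ``j`` on gene ``i`` (positive = activation, negative =
repression, zero = no regulation).  Generated graphs have no autoregulation
(zero diagonal), a connected undirected skeleton, and nonzero weights drawn
i.i.d. from a uniform distribution (default U(-3, 3)).

Density of a directed graph without self-loops is defined as
``edges / (n * (n - 1))``; the generators target ``round(d * n * (n - 1))``
directed edges.  The Barabási–Albert and Watts–Strogatz constructions are
natively undirected: the undirected skeleton is built first and each edge is
then oriented uniformly at random, which preserves the edge-count parity
with the Erdős–Rényi draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .rng import substream

__all__ = [
    "WeightedDigraph",
    "generate_topology",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
]

_MODELS = ("ER", "BA", "WS")


@dataclass
class WeightedDigraph:
    """A weighted directed regulatory network.

    Attributes
    ----------
    weights:
        n x n real matrix; entry (i, j) is the regulatory effect of gene j
        on gene i.  Zero diagonal (no autoregulation).
    topology_model:
        One of "ER", "BA", "WS" or "user".
    seed:
        Seed used to generate the graph (None for user-supplied graphs).
    """

    weights: np.ndarray
    topology_model: str = "user"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        if self.weights.shape[0] < 2:
            raise ValueError("need at least 2 genes")

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of directed edges (nonzero off-diagonal entries)."""
        return int(np.count_nonzero(self.weights))

    def edge_mask(self) -> np.ndarray:
        """Boolean n x n mask of directed edges."""
        return self.weights != 0

    def skeleton_connected(self) -> bool:
        """True iff the undirected skeleton (edge iff w_ij or w_ji nonzero)
        forms a single component."""
        return nx.is_connected(self.to_networkx().to_undirected())

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with edge j -> i for each nonzero w_ij."""
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_genes))
        rows, cols = np.nonzero(self.weights)
        g.add_weighted_edges_from(
            (int(j), int(i), float(self.weights[i, j])) for i, j in zip(rows, cols)
        )
        return g

    def validate(self, weight_low: float | None = None, weight_high: float | None = None) -> None:
        """Raise ValueError on any violated structural invariant."""
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("autoregulation present: nonzero diagonal entries")
        if not self.skeleton_connected():
            raise ValueError("undirected skeleton is not connected")
        w = self.weights[self.weights != 0]
        if weight_low is not None and w.size and (w.min() < weight_low or w.max() > weight_high):
            raise ValueError("nonzero weights outside the configured range")


def _target_edges(n_genes: int, density: float) -> int:
    return int(round(density * n_genes * (n_genes - 1)))


def _undirected_target(m_directed: int) -> int:
    # BA/WS build an undirected skeleton first; each undirected edge becomes
    # exactly one directed edge, so the skeleton targets the same count.
    return m_directed


def _skeleton(model: str, n: int, m_edges: int, rng: np.random.Generator) -> nx.Graph:
    nx_seed = int(rng.integers(2**31))
    if model == "ER":
        g = nx.gnm_random_graph(n, m_edges, seed=nx_seed, directed=True)
        return g
    if model == "BA":
        # Preferential attachment adds m edges per new node: n0 = m + 1 seed
        # nodes, (n - n0) * m edges.  Choose m to get close to the target,
        # then trim/grow by random edge deletion/insertion.
        m = max(1, round(m_edges / max(n - 2, 1)))
        g = nx.barabasi_albert_graph(n, m, seed=nx_seed)
    elif model == "WS":
        # Ring lattice with k neighbours per node has n*k/2 edges; k must be
        # even.  Rewire with probability 0.1 (small-world regime).
        k = max(2, 2 * round(m_edges / n))
        if k >= n:
            k = n - 1 if (n - 1) % 2 == 0 else n - 2
        g = nx.watts_strogatz_graph(n, k, 0.1, seed=nx_seed)
    else:
        raise ValueError(f"unknown topology model {model!r}; expected one of {_MODELS}")
    _adjust_edge_count(g, m_edges, rng)
    return g


def _adjust_edge_count(g: nx.Graph, target: int, rng: np.random.Generator) -> None:
    """Randomly delete/add undirected edges until ``g`` has ``target`` edges."""
    while g.number_of_edges() > target:
        edges = list(g.edges())
        u, v = edges[rng.integers(len(edges))]
        g.remove_edge(u, v)
    n = g.number_of_nodes()
    while g.number_of_edges() < target:
        u, v = rng.integers(n, size=2)
        if u != v and not g.has_edge(int(u), int(v)):
            g.add_edge(int(u), int(v))


def _orient_and_weight(
    g, n: int, weight_low: float, weight_high: float, rng: np.random.Generator
) -> np.ndarray:
    weights = np.zeros((n, n))
    directed = g.is_directed()
    for u, v in g.edges():
        if directed:
            src, dst = u, v
        else:  # orient uniformly at random to a single direction
            src, dst = (u, v) if rng.random() < 0.5 else (v, u)
        w = rng.uniform(weight_low, weight_high)
        while w == 0.0:  # probability-zero; keeps "edge iff nonzero" well defined
            w = rng.uniform(weight_low, weight_high)
        weights[dst, src] = w
    return weights


def generate_topology(
    model: str,
    n_genes: int = 40,
    density: float = 0.05,
    weight_low: float = -3.0,
    weight_high: float = 3.0,
    seed: int = 0,
    max_retries: int = 1000,
) -> WeightedDigraph:
    """Generate a connected weighted directed network without autoregulation.

    Parameters
    ----------
    model:
        "ER" (Erdős–Rényi), "BA" (Barabási–Albert scale-free) or "WS"
        (Watts–Strogatz small-world).
    n_genes:
        Number of nodes (>= 2).
    density:
        Directed density d; the generator targets round(d * n * (n-1))
        directed edges.
    weight_low, weight_high:
        Bounds of the uniform weight distribution.
    seed:
        Root seed; the same (model, n_genes, density, seed) always yields a
        bitwise-identical weight matrix.
    max_retries:
        Rejection-sampling cap for the connectivity requirement.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown topology model {model!r}; expected one of {_MODELS}")
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if not 0.0 < density < 1.0:
        raise ValueError("density must lie strictly in (0, 1)")
    if weight_low >= weight_high:
        raise ValueError("require weight_low < weight_high")
    m_edges = _target_edges(n_genes, density)
    if m_edges < n_genes - 1:
        raise ValueError(
            f"density {density} too low: {m_edges} edges cannot connect {n_genes} nodes"
        )
    rng = substream(seed, 17)  # dedicated topology stream under this seed
    for _ in range(max_retries):
        g = _skeleton(model, n_genes, m_edges, rng)
        if nx.is_connected(g.to_undirected() if g.is_directed() else g):
            weights = _orient_and_weight(g, n_genes, weight_low, weight_high, rng)
            np.fill_diagonal(weights, 0.0)
            graph = WeightedDigraph(weights, topology_model=model, seed=seed)
            graph.validate(weight_low, weight_high)
            return graph
    raise RuntimeError(
        f"no connected {model} graph found in {max_retries} attempts "
        f"(n={n_genes}, density={density})"
    )


# ---------------------------------------------------------------------------
# Edge-list / adjacency I/O (TSV, 0-based node ids); round-trips losslessly.

def write_edge_list(graph: WeightedDigraph, path) -> None:
    rows, cols = np.nonzero(graph.weights)
    df = pd.DataFrame(
        {
            "source": cols.astype(int),  # regulator j
            "target": rows.astype(int),  # regulated gene i
            "weight": graph.weights[rows, cols],
        }
    ).sort_values(["source", "target"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write(f"# n_genes={graph.n_genes}\tmodel={graph.topology_model}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_edge_list(path) -> WeightedDigraph:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(item.split("=") for item in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    n = int(meta["n_genes"])
    weights = np.zeros((n, n))
    weights[df["target"].to_numpy(), df["source"].to_numpy()] = df["weight"].to_numpy()
    return WeightedDigraph(weights, topology_model=meta.get("model", "user"))


def write_adjacency(graph: WeightedDigraph, path) -> None:
    pd.DataFrame(graph.weights).to_csv(path, sep="\t", header=False, index=False,
                                       float_format="%.17g")


def read_adjacency(path) -> WeightedDigraph:
    weights = pd.read_csv(path, sep="\t", header=None,
                          float_precision="round_trip").to_numpy(dtype=float)
    return WeightedDigraph(weights)
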