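"""Topology metrics characterizing connectome reservoirs.

Degree, clustering-coefficient, and directed shortest-path distributions,
plus sparsity and nonzero-weight statistics of the weight matrix. These are
the small-world diagnostics: connectome subgraphs show hub-dominated degree
tails, high clustering and longer directed paths compared with
density-matched random graphs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "MetricReport",
    "degree_distribution",
    "clustering_coefficients",
    "shortest_path_distribution",
    "matrix_stats",
    "metric_report",
]


@dataclass
class MetricReport:
    degree_hist: dict                # direction -> {degree: count}
    clustering: dict                 # direction -> {node: coefficient}
    path_hist: dict                  # hop length -> count (ordered pairs)
    unreachable_pairs: int
    sparsity: float
    weight_variance: float
    weight_hist: tuple               # (densities, bin_edges)
    meta: dict = field(default_factory=dict)


def degree_distribution(g: nx.DiGraph, direction: str = "total") -> dict[int, int]:
    """Histogram of distinct-edge degrees; counts sum to the node count."""
    if direction == "in":
        deg = dict(g.in_degree())
    elif direction == "out":
        deg = dict(g.out_degree())
    elif direction == "total":
        deg = {n: g.in_degree(n) + g.out_degree(n) for n in g.nodes}
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return dict(Counter(deg.values()))


def clustering_coefficients(g: nx.DiGraph, direction: str = "in") -> dict:
    """Local clustering C_i = 2 e_i / (k_i (k_i - 1)) per node.

    The neighborhood of node i is its in-neighbors (``direction='in'``) or
    out-neighbors (``'out'``); e_i counts unordered neighbor pairs joined by
    an edge in either direction, so C_i stays in [0, 1]. Nodes with fewer
    than two neighbors get C_i = 0, keeping distributions count-conserving.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if direction not in {"in", "out"}:
        raise ValueError(f"unknown direction {direction!r}")
    out = {}
    for node in g.nodes:
        if direction == "in":
            nbrs = [u for u in g.predecessors(node) if u != node]
        else:
            nbrs = [u for u in g.successors(node) if u != node]
        k = len(nbrs)
        if k < 2:
            out[node] = 0.0
            continue
        e = 0
        for a in range(k):
            for b in range(a + 1, k):
                u, v = nbrs[a], nbrs[b]
                if g.has_edge(u, v) or g.has_edge(v, u):
                    e += 1
        out[node] = 2.0 * e / (k * (k - 1))
    return out


def shortest_path_distribution(g: nx.DiGraph) -> tuple[dict[int, int], int]:
    """Directed unweighted shortest-path histogram over ordered pairs i != j.

    Returns ``(hop_length -> count, unreachable_pair_count)``; unreachable
    pairs are excluded from the histogram.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    hist: Counter = Counter()
    n = g.number_of_nodes()
    reachable = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                hist[d] += 1
                reachable += 1
    return dict(hist), n * (n - 1) - reachable


def matrix_stats(
    w: np.ndarray, n_bins: int = 50
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Sparsity (fraction of zero entries), population variance of nonzero
    weights, and a density histogram of the nonzero weights."""
    w = np.asarray(w)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square matrix")
    nz = w[w != 0]
    sparsity = 1.0 - nz.size / w.size
    if nz.size == 0:
        raise ValueError("matrix has no nonzero entries; variance undefined")
    variance = float(np.var(nz))
    hist = np.histogram(nz, bins=n_bins, density=True)
    return float(sparsity), variance, hist


def metric_report(g: nx.DiGraph, w: np.ndarray, n_bins: int = 50) -> MetricReport:
    """All reservoir metrics in one report."""
    path_hist, unreachable = shortest_path_distribution(g)
    sparsity, variance, whist = matrix_stats(w, n_bins=n_bins)
    return MetricReport(
        degree_hist={d: degree_distribution(g, d) for d in ("in", "out", "total")},
        clustering={d: clustering_coefficients(g, d) for d in ("in", "out")},
        path_hist=path_hist,
        unreachable_pairs=unreachable,
        sparsity=sparsity,
        weight_variance=variance,
        weight_hist=whist,
        meta={
            "clustering_convention": (
                "neighborhood = in- or out-neighbors; e_i counts unordered "
                "neighbor pairs linked by an edge in either direction"
            )
        },
    )
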