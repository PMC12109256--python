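"""Reservoir extraction from the connectome graph.

Implements the two selection criteria that carve a weakly connected
subgraph of exactly N neurons out of the full connectome ('most connected'
and 'proportional'), the conversion of a subgraph to a dense weight matrix,
spectral-radius rescaling, and the randomized control / hybrid architecture
variants used in the Monte Carlo comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg

__all__ = [
    "ArchitectureKind",
    "ReservoirMatrix",
    "total_degree",
    "select_most_connected",
    "select_proportional",
    "largest_remainder_quotas",
    "extract_weight_matrix",
    "spectral_radius",
    "rescale_spectral",
    "randomize",
]

DEFAULT_SPECTRAL_RADIUS = 0.99


class ArchitectureKind(str, Enum):
    """The five reservoir architectures of the comparative study."""

    CONTROL_RANDOM = "control_random"
    CONN_TOPO_CONN_WEIGHTS = "conn_topo_conn_weights"
    CONN_TOPO_RANDOM_WEIGHTS = "conn_topo_random_weights"
    RANDOM_TOPO_CONN_WEIGHTS = "random_topo_conn_weights"
    CONN_TOPO_SHUFFLED_WEIGHTS = "conn_topo_shuffled_weights"


@dataclass
class ReservoirMatrix:
    """An N-neuron reservoir weight matrix with node metadata.

    ``W[i, j]`` is the aggregated signed weight of the synapse from neuron
    ``node_ids[j]`` onto neuron ``node_ids[i]``.
    """

    node_ids: list
    W: np.ndarray
    class_labels: list
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.W))

    @property
    def sparsity(self) -> float:
        return 1.0 - self.nnz / self.W.size


def total_degree(g: nx.DiGraph, node) -> int:
    """Connectedness measure used for ranking: distinct in-edges plus
    distinct out-edges of the aggregated graph."""
    return g.in_degree(node) + g.out_degree(node)


def _degree_order(g: nx.DiGraph, nodes=None):
    """Nodes by descending total degree, ties broken by ascending id."""
    nodes = g.nodes if nodes is None else nodes
    return sorted(nodes, key=lambda n: (-total_degree(g, n), n))


def select_most_connected(g: nx.DiGraph, n: int) -> nx.DiGraph:
    """Select the N most connected neurons, repaired to a single component.

    Ranks neurons by total degree, takes the top N, keeps only the largest
    weakly connected component (size M <= N), then grows it back to N by
    repeatedly adding the highest-degree neuron among the component's
    neighbors in the full graph.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if n > g.number_of_nodes():
        raise ValueError(f"requested {n} nodes from a {g.number_of_nodes()}-node graph")
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges; no connected reservoir exists")
    if n == g.number_of_nodes():
        return g.copy()

    ranked = _degree_order(g)
    selected = set(ranked[:n])
    sub = g.subgraph(selected)
    component = max(nx.weakly_connected_components(sub), key=len)
    chosen = set(component)
    und = g.to_undirected(as_view=True)
    while len(chosen) < n:
        frontier = {nb for c in chosen for nb in und.neighbors(c)} - chosen
        if not frontier:
            raise ValueError("graph is not weakly connected; cannot reach size n")
        best = _degree_order(g, frontier)[0]
        chosen.add(best)
    out = g.subgraph(chosen).copy()
    out.graph["selection"] = {
        "criterion": "most_connected",
        "requested_n": n,
        "component_size_m": len(component),
    }
    return out


def largest_remainder_quotas(
    proportions: dict, n: int, available: dict | None = None
) -> dict:
    """Apportion n seats over classes by the largest-remainder method.

    ``proportions`` need not be normalized. If ``available`` caps a class
    below its quota, the deficit is redistributed among uncapped classes,
    again by largest remainder.
    """
    labels = sorted(proportions)
    quotas = {c: 0 for c in labels}
    capped: set = set()
    remaining = n
    while remaining > 0:
        pool = [c for c in labels if c not in capped]
        if not pool:
            raise ValueError("not enough neurons to fill all quotas")
        weight = sum(proportions[c] for c in pool)
        exact = {c: remaining * proportions[c] / weight for c in pool}
        alloc = {c: int(np.floor(exact[c])) for c in pool}
        leftover = remaining - sum(alloc.values())
        by_remainder = sorted(pool, key=lambda c: (-(exact[c] - alloc[c]), c))
        for c in by_remainder[:leftover]:
            alloc[c] += 1
        overflow = 0
        for c in pool:
            cap = available.get(c, n) if available is not None else n
            room = cap - quotas[c]
            take = min(alloc[c], room)
            quotas[c] += take
            overflow += alloc[c] - take
            if quotas[c] >= cap:
                capped.add(c)
        if overflow:
            warnings.warn("class quota capped by availability; redistributing")
        remaining = n - sum(quotas.values())
    return quotas


def select_proportional(g: nx.DiGraph, n: int) -> nx.DiGraph:
    """Select N neurons preserving the connectome's class proportions.

    Per-class quotas follow largest-remainder apportionment of N over the
    full-graph class proportions; each class contributes its quota's
    highest-degree neurons. The resulting components are then connected by
    greedily merging the two largest components along the fewest-hop
    undirected path in the full graph (adding path-interior nodes), giving
    M >= N nodes, after which the lowest-degree non-articulation nodes are
    pruned back to exactly N.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if n > g.number_of_nodes():
        raise ValueError(f"requested {n} nodes from a {g.number_of_nodes()}-node graph")
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges; no connected reservoir exists")
    if n == g.number_of_nodes():
        return g.copy()

    classes: dict = {}
    for node, data in g.nodes(data=True):
        classes.setdefault(data.get("cell_class", ""), []).append(node)
    proportions = {c: len(nodes) for c, nodes in classes.items()}
    available = {c: len(nodes) for c, nodes in classes.items()}
    quotas = largest_remainder_quotas(proportions, n, available)

    chosen: set = set()
    for c, q in quotas.items():
        chosen.update(_degree_order(g, classes[c])[:q])
    pre_repair_counts = {
        c: sum(1 for x in chosen if g.nodes[x].get("cell_class", "") == c)
        for c in quotas
    }

    # Connect components: merge the two largest along the shortest
    # undirected path through the full graph.
    und = g.to_undirected(as_view=True)
    while True:
        comps = sorted(nx.weakly_connected_components(g.subgraph(chosen)), key=len)
        if len(comps) <= 1:
            break
        big, second = comps[-1], comps[-2]
        path = _shortest_path_between_sets(und, second, big)
        if path is None:
            raise ValueError("graph is not weakly connected; cannot join components")
        chosen.update(path)

    m = len(chosen)
    # Prune lowest-degree nodes that are not articulation points of the
    # current (undirected view of the) subgraph until size n.
    while len(chosen) > n:
        sub_und = nx.Graph(g.subgraph(chosen).to_undirected())
        articulation = set(nx.articulation_points(sub_und))
        order = sorted(chosen, key=lambda x: (total_degree(g, x), x))
        for candidate in order:
            if candidate not in articulation:
                chosen.discard(candidate)
                break
        else:  # pragma: no cover - degenerate: everything articulates
            chosen.discard(order[0])

    out = g.subgraph(chosen).copy()
    out.graph["selection"] = {
        "criterion": "proportional",
        "requested_n": n,
        "quotas": quotas,
        "pre_repair_class_counts": pre_repair_counts,
        "pre_prune_size_m": m,
        "final_class_counts": {
            c: sum(1 for x in chosen if g.nodes[x].get("cell_class", "") == c)
            for c in quotas
        },
    }
    return out


def _shortest_path_between_sets(und: nx.Graph, sources, targets) -> list | None:
    """Interior of the fewest-hop path from any source to any target."""
    targets = set(targets)
    sources = set(sources)
    dist = {s: (0, [s]) for s in sources}
    frontier = list(sources)
    while frontier:
        nxt = []
        for u in frontier:
            d, path = dist[u]
            for v in und.neighbors(u):
                if v in dist:
                    continue
                dist[v] = (d + 1, path + [v])
                if v in targets:
                    return dist[v][1][1:-1]
                nxt.append(v)
        frontier = nxt
    return None


def extract_weight_matrix(sub: nx.DiGraph) -> ReservoirMatrix:
    """Lay a subgraph out as a dense weight matrix.

    Node order is descending total degree with ties broken by identifier;
    entry (i, j) holds the weight of the edge node_j -> node_i.
    """
    order = _degree_order(sub)
    index = {node: i for i, node in enumerate(order)}
    w = np.zeros((len(order), len(order)))
    for u, v, d in sub.edges(data=True):
        w[index[v], index[u]] = d["weight"]
    prov = dict(sub.graph.get("selection", {}))
    return ReservoirMatrix(
        node_ids=order,
        W=w,
        class_labels=[sub.nodes[x].get("cell_class", "") for x in order],
        provenance=prov,
    )


def spectral_radius(w: np.ndarray | sp.spmatrix) -> float:
    """Largest eigenvalue magnitude, dense for N <= 2000 else sparse
    largest-magnitude Arnoldi iteration (tolerance 1e-10)."""
    n = w.shape[0]
    if n <= 2000:
        dense = w.toarray() if sp.issparse(w) else np.asarray(w)
        if n == 1:
            return float(abs(dense[0, 0]))
        return float(np.max(np.abs(np.linalg.eigvals(dense))))
    ws = sp.csr_matrix(w)
    vals = scipy.sparse.linalg.eigs(
        ws, k=1, which="LM", return_eigenvectors=False, tol=1e-10
    )
    return float(np.abs(vals[0]))


def rescale_spectral(
    w: np.ndarray, target: float = DEFAULT_SPECTRAL_RADIUS
) -> np.ndarray:
    """Rescale a square matrix to the target spectral radius.

    Returns ``(target / rho(W)) * W``; raises if the spectral radius is
    zero (nilpotent or empty matrix), for which rescaling is undefined.
    """
    w = np.asarray(w, dtype=float)
    rho = spectral_radius(w)
    if rho == 0.0:
        raise ValueError(
            "spectral radius is zero (nilpotent or zero matrix); rescaling undefined"
        )
    return (target / rho) * w


def _draw_weights(rng: np.random.Generator, size: int, dist: str) -> np.ndarray:
    if dist == "uniform":
        return rng.uniform(-1.0, 1.0, size)
    if dist == "gaussian":
        return rng.standard_normal(size)
    raise ValueError(f"unknown weight distribution {dist!r}")


def randomize(
    base: ReservoirMatrix,
    kind: ArchitectureKind | str,
    dist: str = "uniform",
    rng: np.random.Generator | None = None,
    target: float = DEFAULT_SPECTRAL_RADIUS,
) -> ReservoirMatrix:
    """Derive one of the five architecture variants from a connectome base.

    All variants are rescaled to the same spectral radius. ``dist`` selects
    the random weight family (uniform(-1, 1) or standard normal) where one
    is drawn; the connectome variant ignores it.
    """
    kind = ArchitectureKind(kind)
    rng = np.random.default_rng() if rng is None else rng
    n = base.n
    w0 = base.W
    nz = w0 != 0.0
    nnz = int(nz.sum())
    conn_weights = w0[nz]

    if kind is ArchitectureKind.CONN_TOPO_CONN_WEIGHTS:
        w = w0.copy()
    elif kind is ArchitectureKind.CONN_TOPO_RANDOM_WEIGHTS:
        w = np.zeros_like(w0)
        w[nz] = _draw_weights(rng, nnz, dist)
    elif kind is ArchitectureKind.CONN_TOPO_SHUFFLED_WEIGHTS:
        w = np.zeros_like(w0)
        w[nz] = rng.permutation(conn_weights)
    elif kind is ArchitectureKind.RANDOM_TOPO_CONN_WEIGHTS:
        # exact-count mask: nnz positions drawn uniformly without
        # replacement, weights a random permutation of the original multiset
        w = np.zeros(n * n)
        pos = rng.choice(n * n, size=nnz, replace=False)
        w[pos] = rng.permutation(conn_weights)
        w = w.reshape(n, n)
    elif kind is ArchitectureKind.CONTROL_RANDOM:
        # Bernoulli mask with per-entry nonzero probability equal to the
        # base matrix's nonzero fraction (diagonal treated like any entry)
        p = nnz / (n * n)
        for _ in range(100):
            mask = rng.random((n, n)) < p
            w = np.zeros_like(w0)
            w[mask] = _draw_weights(rng, int(mask.sum()), dist)
            if spectral_radius(w) > 0:
                break
        else:  # pragma: no cover
            raise ValueError("could not draw a control matrix with nonzero radius")
    else:  # pragma: no cover
        raise ValueError(f"unknown architecture kind {kind}")

    w = rescale_spectral(w, target)
    prov = dict(base.provenance)
    prov.update({"architecture": kind.value, "distribution": dist, "target_radius": target})
    return ReservoirMatrix(
        node_ids=list(base.node_ids),
        W=w,
        class_labels=list(base.class_labels),
        provenance=prov,
    )
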