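"""Ingest of FlyWire-schema connectome tables.

Reads neuron and synapse CSV/TSV exports, applies the synapse quality
filter (cleft score >= 50, connection score >= 100 by default, and removal
of synapses whose endpoints are not classified neurons), assigns each
synapse an excitatory/inhibitory sign from its neurotransmitter
probabilities, and aggregates the result into a signed, weighted, directed
graph whose edge weights are summed connection scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "NeuronRecord",
    "SynapseRecord",
    "SchemaError",
    "NT_ORDER",
    "read_tables",
    "filter_synapses",
    "assign_sign",
    "build_graph",
    "write_graph",
    "read_graph",
]

#: Neurotransmitter column order; also the tie-break priority for argmax.
NT_ORDER = ("gaba", "ach", "glut", "oct", "ser", "da")

#: Sign contributed by each neurotransmitter when it is the argmax.
#: GABA is inhibitory; acetylcholine and glutamate are excitatory;
#: octopamine, serotonin and dopamine are modulatory and contribute no edge.
NT_SIGN = {"gaba": -1, "ach": +1, "glut": +1, "oct": 0, "ser": 0, "da": 0}

NEURON_COLUMNS = ("neuron_id", "pos_x", "pos_y", "pos_z", "cell_class")
SYNAPSE_COLUMNS = (
    "pre_id",
    "post_id",
    "cleft_score",
    "connection_score",
    "p_gaba",
    "p_ach",
    "p_glut",
    "p_oct",
    "p_ser",
    "p_da",
)


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


@dataclass(frozen=True)
class NeuronRecord:
    """One classified neuron: identifier, position (nm) and cell class."""

    neuron_id: int
    position: tuple[float, float, float]
    cell_class: str


@dataclass(frozen=True)
class SynapseRecord:
    """One synapse with its quality scores and neurotransmitter profile.

    ``nt_probs`` follows :data:`NT_ORDER`.
    """

    pre_id: int
    post_id: int
    cleft_score: float
    connection_score: float
    nt_probs: tuple[float, ...]


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, columns: Iterable[str], name: str) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{name}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at row {row}"
            )
        df[col] = converted
    return df


def read_tables(
    neuron_path: str | Path, synapse_path: str | Path
) -> tuple[list[NeuronRecord], list[SynapseRecord]]:
    """Parse neuron and synapse tables into typed records, preserving row order.

    Delimiter is inferred from the extension (``.tsv``/``.tab`` means tab,
    anything else comma). Raises :class:`SchemaError` naming the offending
    column or row on malformed input.
    """
    ndf = _read_table(neuron_path, NEURON_COLUMNS)
    ndf = _numeric(ndf, ("neuron_id", "pos_x", "pos_y", "pos_z"), "neuron table")
    if ndf["neuron_id"].duplicated().any():
        dup = int(ndf["neuron_id"][ndf["neuron_id"].duplicated()].iloc[0])
        raise SchemaError(f"neuron table: duplicate neuron_id {dup}")
    if (ndf["cell_class"].astype(str).str.len() == 0).any():
        raise SchemaError("neuron table: empty cell_class")
    neurons = [
        NeuronRecord(int(r.neuron_id), (r.pos_x, r.pos_y, r.pos_z), str(r.cell_class))
        for r in ndf.itertuples(index=False)
    ]

    sdf = _read_table(synapse_path, SYNAPSE_COLUMNS)
    sdf = _numeric(sdf, [c for c in SYNAPSE_COLUMNS], "synapse table")
    prob_cols = [f"p_{nt}" for nt in NT_ORDER]
    synapses = [
        SynapseRecord(
            int(r.pre_id),
            int(r.post_id),
            float(r.cleft_score),
            float(r.connection_score),
            tuple(float(getattr(r, c)) for c in prob_cols),
        )
        for r in sdf.itertuples(index=False)
    ]
    return neurons, synapses


def filter_synapses(
    synapses: Sequence[SynapseRecord],
    neurons: Sequence[NeuronRecord],
    cleft_min: float = 50.0,
    conn_min: float = 100.0,
) -> list[SynapseRecord]:
    """Apply the synapse quality filter.

    A synapse is retained iff its cleft score is >= ``cleft_min``, its
    connection score is >= ``conn_min`` (scores *below* the threshold are
    deleted, equality keeps), and both endpoints appear in the classified
    neuron set. Idempotent.
    """
    if cleft_min < 0 or conn_min < 0:
        raise ValueError("thresholds must be non-negative")
    ids = {n.neuron_id for n in neurons}
    return [
        s
        for s in synapses
        if s.cleft_score >= cleft_min
        and s.connection_score >= conn_min
        and s.pre_id in ids
        and s.post_id in ids
    ]


def assign_sign(nt_probs: Sequence[float]) -> int:
    """Map a neurotransmitter probability vector to an edge sign.

    Returns ``-1`` (inhibitory, GABA), ``+1`` (excitatory, ACh or
    glutamate) or ``0`` (modulatory argmax — octopamine, serotonin or
    dopamine — meaning the synapse is dropped). Exact ties resolve by the
    fixed priority order of :data:`NT_ORDER`, which ``numpy.argmax``
    implements by taking the first maximum.

    Vectors whose sum is off unity are renormalized with a warning when the
    sum lies in [0.5, 1.5]; otherwise rejected.
    """
    p = np.asarray(nt_probs, dtype=float)
    if p.shape != (len(NT_ORDER),):
        raise ValueError(f"expected {len(NT_ORDER)} probabilities, got {p.shape}")
    if (p < 0).any():
        raise ValueError("negative neurotransmitter probability")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero neurotransmitter probability vector")
    if not (0.99 <= total <= 1.01):
        if 0.5 <= total <= 1.5:
            warnings.warn(
                f"nt_probs sum {total:.3f} != 1; renormalizing", stacklevel=2
            )
            p = p / total
        else:
            raise ValueError(f"nt_probs sum {total:.3f} outside [0.5, 1.5]")
    return NT_SIGN[NT_ORDER[int(np.argmax(p))]]


def build_graph(
    neurons: Sequence[NeuronRecord], filtered: Sequence[SynapseRecord]
) -> nx.DiGraph:
    """Aggregate filtered synapses into a signed weighted directed graph.

    Parallel synapses between the same ordered pair sum as
    sign * connection_score; pairs whose signed sum cancels to zero yield
    no edge, and modulatory-argmax synapses contribute nothing. Node
    attributes carry position and cell class.
    """
    g = nx.DiGraph()
    for n in neurons:
        g.add_node(n.neuron_id, position=n.position, cell_class=n.cell_class)
    acc: dict[tuple[int, int], float] = {}
    for s in filtered:
        sign = assign_sign(s.nt_probs)
        if sign == 0:
            continue
        key = (s.pre_id, s.post_id)
        acc[key] = acc.get(key, 0.0) + sign * s.connection_score
    for (pre, post), w in acc.items():
        if w != 0.0:
            g.add_edge(pre, post, weight=w)
    return g


def write_graph(g: nx.DiGraph, mtx_path: str | Path, meta_path: str | Path) -> None:
    """Export the signed sparse adjacency as Matrix Market plus a node
    metadata CSV sidecar (row order of the sidecar defines matrix order)."""
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, d in g.edges(data=True):
        # adjacency convention: entry (i, j) = weight of edge j -> i
        rows.append(index[v])
        cols.append(index[u])
        vals.append(d["weight"])
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    scipy.io.mmwrite(str(mtx_path), mat)
    meta = pd.DataFrame(
        {
            "neuron_id": nodes,
            "pos_x": [g.nodes[n]["position"][0] for n in nodes],
            "pos_y": [g.nodes[n]["position"][1] for n in nodes],
            "pos_z": [g.nodes[n]["position"][2] for n in nodes],
            "cell_class": [g.nodes[n]["cell_class"] for n in nodes],
        }
    )
    meta.to_csv(meta_path, index=False)


def read_graph(mtx_path: str | Path, meta_path: str | Path) -> nx.DiGraph:
    """Inverse of :func:`write_graph`."""
    mat = scipy.io.mmread(str(mtx_path)).tocoo()
    meta = pd.read_csv(meta_path)
    nodes = meta["neuron_id"].tolist()
    g = nx.DiGraph()
    for r in meta.itertuples(index=False):
        g.add_node(
            int(r.neuron_id),
            position=(r.pos_x, r.pos_y, r.pos_z),
            cell_class=str(r.cell_class),
        )
    for i, j, w in zip(mat.row, mat.col, mat.data):
        g.add_edge(nodes[j], nodes[i], weight=float(w))
    return g
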