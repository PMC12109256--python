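"""Synthetic FlyWire-schema connectome generator.

Emits neuron and synapse tables with the statistical structure the
pipeline assumes from the real whole-brain connectome: an open class
vocabulary dominated by optic-lobe classes (ME, ME>LO), small-world
topology (rewired ring lattice plus preferential-attachment hubs), a
bimodal heavy-tailed signed weight distribution (log-normal magnitudes per
sign), neurotransmitter probability vectors peaked on the class-appropriate
transmitter, and controllable fractions of sub-threshold and
modulatory-argmax synapses to exercise every filtering branch.

Classes affect labels and selection quotas only; class-conditional wiring
is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import NT_ORDER, SYNAPSE_COLUMNS, build_graph

__all__ = ["SynthConfig", "generate", "make_fixture", "DEFAULT_CLASS_TABLE"]

#: Default class proportions: a reduced Table-1-style vocabulary with the
#: optic-lobe classes dominant, spanning sensory (input), intermediate and
#: output categories so class-restricted wiring is exercisable.
DEFAULT_CLASS_TABLE = {
    "ME": 0.33,
    "ME>LO": 0.12,
    "LO": 0.07,
    "bilateral": 0.05,
    "LA": 0.05,
    "Kenyon Cell": 0.05,
    "ME>LOP": 0.04,
    "LOP": 0.04,
    "olfactory": 0.04,
    "CX": 0.03,
    "visual": 0.03,
    "AN": 0.02,
    "mechanosensory": 0.02,
    "MBON": 0.02,
    "DAN": 0.02,
    "LOP>LO": 0.02,
    "TuBu": 0.01,
    "LHCENT": 0.01,
    "clock": 0.01,
    "gustatory": 0.01,
    "thermosensory": 0.005,
    "hygrosensory": 0.005,
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic connectome.

    Topology: each neuron sits on a ring lattice of ``lattice_degree``
    neighbors rewired with probability ``rewire_prob`` (high clustering),
    and a ``hub_fraction`` of neurons additionally receives
    ``hub_attachment`` degree-preferential edges (hub-dominated degree
    tail). Weights: connection scores are 100 plus a log-normal draw, so
    magnitudes concentrate in the 1e2-1e3 decade, signed excitatory with
    probability ``excitatory_fraction``. ``subthreshold_fraction`` of
    synapses get a quality score below the filter thresholds and
    ``modulatory_fraction`` get a modulatory-argmax neurotransmitter, so
    both removal paths are exercised.
    """

    n_neurons: int = 2000
    class_table: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_TABLE))
    lattice_degree: int = 8
    rewire_prob: float = 0.1
    hub_fraction: float = 0.02
    hub_attachment: int = 30
    excitatory_fraction: float = 0.6
    lognormal_mu: float = float(np.log(150.0))
    lognormal_sigma: float = 0.8
    modulatory_fraction: float = 0.05
    subthreshold_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_table.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        for name in (
            "hub_fraction",
            "excitatory_fraction",
            "modulatory_fraction",
            "subthreshold_fraction",
            "rewire_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.lattice_degree >= self.n_neurons:
            raise ValueError("lattice_degree must be smaller than n_neurons")


def _nt_probs(rng: np.random.Generator, dominant: int, size: int) -> np.ndarray:
    """Probability vectors peaked on one transmitter (argmax guaranteed)."""
    probs = np.empty((size, len(NT_ORDER)))
    peak = rng.uniform(0.6, 0.9, size)
    rest = rng.dirichlet(np.ones(len(NT_ORDER) - 1), size) * (1.0 - peak)[:, None]
    others = [i for i in range(len(NT_ORDER)) if i != dominant]
    probs[:, dominant] = peak
    probs[:, others] = rest
    return probs


def generate(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (neuron table, synapse table) DataFrames, fully seeded."""
    rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    ids = np.arange(1, n + 1)

    # classes by largest-remainder apportionment of the proportions
    labels = sorted(config.class_table)
    exact = np.array([config.class_table[c] * n for c in labels])
    counts = np.floor(exact).astype(int)
    for i in np.argsort(-(exact - counts))[: n - counts.sum()]:
        counts[i] += 1
    cell_class = rng.permutation(np.repeat(labels, counts))

    # two mirrored spatial clusters (hemispheres), nanometre scale
    hemi = rng.random(n) < 0.5
    centers = np.where(hemi[:, None], [250_000.0, 0, 0], [-250_000.0, 0, 0])
    pos = centers + rng.normal(scale=120_000.0, size=(n, 3))

    neuron_df = pd.DataFrame(
        {
            "neuron_id": ids,
            "pos_x": pos[:, 0],
            "pos_y": pos[:, 1],
            "pos_z": pos[:, 2],
            "cell_class": cell_class,
        }
    )

    # topology: rewired ring lattice, randomly oriented, plus hub edges
    ws_seed = int(rng.integers(2**31))
    lattice = nx.watts_strogatz_graph(
        n, config.lattice_degree, config.rewire_prob, seed=ws_seed
    )
    edges = []
    for u, v in lattice.edges:
        edges.append((u, v) if rng.random() < 0.5 else (v, u))
    degree = np.array([lattice.degree(i) for i in range(n)], dtype=float)
    n_hubs = int(round(config.hub_fraction * n))
    if n_hubs:
        hubs = rng.choice(n, size=n_hubs, replace=False)
        for hub in hubs:
            partners = rng.choice(n, size=config.hub_attachment, p=degree / degree.sum())
            for p in partners:
                if p == hub:
                    continue
                edges.append((hub, p) if rng.random() < 0.5 else (p, hub))
                degree[hub] += 1
                degree[p] += 1
    edges = np.array(edges)
    m = len(edges)

    # signed heavy-tailed weights: connection score = 100 + log-normal
    excitatory = rng.random(m) < config.excitatory_fraction
    conn_score = 100.0 + rng.lognormal(config.lognormal_mu, config.lognormal_sigma, m)
    cleft_score = rng.uniform(50.0, 200.0, m)

    # sub-threshold rows: fail either the cleft or the connection filter
    sub = rng.random(m) < config.subthreshold_fraction
    fail_cleft = rng.random(m) < 0.5
    cleft_score[sub & fail_cleft] = rng.uniform(0.0, 49.9, int((sub & fail_cleft).sum()))
    conn_score[sub & ~fail_cleft] = rng.uniform(10.0, 99.9, int((sub & ~fail_cleft).sum()))

    # neurotransmitter identity: GABA for inhibitory, ACh/Glu for
    # excitatory, one of the three modulatory transmitters for the
    # modulatory fraction (those synapses are dropped downstream)
    modulatory = rng.random(m) < config.modulatory_fraction
    dominant = np.where(excitatory, np.where(rng.random(m) < 0.7, 1, 2), 0)
    dominant[modulatory] = rng.integers(3, 6, int(modulatory.sum()))
    probs = np.empty((m, len(NT_ORDER)))
    for d in range(len(NT_ORDER)):
        mask = dominant == d
        if mask.any():
            probs[mask] = _nt_probs(rng, d, int(mask.sum()))

    synapse_df = pd.DataFrame(
        {
            "pre_id": ids[edges[:, 0]],
            "post_id": ids[edges[:, 1]],
            "cleft_score": cleft_score,
            "connection_score": conn_score,
            **{f"p_{nt}": probs[:, i] for i, nt in enumerate(NT_ORDER)},
        }
    )
    return neuron_df, synapse_df[list(SYNAPSE_COLUMNS)]


# ---------------------------------------------------------------------------
# deterministic hand-built fixture


def _peaked(dominant: str) -> dict:
    probs = {f"p_{nt}": 0.04 for nt in NT_ORDER}
    probs[f"p_{dominant}"] = 0.8
    return probs


def make_fixture() -> tuple[pd.DataFrame, pd.DataFrame, nx.DiGraph]:
    """A 12-neuron, 30-synapse table with its hand-computed expected graph.

    Covers every ingest branch: sub-threshold cleft and connection scores,
    orphan pre/post endpoints, all three modulatory transmitters, a
    mixed-sign cancelling pair, parallel-synapse aggregation (same and
    mixed sign), the GABA/ACh exact tie, and an autapse. Classes are
    A:B:C = 6:4:2 so proportional selection quotas are hand-checkable.
    """
    neuron_df = pd.DataFrame(
        {
            "neuron_id": range(1, 13),
            "pos_x": [float(10 * i) for i in range(1, 13)],
            "pos_y": [0.0] * 12,
            "pos_z": [float(i % 3) for i in range(1, 13)],
            "cell_class": ["A"] * 6 + ["B"] * 4 + ["C"] * 2,
        }
    )

    rows: list[dict] = []

    def syn(pre, post, conn, nt="ach", cleft=60.0, **probs):
        row = {"pre_id": pre, "post_id": post, "cleft_score": cleft,
               "connection_score": conn}
        row.update(probs if probs else _peaked(nt))
        rows.append(row)

    # removed by the quality filter
    syn(1, 3, 150, cleft=49.0)                       # cleft below 50
    syn(1, 4, 99.0)                                  # connection below 100
    syn(1, 99, 150)                                  # orphan post
    syn(98, 2, 150)                                  # orphan pre
    # dropped at sign assignment (modulatory argmax)
    syn(2, 4, 140, nt="oct")
    syn(2, 5, 140, nt="ser")
    syn(2, 6, 140, nt="da")
    # mixed-sign cancelling pair -> edge absent
    syn(1, 2, 150, nt="ach")
    syn(1, 2, 150, nt="gaba")
    # parallel excitatory pair -> +250
    syn(2, 3, 120, nt="ach")
    syn(2, 3, 130, nt="glut")
    # parallel mixed, not cancelling -> +50
    syn(3, 4, 200, nt="ach")
    syn(3, 4, 150, nt="gaba")
    # plain inhibitory -> -180
    syn(4, 5, 180, nt="gaba")
    # exact GABA/ACh tie -> priority order gives inhibitory -> -110
    syn(5, 6, 110, p_gaba=0.4, p_ach=0.4, p_glut=0.05, p_oct=0.05,
        p_ser=0.05, p_da=0.05)
    # autapse -> +130
    syn(6, 6, 130, nt="ach")
    # plain excitatory edges completing a connected graph
    plain = [
        (1, 7, 150), (7, 8, 160), (8, 9, 170), (9, 10, 180), (10, 11, 190),
        (11, 12, 200), (12, 1, 210), (6, 7, 120), (3, 7, 140), (9, 2, 155),
        (5, 9, 165), (2, 8, 175), (10, 4, 185), (12, 6, 195),
    ]
    for pre, post, w in plain:
        syn(pre, post, float(w))

    synapse_df = pd.DataFrame(rows)[list(SYNAPSE_COLUMNS)]
    assert len(synapse_df) == 30

    expected_edges = [
        (2, 3, 250.0), (3, 4, 50.0), (4, 5, -180.0), (5, 6, -110.0),
        (6, 6, 130.0),
    ] + [(pre, post, float(w)) for pre, post, w in plain]
    expected = nx.DiGraph()
    for r in neuron_df.itertuples(index=False):
        expected.add_node(
            int(r.neuron_id),
            position=(r.pos_x, r.pos_y, r.pos_z),
            cell_class=str(r.cell_class),
        )
    for u, v, w in expected_edges:
        expected.add_edge(u, v, weight=w)
    return neuron_df, synapse_df, expected


def fixture_graph() -> nx.DiGraph:
    """The expected fixture graph, rebuilt through the ingest pipeline."""
    _, _, expected = make_fixture()
    return expected


def synthetic_graph(config: SynthConfig | None = None) -> nx.DiGraph:
    """Convenience: generate tables and run them through the full ingest."""
    from .io import filter_synapses, read_tables  # local import, avoids cycle

    config = SynthConfig() if config is None else config
    neuron_df, synapse_df = generate(config)
    from .io import NeuronRecord, SynapseRecord

    neurons = [
        NeuronRecord(int(r.neuron_id), (r.pos_x, r.pos_y, r.pos_z), str(r.cell_class))
        for r in neuron_df.itertuples(index=False)
    ]
    synapses = [
        SynapseRecord(
            int(r.pre_id), int(r.post_id), float(r.cleft_score),
            float(r.connection_score),
            tuple(float(getattr(r, f"p_{nt}")) for nt in NT_ORDER),
        )
        for r in synapse_df.itertuples(index=False)
    ]
    return build_graph(neurons, filter_synapses(synapses, neurons))
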