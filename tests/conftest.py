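import networkx as nx
import numpy as np
import pytest

from connres import cr3bp, io, synthetic


@pytest.fixture(scope="session")
def fixture_tables(tmp_path_factory):
    """The hand-built 12-neuron / 30-synapse tables written to CSV."""
    neuron_df, synapse_df, expected = synthetic.make_fixture()
    d = tmp_path_factory.mktemp("fixture")
    neuron_path = d / "neurons.csv"
    synapse_path = d / "synapses.csv"
    neuron_df.to_csv(neuron_path, index=False)
    synapse_df.to_csv(synapse_path, index=False)
    return neuron_path, synapse_path, expected


@pytest.fixture(scope="session")
def fixture_records(fixture_tables):
    neuron_path, synapse_path, expected = fixture_tables
    neurons, synapses = io.read_tables(neuron_path, synapse_path)
    return neurons, synapses, expected


@pytest.fixture(scope="session")
def fixture_graph(fixture_records):
    neurons, synapses, _ = fixture_records
    return io.build_graph(neurons, io.filter_synapses(synapses, neurons))


@pytest.fixture(scope="session")
def reference_trajectory():
    """The 10,000-sample trajectory from the reference initial conditions."""
    return cr3bp.propagate(cr3bp.REFERENCE_STATE0, steps=10000)


@pytest.fixture(scope="session")
def small_synthetic_graph():
    """A 400-neuron synthetic connectome graph for pipeline tests."""
    return synthetic.synthetic_graph(synthetic.SynthConfig(n_neurons=400, seed=7))


def random_connected_digraph(rng: np.random.Generator, n: int) -> nx.DiGraph:
    """A random weakly connected directed graph with class labels."""
    while True:
        g = nx.DiGraph()
        for i in range(n):
            g.add_node(i, cell_class=rng.choice(["A", "B", "C"]),
                       position=(0.0, 0.0, 0.0))
        for u in range(n):
            for v in range(n):
                if u != v and rng.random() < 2.5 / n:
                    g.add_edge(u, v, weight=float(rng.normal()) or 1.0)
        if g.number_of_edges() > 0 and nx.is_weakly_connected(g):
            return g
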