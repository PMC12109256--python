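# connres

Connectome-derived reservoirs for echo state networks, evaluated on
chaotic three-body trajectory forecasting.

The complete synaptic wiring diagram of the fruit fly brain — roughly
10⁵ classified neurons with signed, weighted connections inferable from
synapse size and neurotransmitter identity — can be read as the fixed
recurrent weight matrix of an echo state network (ESN), in which only a
linear readout is trained. `connres` implements that idea end to end for
computational-neuroscience and reservoir-computing researchers:

* **ingest** FlyWire-schema neuron/synapse tables, apply the synapse
  quality filter (cleft score ≥ 50, connection score ≥ 100, classified
  endpoints only), assign signs from neurotransmitter probabilities
  (GABA inhibitory; ACh/Glu excitatory; modulatory transmitters dropped)
  and aggregate parallel synapses into a signed weighted directed graph;
* **select** a weakly connected reservoir of exactly N neurons by either
  the *most-connected* or the class-*proportional* criterion, lay it out
  as a weight matrix W, and rescale it to spectral radius 0.99;
* **characterize** its small-world topology: degree, directed clustering
  coefficient C_i = 2e_i/(k_i(k_i−1)), shortest-path distributions,
  sparsity and weight statistics;
* **forecast** trajectories of the circularly restricted three-body
  problem (earth–moon mass ratio, normalized rotating-frame units) with
  the leaky ESN x_n = (1−α)x_{n−1} + α·tanh(Wx_{n−1} + W_in[1;u_n]) and
  a one-shot ridge readout W_out = YXᵀ(XXᵀ+βI)⁻¹, scoring normalized
  root-mean-square error (nRMSE);
* **compare** five architectures (random control, full connectome,
  connectome topology with random or shuffled weights, random topology
  with connectome weights) in a seeded Monte Carlo grid over size,
  regularization, horizon and distribution, with Mann–Whitney–Wilcoxon
  significance tests and Bhattacharyya distances between error
  distributions.

A seeded synthetic connectome generator emulates the FlyWire export
schema — small-world topology with hubs, bimodal heavy-tailed signed
weights, Table-style class labels — so the entire pipeline runs and is
tested without any database access.

## Worked example

```python
import numpy as np
from connres import cr3bp, esn, selection, synthetic

# synthetic connectome tables -> signed graph (2000 neurons)
graph = synthetic.synthetic_graph(synthetic.SynthConfig(seed=1))

# carve a 200-neuron reservoir and rescale it to the edge of chaos
sub = selection.select_most_connected(graph, 200)
res = selection.extract_weight_matrix(sub)
W = selection.rescale_spectral(res.W)          # spectral radius 0.99

# a 10,000-sample three-body trajectory from the reference initial state
traj = cr3bp.propagate(cr3bp.REFERENCE_STATE0, steps=10000)
print(f"Jacobi drift: {traj.provenance['jacobi_drift']:.2e}")

# one-step-ahead forecast with a ridge readout
trial = esn.forecast_trial(
    W, esn.EsnConfig(beta=1e-6, horizon=1), traj,
    rng=np.random.default_rng(2),
)
print(f"train nRMSE: {trial.train_nrmse:.4f}")
print(f"test  nRMSE: {trial.test_nrmse:.4f}")
```

prints

```
Jacobi drift: 1.03e-10
train nRMSE: 0.0020
test  nRMSE: 0.0265
```

The Jacobi constant (the conserved energy-like integral of the rotating
frame) drifts by only ~1e−10 over 10,000 samples, validating the
propagation. The reservoir forecasts one step ahead with test error well
under the target scale (nRMSE ≈ 2.7%); the gap between train and test
error is the overfitting signature that the architecture comparison
quantifies: at weak regularization the random control reservoir develops
a large train-to-test gap, while connectome-derived reservoirs remain
comparatively resilient.

The same pipeline is scriptable from the shell:

```sh
connres generate --n 2000 --seed 1 --out data/
connres ingest --neurons data/neurons.csv --synapses data/synapses.csv \
    --out data/graph.mtx --meta data/nodes.csv
connres select --criterion most-connected --n 200 \
    --in data/graph.mtx --meta data/nodes.csv --out data/reservoir.mtx
connres run-grid --config grid.yaml --graph data/graph.mtx \
    --meta data/nodes.csv --out results.csv
connres report --in results.csv --out summary.csv
```

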