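# Methods

This note documents the models and procedures implemented in `connres`,
the defaults they use, and the choices made where the design was open.

## Connectome ingest and the signed weight matrix

The ingest operates on two tables following the FlyWire/CAVE export
schema: a neuron table (unique id, x/y/z position in nanometres, cell
class) and a synapse table (pre/post ids, a cleft score measuring how
well-defined the synaptic cleft is, a connection score measuring synapse
size, and a probability vector over six neurotransmitters: GABA,
acetylcholine, glutamate, octopamine, serotonin, dopamine).

The quality filter removes synapses whose cleft score is below 50 or
whose connection score is below 100 — "below threshold" is read as
strict-less-than, so equality keeps the synapse — and synapses whose
endpoints are not in the classified neuron set.

Sign assignment takes the argmax of the neurotransmitter probabilities:
GABA is inhibitory (−1), acetylcholine and glutamate excitatory (+1), and
the three modulatory transmitters (octopamine, serotonin, dopamine) make
the synapse drop out entirely — a firing-rate neuron model has no resting
potential for them to modulate. Exact ties resolve by a fixed priority
order (GABA, ACh, Glu, Oct, Ser, Dop) for determinism. Probability
vectors whose sum is off unity are renormalized with a warning when the
sum lies in [0.5, 1.5] and rejected otherwise.

The connection score serves as the synaptic strength. Multiple synapses
between the same ordered neuron pair aggregate as the *signed sum* of
their connection scores; the tables do not dictate an aggregation rule,
and summation preserves total anatomical strength while letting opposing
synapses cancel (an exactly cancelling pair produces no edge). Autapses
are kept when present. Raw scores are used without normalization: the
later spectral rescaling makes any global scale irrelevant.

## Reservoir selection

Both selectors return a weakly connected subgraph of exactly N neurons.
"Most connected" is measured as total degree — the count of distinct
in-edges plus distinct out-edges of the aggregated graph — and weak
connectivity of the directed graph is the connectivity notion throughout,
since a reservoir only needs a single interacting component.

* **most-connected**: rank all neurons by total degree (ties by id), take
  the top N, keep the largest weakly connected component (size M ≤ N),
  then repeatedly add the highest-degree node among the component's
  graph neighbors until the size is back to N.
* **proportional**: compute per-class quotas by largest-remainder
  apportionment of N over the whole-graph class proportions (quotas
  capped by availability, deficits redistributed); take each class's
  quota of highest-degree neurons; join the resulting components by
  repeatedly merging the two largest along the fewest-hop undirected
  path through the full graph, adding path-interior nodes (size M ≥ N);
  finally prune the lowest-degree nodes that are not articulation points
  of the current subgraph until exactly N remain. The greedy
  shortest-path merge stands in for the minimum connector (an exact
  Steiner tree is NP-hard); provenance records the criterion, quotas,
  pre-repair class counts and intermediate sizes.

The weight matrix W places the edge j→i at entry (i, j); node order is
descending degree with ties by identifier. W is rescaled by
`target / ρ(W)` to spectral radius 0.99, keeping the network just inside
the echo-state regime near the edge of chaos. The spectral radius is
computed densely for N ≤ 2000 and by sparse largest-magnitude Arnoldi
iteration (tolerance 1e−10) above; a zero spectral radius (nilpotent
matrix) is an error since the rescaling is undefined there.

### Architecture variants

Five architectures derive from a connectome base matrix, all rescaled to
the same spectral radius so only topology and weights differ:

| kind | topology | weights |
|---|---|---|
| `control_random` | Bernoulli mask at the base's nonzero fraction | i.i.d. uniform(−1,1) or N(0,1) |
| `conn_topo_conn_weights` | connectome | connectome |
| `conn_topo_random_weights` | connectome | i.i.d. random |
| `random_topo_conn_weights` | exact-count random mask | permutation of connectome weights |
| `conn_topo_shuffled_weights` | connectome | permutation of its own weights |

The control mask treats the diagonal like any other entry. The
exact-count mask draws exactly the base's number of nonzero positions
uniformly without replacement — equivalent to conditioning the Bernoulli
mask on its count. Uniform(−1, 1) and standard normal are used for the
random weight families; their scale is immaterial after rescaling.

## Topology metrics

Degree distributions count distinct edges (in, out, total). The local
clustering coefficient is C_i = 2 e_i / (k_i (k_i − 1)) with two directed
variants: the neighborhood of i is its in-neighbors or its out-neighbors,
and e_i counts unordered neighbor pairs joined by an edge in either
direction, which keeps C_i in [0, 1]. Nodes with fewer than two neighbors
get C_i = 0 so distributions conserve counts. Shortest paths are directed
unweighted BFS hop counts over ordered pairs; unreachable pairs are
excluded from the histogram and reported separately. Matrix statistics:
sparsity is the fraction of zero entries of the N×N matrix, and the
weight variance is the population variance of the nonzero entries.

## CR3BP forecasting task

The prediction target is the circularly restricted three-body problem in
the rotating frame, normalized units (separation = angular rate = 1),
with the earth–moon mass ratio μ = 0.0121505856. Trajectories integrate
the standard rotating-frame equations with adaptive 8th-order
Runge–Kutta (DOP853, rtol = atol = 1e−12), sampled every dt = 0.1 for
10,000 samples from the reference initial state r = (−0.80, 0, 0),
v = (0, −0.63, 0.08). The Jacobi constant
C = x² + y² + 2(1−μ)/r₁ + 2μ/r₂ − |v|² is recorded along every
trajectory; its drift stays below 1e−8 at the default tolerances (about
1e−10 in practice), and approaches within 1e−6 of either primary raise a
singularity error. Evaluation trajectories are generated by multiplying
each nonzero component of the reference initial state by (1 + ε) with ε
uniform in (−1%, +1%); zero components stay zero. Each trajectory splits
into contiguous washout (500), training (6500) and test (3000) segments;
the washout erases the arbitrary initial reservoir state.

## Echo state network

State update, with N-vector state x and 3-vector input u:

x_n = (1 − α) x_{n−1} + α tanh(W x_{n−1} + W_in [1; u_n]),

α = 0.9 (so the leakage rate 1 − α matches the 0.1 sampling step) and
input scaling 0.7. Each input-receiving neuron is wired to exactly one of
the three coordinates, chosen uniformly at random, with its input weight
and bias uniform(−1, 1) times the input scaling; so roughly a third of
the neurons see each coordinate. The initial state is the zero vector;
the washout makes this choice immaterial (verified by the fading-memory
test).

The readout is linear and trained in one shot by ridge regression,
W_out = Y Xᵀ (X Xᵀ + βI)⁻¹. The default regressor contains the
readout-visible states only, which makes the trained parameter count
exactly 3 × (number of visible neurons) — 150 at N = 50, 4500 at
N = 1500 with everything visible; a `full_regressor` mode stacking
[1; x; u] is also provided. At β = 0 the solve falls back to the plain
least-squares solution and raises on a singular system, advising β > 0.

Forecasting is open-loop direct h-step-ahead prediction: input u_n,
target u_{n+h}. Training targets are kept inside the training window and
test targets inside the trajectory. No autonomous closed-loop mode is
implemented. The error metric is

nRMSE = RMS(Y − Ŷ) / mean_t ‖Y_t‖,

the root-mean-square error over all 3T components normalized by the
time-mean Euclidean norm of the target — positive, scale-invariant, and
zero only for an exact prediction. A non-scale-invariant literal variant
(summed squared error over the grand mean of Y) is available behind a
flag for comparison.

## Synthetic connectome

The generator emulates the statistical features of the real data the
pipeline depends on, at a size (default 2000 neurons) where every stage
runs quickly:

* **classes**: a reduced vocabulary with the optic-lobe classes ME and
  ME>LO dominant, apportioned by largest remainder and spanning sensory,
  intermediate and output categories so class-restricted wiring is
  exercisable;
* **positions**: two mirrored Gaussian clusters (hemispheres) in
  nanometre coordinates;
* **topology**: a rewired ring lattice (degree 8, rewiring probability
  0.1, edges randomly oriented) for high clustering, plus 2% hub neurons
  receiving 30 degree-preferential attachments each for the
  hub-dominated degree tail — jointly a small-world organization;
* **weights**: connection score = 100 + log-normal(ln 150, 0.8), so
  magnitudes concentrate in the 10²–10³ decade with a heavy upper tail;
  synapses are excitatory with probability 0.6, making the signed weight
  distribution bimodal with both signs well represented;
* **filter fodder**: 5% of synapses get a sub-threshold cleft or
  connection score and 5% a modulatory-argmax transmitter, so the
  removal paths are exercised end to end.

What it does *not* model: class-conditional wiring, the real degree
sequence, spatial wiring statistics, or hemispheric asymmetries. Passing
tests therefore demonstrate the pipeline's correctness and the
qualitative overfitting-resilience phenomenology on small-world
bimodal-weight graphs, not quantitative agreement with the biological
connectome; whole-connectome results at N ≈ 10⁵ require the real data.

A deterministic 12-neuron / 30-synapse fixture with a hand-computed
expected graph covers every filter, sign, and aggregation branch.

## Monte Carlo comparison

The grid spans reservoir size, ridge regularizer β, forecast horizon,
weight distribution, selection criterion, spectral radius and
architecture; each combination is evaluated on several perturbed
trajectories with several re-initializations each (defaults: 5 × 10).
Within a (trajectory, trial) cell all architectures share the trajectory,
the input wiring and bias draws, and the spectral radius; the control
architecture re-draws everything per trial while connectome-based
variants re-draw only the input wiring. Reservoir states for a given
matrix and trajectory are computed once and reused across (β, horizon)
pairs — valid because the state sequence does not depend on the readout.
All randomness descends from a single master seed through named seed
sequences, making result tables bit-for-bit reproducible.

Comparisons use the two-sided Mann–Whitney–Wilcoxon rank test (midrank
ties, tie-corrected normal approximation with continuity correction),
flagged at p < 0.05 with no multiple-testing correction (markers are
reported individually), and the Bhattacharyya distance
D_B = −ln Σᵢ √(pᵢ qᵢ) between nRMSE distributions. The distance is
computed over a shared 10-bin histogram of the pooled samples — a
distribution-overlap reading; pairing individual datapoints does not
define an overlap — and then averaged over N and β (mean ± std).
Error bars in summaries are the standard deviation of the mean
(std/√n). Whole-graph mode restricts input wiring to sensory-class
neurons and readout visibility to output-class neurons per the default
class partition; a partition with no input classes at all degenerates to
the standard unrestricted wiring.

## Problem sizes used in the test suite

The automated suite exercises the full protocol at reduced scale, chosen
to keep a complete run comfortably interactive: a 2000-neuron synthetic
connectome; grid N ∈ {50, 200, 500}, β ∈ {1e−3, 1e−6, 1e−9},
horizons {1, 10}, one criterion and distribution, all five
architectures, 2 trajectories × 3 trials. At these sizes the control
architecture already shows the positive train-to-test gap at β = 1e−9
that motivates the comparison.

## Known limitations

* Graph neighbors (not spatial neighbors) are used when growing the
  most-connected selection; the two readings coincide in intent — both
  repair connectivity — and only graph neighbors guarantee it.
* The proportional criterion's connector is greedy, not minimal; the
  deviation is recorded in provenance.
* The sparse-matrix path of the spectral radius relies on Arnoldi
  convergence; for pathological spectra the dense fallback bound
  (N ≤ 2000) can be raised by the caller.
* Forecasting is strictly open-loop; closed-loop autonomous rollout is
  out of scope.
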