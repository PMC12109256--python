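"""Monte Carlo comparison of reservoir architectures.

Drives the grid over reservoir sizes, ridge regularizers, forecast
horizons, weight distributions, selection criteria and the five
architectures; each hyperparameter combination is evaluated on several
trajectories (1% perturbations of the reference initial conditions) with
several random re-initializations per trajectory. Within a (trajectory,
trial) cell all architectures share the trajectory, the input wiring and
the bias draws, and all matrices are rescaled to the same spectral radius,
so differences in forecast error isolate the architecture itself.

Also provides the comparison statistics (Mann-Whitney-Wilcoxon rank test,
Bhattacharyya distance between error distributions) and the
whole-connectome mode in which input and readout access are restricted by
neuron class.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from . import cr3bp, esn, selection
from .selection import ArchitectureKind, ReservoirMatrix

__all__ = [
    "GridSpec",
    "DEFAULT_CLASS_MAP",
    "run_grid",
    "mann_whitney_u",
    "bhattacharyya_distance",
    "full_connectome_trial",
    "summarize",
]

#: Partition of the neuron-class vocabulary into input / intermediate /
#: output roles for whole-connectome mode: sensory classes receive the
#: signal, output-side classes feed the readout.
DEFAULT_CLASS_MAP = {
    **{c: "input" for c in (
        "olfactory", "visual", "mechanosensory", "hygrosensory",
        "thermosensory", "gustatory", "ocellar", "unknown sensory",
    )},
    **{c: "intermediate" for c in (
        "CX", "ALPN", "LO", "bilateral", "ME", "ME>LOP", "ME>LO", "LO>LOP",
        "ME>LA", "LA>ME", "ME>LO.LOP", "ALLN", "LOP>ME.LO", "LOP>LO.ME",
        "LA", "AN", "ALIN", "mAL", "LHLN", "ME.LO", "ME.LO.LOP", "LO>ME",
        "optic lobes", "ME.LOP", "TPN",
    )},
    # LOP>LO.ME appears on both the intermediate and output sides of the
    # class partition; the readout-side (output) assignment wins here
    **{c: "output" for c in (
        "MBON", "DAN", "LHCENT", "clock", "pars intercerebralis",
        "pars lateralis", "Kenyon Cell", "ALON", "LOP>ME", "LOP>LO.ME",
        "LOP>LO", "LOP", "TuBu",
    )},
}

ALL_ARCHITECTURES = tuple(k.value for k in ArchitectureKind)


@dataclass
class GridSpec:
    """The Monte Carlo grid. Defaults mirror the full study protocol."""

    sizes: tuple = (50, 100, 300, 500, 700, 1000, 1300, 1500)
    betas: tuple = (1e-3, 1e-6, 1e-9)
    horizons: tuple = (1, 3, 7, 10)
    spectral_radii: tuple = (0.99,)
    criteria: tuple = ("most_connected", "proportional")
    distributions: tuple = ("uniform", "gaussian")
    architectures: tuple = ALL_ARCHITECTURES
    n_trajectories: int = 5
    trials_per_trajectory: int = 10
    alpha: float = 0.9
    input_scaling: float = 0.7
    washout: int = 500
    train: int = 6500
    test: int = 3000
    seed: int = 0

    def __post_init__(self):
        for name in ("sizes", "betas", "horizons", "spectral_radii",
                     "criteria", "distributions", "architectures"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.trials_per_trajectory < 1:
            raise ValueError("trials_per_trajectory must be >= 1")


_SELECTORS = {
    "most_connected": selection.select_most_connected,
    "proportional": selection.select_proportional,
}


def _trajectories(spec: GridSpec) -> list[cr3bp.Trajectory]:
    """The evaluation trajectories: 1% perturbations of the reference
    initial conditions, one per trajectory id."""
    steps = spec.washout + spec.train + spec.test
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC3]))
    out = []
    for _ in range(spec.n_trajectories):
        s0 = cr3bp.perturb_initial(cr3bp.REFERENCE_STATE0, 0.01, rng)
        out.append(cr3bp.propagate(s0, steps=steps))
    return out


def _evaluate_all(
    states: np.ndarray,
    positions: np.ndarray,
    spec: GridSpec,
) -> dict[tuple[float, int], tuple[float, float]]:
    """Train/test h-step-ahead nRMSE for every (beta, horizon) pair from
    one precomputed state sequence; the Gram matrix of the training states
    is shared across betas."""
    a, b = spec.washout, spec.washout + spec.train
    total = b + spec.test
    out = {}
    k = states.shape[0]
    for horizon in spec.horizons:
        train_idx = np.arange(a, b - horizon)
        test_idx = np.arange(b, total - horizon)
        x_train = states[:, train_idx]
        x_test = states[:, test_idx]
        y_train = positions[train_idx + horizon].T
        y_test = positions[test_idx + horizon].T
        gram = x_train @ x_train.T
        cross = y_train @ x_train.T
        for beta in spec.betas:
            reg = gram.copy()
            reg[np.diag_indices(k)] += beta
            wout = scipy.linalg.solve(reg, cross.T, assume_a="sym").T
            out[(beta, horizon)] = (
                esn.nrmse(y_train, wout @ x_train),
                esn.nrmse(y_test, wout @ x_test),
            )
    return out


def run_grid(spec: GridSpec, graph: nx.DiGraph) -> pd.DataFrame:
    """Run the full Monte Carlo grid; one row per evaluated combination.

    The reservoir states for a given (architecture, trajectory, trial) are
    computed once and reused across all (beta, horizon) pairs, which leaves
    the results identical to independent runs because the state sequence
    does not depend on the readout.
    """
    trajs = _trajectories(spec)
    rows = []
    for criterion in spec.criteria:
        selector = _SELECTORS[criterion]
        for n in spec.sizes:
            if n > graph.number_of_nodes():
                warnings.warn(f"skipping N={n}: graph has only "
                              f"{graph.number_of_nodes()} nodes")
                continue
            base = selection.extract_weight_matrix(selector(graph, n))
            for rho in spec.spectral_radii:
                for ti, traj in enumerate(trajs):
                    for trial in range(spec.trials_per_trajectory):
                        cell = np.random.SeedSequence(
                            [spec.seed, zlib.crc32(criterion.encode()), n,
                             int(rho * 1000), ti, trial]
                        )
                        shared_rng, arch_rng = [
                            np.random.default_rng(s) for s in cell.spawn(2)
                        ]
                        # shared across architectures and distributions
                        input_map = esn.build_input_map(
                            n, spec.input_scaling, rng=shared_rng
                        )
                        win_hash = zlib.crc32(input_map.Win.tobytes())
                        for dist in spec.distributions:
                            for arch in spec.architectures:
                                variant = selection.randomize(
                                    base, arch, dist=dist,
                                    rng=np.random.default_rng(arch_rng.integers(2**31)),
                                    target=rho,
                                )
                                states = esn.run_reservoir(
                                    variant.W, input_map,
                                    traj.positions, alpha=spec.alpha,
                                )
                                scores = _evaluate_all(states, traj.positions, spec)
                                for beta in spec.betas:
                                    for horizon in spec.horizons:
                                        tr, te = scores[(beta, horizon)]
                                        rows.append({
                                            "architecture": arch,
                                            "criterion": criterion,
                                            "N": n,
                                            "beta": beta,
                                            "horizon": horizon,
                                            "distribution": dist,
                                            "spectral_radius": rho,
                                            "trajectory": ti,
                                            "trial": trial,
                                            "train_nrmse": tr,
                                            "test_nrmse": te,
                                            "seed": spec.seed,
                                            "win_hash": win_hash,
                                        })
    return pd.DataFrame(rows)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    Midrank ties, tie-corrected normal approximation with continuity
    correction. Returns (U of the first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bhattacharyya_distance(a, b, n_bins: int = 10) -> float:
    """Bhattacharyya distance between two samples' distributions.

    Both samples are histogrammed over the shared range of the pooled data
    with ``n_bins`` bins and normalized to probability vectors p, q;
    DB = -ln sum_i sqrt(p_i q_i). Symmetric, >= 0, zero for identical
    samples; +inf when the histograms do not overlap at all.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:  # all values identical: full overlap
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p = np.histogram(a, bins=edges)[0] / a.size
    q = np.histogram(b, bins=edges)[0] / b.size
    coeff = float(np.sum(np.sqrt(p * q)))
    if coeff <= 0.0:
        return float("inf")
    return float(-np.log(min(coeff, 1.0)))


def full_connectome_trial(
    graph: nx.DiGraph,
    config: esn.EsnConfig,
    traj: cr3bp.Trajectory,
    class_map: dict | None = None,
    rng: np.random.Generator | None = None,
    reservoir: ReservoirMatrix | None = None,
) -> esn.EsnTrial:
    """One forecasting trial using the whole graph as the reservoir, with
    input and readout access restricted by neuron class.

    ``class_map`` assigns each cell class to 'input', 'intermediate' or
    'output'; input-class neurons receive the signal, output-class neurons
    feed the readout (3 x |output| trained parameters). Pass a prebuilt
    ``reservoir`` to amortize extraction over repeated trials.
    """
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    if reservoir is None:
        sub = graph
        base = selection.extract_weight_matrix(sub)
        base.W = selection.rescale_spectral(base.W)
        reservoir = base
    roles = [class_map.get(c, "intermediate") for c in reservoir.class_labels]
    input_nodes = np.flatnonzero([r == "input" for r in roles])
    output_nodes = np.flatnonzero([r == "output" for r in roles])
    if input_nodes.size == 0:
        if any(r == "input" for r in class_map.values()):
            raise ValueError("no neurons belong to an input class")
        # degenerate partition with no input classes at all: every neuron
        # receives the signal, as in the standard unrestricted trial
        input_nodes = np.arange(reservoir.n)
    if output_nodes.size == 0:
        raise ValueError("no neurons belong to an output class")
    return esn.forecast_trial(
        reservoir.W, config, traj, rng=rng,
        input_nodes=input_nodes, visible_index=output_nodes,
    )


_CELL = ["criterion", "N", "beta", "horizon", "distribution", "spectral_radius"]


def summarize(
    results: pd.DataFrame,
    control: str = ArchitectureKind.CONTROL_RANDOM.value,
    alpha: float = 0.05,
    metric: str = "test_nrmse",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-combination summary statistics and architecture comparisons.

    Returns ``(summary, distances)``. ``summary`` has, per (architecture x
    hyperparameter combination), the mean and the standard deviation of the
    mean of the nRMSE over trials, plus the two-sided
    Mann-Whitney-Wilcoxon p-value against the control architecture in the
    same cell and its significance flag at p < alpha. ``distances`` holds
    the Bhattacharyya distance between each architecture's nRMSE
    distribution and the control's, computed per (N, beta) cell and then
    averaged (mean +- std) over N and beta.
    """
    if results["architecture"].nunique() < 2:
        raise ValueError("need at least two architectures to compare")
    group_cols = ["architecture"] + _CELL
    recs = []
    for keys, cell in results.groupby(group_cols, sort=True):
        vals = cell[metric].to_numpy()
        n = vals.size
        if n < 2:
            warnings.warn("single-trial cell: std of the mean reported as 0")
        rec = dict(zip(group_cols, keys))
        rec["mean"] = vals.mean()
        rec["sem"] = vals.std(ddof=0) / np.sqrt(n) if n > 1 else 0.0
        rec["n_trials"] = n
        recs.append(rec)
    summary = pd.DataFrame(recs)

    pvals, flags = [], []
    for _, row in summary.iterrows():
        if row["architecture"] == control:
            pvals.append(np.nan)
            flags.append(False)
            continue
        sel = (results["architecture"] == row["architecture"])
        ctl = (results["architecture"] == control)
        for c in _CELL:
            sel &= results[c] == row[c]
            ctl &= results[c] == row[c]
        if not ctl.any():
            pvals.append(np.nan)
            flags.append(False)
            continue
        a = results.loc[sel, metric].to_numpy()
        b = results.loc[ctl, metric].to_numpy()
        if np.array_equal(a, b):
            p = 1.0  # identical samples: no separation
        else:
            _, p = mann_whitney_u(a, b)
        pvals.append(p)
        flags.append(bool(p < alpha))
    summary["p_vs_control"] = pvals
    summary["significant"] = flags

    dist_recs = []
    pair_cols = [c for c in _CELL if c not in ("N", "beta")]
    for arch in sorted(results["architecture"].unique()):
        if arch == control:
            continue
        for keys, block in results.groupby(pair_cols, sort=True):
            dbs = []
            for _, cell in block.groupby(["N", "beta"], sort=True):
                a = cell.loc[cell["architecture"] == arch, metric].to_numpy()
                b = cell.loc[cell["architecture"] == control, metric].to_numpy()
                if a.size and b.size:
                    dbs.append(bhattacharyya_distance(a, b))
            if dbs:
                rec = dict(zip(pair_cols, keys))
                rec.update(
                    architecture=arch,
                    control=control,
                    bhattacharyya_mean=float(np.mean(dbs)),
                    bhattacharyya_std=float(np.std(dbs)),
                    n_cells=len(dbs),
                )
                dist_recs.append(rec)
    return summary, pd.DataFrame(dist_recs)
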