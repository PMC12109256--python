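"""Leaky echo-state network with a one-shot ridge-regression readout.

State update: x_n = (1 - alpha) x_{n-1} + alpha tanh(W x_{n-1} + Win [1; u_n]),
with alpha = 0.9 and input scaling 0.7 by default. Each input-receiving
neuron is wired to exactly one of the three Cartesian coordinates of the
trajectory, chosen uniformly at random. The readout is trained in one shot
by ridge regression, Wout = Y X^T (X X^T + beta I)^{-1}, over the training
window, and forecasting is open-loop direct h-step-ahead prediction
(input u_n, target u_{n+h}). Performance is the normalized root mean
squared error (nRMSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .cr3bp import Trajectory

__all__ = [
    "EsnConfig",
    "InputMap",
    "Readout",
    "EsnTrial",
    "build_input_map",
    "run_reservoir",
    "train_readout",
    "nrmse",
    "forecast_trial",
]


@dataclass(frozen=True)
class EsnConfig:
    """Hyperparameters of one forecasting trial.

    ``alpha`` is the state-update mixing coefficient (1 - alpha is the
    leakage rate), ``beta`` the ridge regularizer, ``horizon`` the forecast
    offset in samples, and the three window lengths partition the
    trajectory.
    """

    alpha: float = 0.9
    input_scaling: float = 0.7
    beta: float = 1e-6
    horizon: int = 1
    washout: int = 500
    train: int = 6500
    test: int = 3000

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.input_scaling < 0:
            raise ValueError("input_scaling must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass
class InputMap:
    """Input wiring: Win is N x 4 (bias column then x, y, z columns).

    ``assignment[i]`` is the coordinate index fed to neuron i, or -1 for
    neurons that receive no input.
    """

    Win: np.ndarray
    assignment: np.ndarray

    @property
    def n(self) -> int:
        return self.Win.shape[0]


@dataclass
class Readout:
    """Trained linear readout over the readout-visible state components."""

    Wout: np.ndarray            # 3 x K (or 3 x (1 + K + 3) in full mode)
    visible_index: np.ndarray   # neurons feeding the readout
    mode: str = "states_only"

    @property
    def n_parameters(self) -> int:
        return int(self.Wout.size)

    def predict(self, x_visible: np.ndarray, u: np.ndarray | None = None) -> np.ndarray:
        if self.mode == "states_only":
            return self.Wout @ x_visible
        ones = np.ones((1, x_visible.shape[1]))
        if u is None:
            raise ValueError("full_regressor mode needs the input series")
        return self.Wout @ np.vstack([ones, x_visible, u])


@dataclass
class EsnTrial:
    """Result of one architecture/config evaluation."""

    train_nrmse: float
    test_nrmse: float
    config: EsnConfig
    n_parameters: int = 0
    meta: dict = field(default_factory=dict)


def build_input_map(
    n: int,
    input_scaling: float = 0.7,
    rng: np.random.Generator | None = None,
    input_nodes: Sequence[int] | None = None,
) -> InputMap:
    """Wire each input-receiving neuron to one random trajectory coordinate.

    Coordinate assignment is uniform over {x, y, z}; the input weight and
    the bias of each input neuron are drawn uniform(-1, 1) times
    ``input_scaling``. Neurons outside ``input_nodes`` (default: all
    neurons) get all-zero rows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    if input_nodes is None:
        input_nodes = np.arange(n)
    else:
        input_nodes = np.asarray(input_nodes, dtype=int)
        if input_nodes.size == 0:
            raise ValueError("input_nodes must not be empty")
    win = np.zeros((n, 4))
    assignment = np.full(n, -1, dtype=int)
    coords = rng.integers(0, 3, size=input_nodes.size)
    biases = rng.uniform(-1.0, 1.0, size=input_nodes.size) * input_scaling
    weights = rng.uniform(-1.0, 1.0, size=input_nodes.size) * input_scaling
    assignment[input_nodes] = coords
    win[input_nodes, 0] = biases
    win[input_nodes, 1 + coords] = weights
    return InputMap(Win=win, assignment=assignment)


def run_reservoir(
    w: np.ndarray | sp.spmatrix,
    input_map: InputMap,
    inputs: np.ndarray,
    alpha: float = 0.9,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Drive the reservoir with a T x 3 input series; return N x T states.

    Column n holds the state after consuming input sample n.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 2 or inputs.shape[1] != 3:
        raise ValueError("inputs must be T x 3")
    n = input_map.n
    if w.shape != (n, n):
        raise ValueError(f"W is {w.shape} but input map expects {(n, n)}")
    ws = sp.csr_matrix(w) if not sp.issparse(w) else w.tocsr()
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    if x.shape != (n,):
        raise ValueError("x0 has wrong shape")
    t = inputs.shape[0]
    # precompute the input drive for the whole series: Win [1; u_n]
    drive = input_map.Win[:, 0][:, None] + input_map.Win[:, 1:] @ inputs.T
    states = np.empty((n, t))
    for k in range(t):
        x = (1.0 - alpha) * x + alpha * np.tanh(ws @ x + drive[:, k])
        states[:, k] = x
    return states


def train_readout(
    x: np.ndarray,
    y: np.ndarray,
    beta: float,
    u: np.ndarray | None = None,
    mode: str = "states_only",
    visible_index: np.ndarray | None = None,
) -> Readout:
    """One-shot ridge regression of the readout weights.

    ``x`` holds the readout-visible states (K x T) and ``y`` the targets
    (3 x T). ``states_only`` regresses on the states alone (3 K trained
    parameters); ``full_regressor`` stacks [1; x; u]. At beta = 0 a
    singular normal system raises, advising beta > 0.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("X and Y must have the same number of columns")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if mode == "states_only":
        reg = x
    elif mode == "full_regressor":
        if u is None:
            raise ValueError("full_regressor mode needs the input series U")
        u = np.atleast_2d(np.asarray(u, dtype=float))
        reg = np.vstack([np.ones((1, x.shape[1])), x, u])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    gram = reg @ reg.T
    gram[np.diag_indices_from(gram)] += beta
    try:
        wout = scipy.linalg.solve(gram, reg @ y.T, assume_a="sym").T
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as err:
        raise np.linalg.LinAlgError(
            "normal equations are singular; use beta > 0 for a regularized solve"
        ) from err
    if not np.all(np.isfinite(wout)):
        raise np.linalg.LinAlgError(
            "normal equations are singular; use beta > 0 for a regularized solve"
        )
    if visible_index is None:
        visible_index = np.arange(x.shape[0])
    return Readout(Wout=wout, visible_index=np.asarray(visible_index), mode=mode)


def nrmse(y: np.ndarray, yhat: np.ndarray, literal: bool = False) -> float:
    """Normalized root mean squared error between 3 x T targets and predictions.

    Default: RMS error over all components, normalized by the time-mean of
    the Euclidean norm of the target vectors — positive, scale-invariant,
    zero iff the prediction is exact. ``literal=True`` instead divides the
    summed squared error by the grand mean of Y (an alternative reading of
    the same name; not scale-invariant).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float))
    if y.shape != yhat.shape:
        raise ValueError("Y and Yhat must have the same shape")
    if literal:
        denom = y.mean()
        if denom == 0:
            raise ValueError("mean of Y is zero; literal normalization undefined")
        return float(np.sum((y - yhat) ** 2) / denom)
    scale = np.mean(np.linalg.norm(y, axis=0))
    if scale == 0:
        raise ValueError("all-zero targets; nRMSE normalization undefined")
    return float(np.sqrt(np.mean((y - yhat) ** 2)) / scale)


def forecast_trial(
    w: np.ndarray | sp.spmatrix,
    config: EsnConfig,
    traj: Trajectory,
    rng: np.random.Generator | None = None,
    input_map: InputMap | None = None,
    input_nodes: Sequence[int] | None = None,
    visible_index: Sequence[int] | None = None,
) -> EsnTrial:
    """Run one full forecasting trial on a trajectory.

    Builds (or reuses) the input wiring, drives the reservoir through
    washout + train + test, trains the readout on h-step-ahead targets of
    the training window, and evaluates open-loop h-step-ahead nRMSE on both
    windows. Training targets stay inside the training window; test targets
    stay inside the trajectory.
    """
    n = w.shape[0]
    total = config.washout + config.train + config.test
    if total > len(traj):
        raise ValueError("split exceeds trajectory length")
    h = config.horizon
    if h >= config.train or h >= config.test:
        raise ValueError("horizon must be shorter than the train and test windows")
    if input_map is None:
        input_map = build_input_map(
            n, config.input_scaling, rng=rng, input_nodes=input_nodes
        )
    p = traj.positions[:total]
    states = run_reservoir(w, input_map, p, alpha=config.alpha)
    visible = (
        np.arange(n) if visible_index is None else np.asarray(visible_index, dtype=int)
    )
    if visible.size == 0:
        raise ValueError("visible_index must not be empty")

    a, b = config.washout, config.washout + config.train
    train_idx = np.arange(a, b - h)
    test_idx = np.arange(b, total - h)
    xs = states[visible]
    readout = train_readout(
        xs[:, train_idx], p[train_idx + h].T, config.beta, u=p[train_idx].T,
        mode="states_only", visible_index=visible,
    )
    yhat_train = readout.predict(xs[:, train_idx], p[train_idx].T)
    yhat_test = readout.predict(xs[:, test_idx], p[test_idx].T)
    return EsnTrial(
        train_nrmse=nrmse(p[train_idx + h].T, yhat_train),
        test_nrmse=nrmse(p[test_idx + h].T, yhat_test),
        config=config,
        n_parameters=readout.n_parameters,
        meta={"n": n, "visible": int(visible.size)},
    )
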