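"""Circularly restricted three-body problem (CR3BP) trajectory generation.

The forecasting task: motion of a massless particle in the rotating frame
of two primaries (mass ratio mu), in normalized units where the
primary-secondary separation and the angular rate are both 1. The Jacobi
constant is the conserved integral used to validate propagation. Defaults
follow the study conditions: earth-moon mass ratio, sampling step 0.1,
10,000 samples per trajectory, split into washout / train / test segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "EARTH_MOON_MU",
    "StateVector",
    "Trajectory",
    "propagate",
    "jacobi_constant",
    "perturb_initial",
    "split_trajectory",
]

#: Standard earth-moon mass ratio m2 / (m1 + m2).
EARTH_MOON_MU = 0.0121505856

#: Initial conditions of the reference trajectory family.
REFERENCE_STATE0 = np.array([-0.80, 0.0, 0.0, 0.0, -0.63, 0.08])

_SINGULARITY_RADIUS = 1e-6


StateVector = np.ndarray  # shape (6,): x, y, z, vx, vy, vz


@dataclass
class Trajectory:
    """A sampled CR3BP trajectory in the rotating frame."""

    positions: np.ndarray          # (T, 3)
    velocities: np.ndarray         # (T, 3)
    dt: float
    mu: float
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def states(self) -> np.ndarray:
        return np.hstack([self.positions, self.velocities])


class SingularityError(RuntimeError):
    """The particle approached a primary closer than the cutoff radius."""


def _accelerations(state: np.ndarray, mu: float) -> np.ndarray:
    x, y, z, vx, vy, vz = state
    ax = 2 * vy + x
    ay = -2 * vx + y
    az = 0.0
    # a zero-mass primary exerts no force; skipping it avoids 0 * (0/0)
    if mu < 1.0:
        r1c = ((x + mu) ** 2 + y * y + z * z) ** 1.5
        ax -= (1 - mu) * (x + mu) / r1c
        ay -= (1 - mu) * y / r1c
        az -= (1 - mu) * z / r1c
    if mu > 0.0:
        r2c = ((x - 1 + mu) ** 2 + y * y + z * z) ** 1.5
        ax -= mu * (x - 1 + mu) / r2c
        ay -= mu * y / r2c
        az -= mu * z / r2c
    return np.array([vx, vy, vz, ax, ay, az])


def _primary_distances(state: np.ndarray, mu: float) -> tuple[float, float]:
    x, y, z = state[:3]
    r1 = np.sqrt((x + mu) ** 2 + y * y + z * z)
    r2 = np.sqrt((x - 1 + mu) ** 2 + y * y + z * z)
    return float(r1), float(r2)


def propagate(
    state0: StateVector,
    mu: float = EARTH_MOON_MU,
    dt: float = 0.1,
    steps: int = 10000,
    rtol: float = 1e-12,
    atol: float = 1e-12,
) -> Trajectory:
    """Propagate the rotating-frame CR3BP equations of motion.

    Uses adaptive 8th-order Runge-Kutta (DOP853) sampled every ``dt`` for
    ``steps`` samples (the first sample is the initial state). ``dt`` may
    be negative for backward propagation. Raises :class:`SingularityError`
    if the particle approaches either primary within 1e-6.
    """
    state0 = np.asarray(state0, dtype=float)
    if state0.shape != (6,):
        raise ValueError("state0 must be a 6-vector [x, y, z, vx, vy, vz]")
    if not 0.0 <= mu <= 0.5:
        raise ValueError("mu must lie in [0, 0.5]")
    if steps < 1:
        raise ValueError("steps must be >= 1")

    t_eval = dt * np.arange(steps)

    def rhs(t, s):
        return _accelerations(s, mu)

    def close_approach(t, s):
        r1, r2 = _primary_distances(s, mu)
        # only massive primaries are singular
        r = r1 if mu == 0.0 else (r2 if mu == 1.0 else min(r1, r2))
        return r - _SINGULARITY_RADIUS

    close_approach.terminal = True

    sol = solve_ivp(
        rhs,
        (0.0, t_eval[-1] if steps > 1 else dt),
        state0,
        method="DOP853",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        events=close_approach,
    )
    if sol.status == 1:
        step = int(np.searchsorted(np.abs(t_eval), abs(sol.t_events[0][0])))
        raise SingularityError(
            f"close approach to a primary near sample {step} "
            f"(t = {sol.t_events[0][0]:.3f})"
        )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")

    states = sol.y.T
    jac = np.array([jacobi_constant(s, mu) for s in states])
    return Trajectory(
        positions=states[:, :3].copy(),
        velocities=states[:, 3:].copy(),
        dt=dt,
        mu=mu,
        provenance={
            "state0": state0.tolist(),
            "rtol": rtol,
            "atol": atol,
            "jacobi_drift": float(np.max(np.abs(jac - jac[0]))),
        },
    )


def jacobi_constant(state: StateVector, mu: float = EARTH_MOON_MU) -> float:
    """C = x^2 + y^2 + 2(1-mu)/r1 + 2 mu/r2 - |v|^2."""
    state = np.asarray(state, dtype=float)
    x, y, _z = state[:3]
    r1, r2 = _primary_distances(state, mu)
    if (mu < 1.0 and r1 <= _SINGULARITY_RADIUS) or (
        mu > 0.0 and r2 <= _SINGULARITY_RADIUS
    ):
        raise SingularityError("state lies on (or numerically at) a primary")
    v2 = float(np.dot(state[3:], state[3:]))
    potential = 0.0
    if mu < 1.0:
        potential += 2 * (1 - mu) / r1
    if mu > 0.0:
        potential += 2 * mu / r2
    return x * x + y * y + potential - v2


def perturb_initial(
    state0: StateVector,
    fraction: float = 0.01,
    rng: np.random.Generator | None = None,
) -> StateVector:
    """Multiplicatively perturb each nonzero component by up to +-fraction.

    Each nonzero component is multiplied by (1 + eps) with eps drawn
    uniformly from (-fraction, +fraction); zero components stay zero.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    state0 = np.asarray(state0, dtype=float).copy()
    eps = rng.uniform(-fraction, fraction, size=state0.shape)
    nonzero = state0 != 0.0
    state0[nonzero] *= 1.0 + eps[nonzero]
    return state0


def split_trajectory(
    traj: Trajectory, washout_len: int, train_len: int, test_len: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split positions into contiguous washout / train / test segments."""
    lengths = (washout_len, train_len, test_len)
    if any(l < 0 for l in lengths):
        raise ValueError("segment lengths must be non-negative")
    if sum(lengths) > len(traj):
        raise ValueError(
            f"segments sum to {sum(lengths)} but trajectory has {len(traj)} samples"
        )
    a, b = washout_len, washout_len + train_len
    c = b + test_len
    p = traj.positions
    return p[:a], p[a:b], p[b:c]
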