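"""Echo-state network: state update, readout training, nRMSE, trials."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connres import esn
from connres.cr3bp import Trajectory
from connres.esn import EsnConfig


def _toy_trajectory(t=600, constant=None, seed=0):
    """A synthetic smooth 3D series (not a physical orbit) for fast tests."""
    if constant is not None:
        pos = np.tile(np.asarray(constant, dtype=float), (t, 1))
    else:
        rng = np.random.default_rng(seed)
        phase = rng.uniform(0, 2 * np.pi, 3)
        k = np.arange(t)[:, None] * np.array([0.031, 0.017, 0.043])
        pos = np.sin(k + phase)
    return Trajectory(
        positions=pos, velocities=np.zeros_like(pos), dt=0.1, mu=0.0,
        provenance={"synthetic": True},
    )


class TestBuildInputMap:
    def test_coordinate_assignment_binomial(self):
        im = esn.build_input_map(3000, rng=np.random.default_rng(0))
        counts = np.bincount(im.assignment, minlength=3)
        assert counts.sum() == 3000
        sigma = np.sqrt(3000 * (1 / 3) * (2 / 3))
        assert np.abs(counts - 1000).max() < 3 * sigma

    def test_each_input_row_has_one_coordinate(self):
        im = esn.build_input_map(50, rng=np.random.default_rng(1))
        nonzero_coord_cols = (im.Win[:, 1:] != 0).sum(axis=1)
        assert (nonzero_coord_cols == 1).all()
        assert np.abs(im.Win).max() <= 0.7

    def test_zero_scaling(self):
        im = esn.build_input_map(20, input_scaling=0.0,
                                 rng=np.random.default_rng(2))
        assert not im.Win.any()

    def test_seed_reproducible(self):
        a = esn.build_input_map(100, rng=np.random.default_rng(5))
        b = esn.build_input_map(100, rng=np.random.default_rng(5))
        assert np.array_equal(a.Win, b.Win)
        assert np.array_equal(a.assignment, b.assignment)

    def test_restricted_input_nodes(self):
        im = esn.build_input_map(10, rng=np.random.default_rng(3),
                                 input_nodes=[2, 5])
        untouched = np.delete(np.arange(10), [2, 5])
        assert not im.Win[untouched].any()
        assert (im.assignment[untouched] == -1).all()
        with pytest.raises(ValueError):
            esn.build_input_map(10, input_nodes=[])


class TestRunReservoir:
    def test_alpha_zero_freezes_state(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(5, 5))
        im = esn.build_input_map(5, rng=rng)
        x0 = rng.normal(size=5)
        states = esn.run_reservoir(w, im, rng.normal(size=(10, 3)),
                                   alpha=0.0, x0=x0)
        assert np.allclose(states, x0[:, None])

    def test_zero_system_stays_zero(self):
        im = esn.InputMap(Win=np.zeros((4, 4)), assignment=np.full(4, -1))
        states = esn.run_reservoir(np.zeros((4, 4)), im,
                                   np.ones((8, 3)), alpha=0.9)
        assert not states.any()

    def test_single_neuron_hand_unrolled(self):
        # x_n = 0.1 x_{n-1} + 0.9 tanh(0.5 x_{n-1} + b + w u)
        w = np.array([[0.5]])
        win = np.array([[0.3, 0.2, 0.0, 0.0]])
        im = esn.InputMap(Win=win, assignment=np.array([0]))
        u = np.full((20, 3), 0.8)
        states = esn.run_reservoir(w, im, u, alpha=0.9)
        x = 0.0
        for n in range(20):
            x = 0.1 * x + 0.9 * np.tanh(0.5 * x + 0.3 + 0.2 * 0.8)
            assert states[0, n] == pytest.approx(x, abs=1e-12)

    def test_dimension_mismatch(self):
        im = esn.build_input_map(5, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            esn.run_reservoir(np.zeros((4, 4)), im, np.zeros((10, 3)))

    def test_fading_memory(self):
        # spectral radius 0.5: initial-condition dependence washes out
        rng = np.random.default_rng(6)
        from connres.selection import rescale_spectral

        w = rescale_spectral(rng.normal(size=(60, 60)), 0.5)
        im = esn.build_input_map(60, rng=np.random.default_rng(7))
        u = rng.uniform(-1, 1, (200, 3))
        a = esn.run_reservoir(w, im, u, x0=np.zeros(60))
        b = esn.run_reservoir(w, im, u, x0=rng.uniform(-1, 1, 60))
        assert np.abs(a[:, -1] - b[:, -1]).max() < 1e-6


class TestTrainReadout:
    def test_exact_recovery_of_linear_map(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 200))
        w_true = rng.normal(size=(3, 10))
        readout = esn.train_readout(x, w_true @ x, beta=0.0)
        assert np.allclose(readout.Wout, w_true, atol=1e-10)
        assert readout.n_parameters == 30

    def test_ridge_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 100))
        readout = esn.train_readout(x, rng.normal(size=(3, 100)), beta=1e12)
        assert np.abs(readout.Wout).max() <= 1e-6

    def test_matches_independent_normal_equation_solve(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 200))
        y = rng.normal(size=(3, 200))
        beta = 1e-3
        want = y @ x.T @ np.linalg.inv(x @ x.T + beta * np.eye(20))
        readout = esn.train_readout(x, y, beta=beta)
        assert np.allclose(readout.Wout, want, atol=1e-10)
        resid = readout.Wout @ (x @ x.T + beta * np.eye(20)) - y @ x.T
        assert np.linalg.norm(resid) <= 1e-8 * np.linalg.norm(y @ x.T)

    def test_beta_zero_equals_least_squares(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 300))
        y = rng.normal(size=(3, 300))
        lsq = np.linalg.lstsq(x.T, y.T, rcond=None)[0].T
        readout = esn.train_readout(x, y, beta=0.0)
        assert np.allclose(readout.Wout, lsq, atol=1e-9)

    def test_singular_at_beta_zero_advises(self):
        x = np.ones((4, 50))  # rank one
        y = np.random.default_rng(4).normal(size=(3, 50))
        with pytest.raises(np.linalg.LinAlgError, match="beta > 0"):
            esn.train_readout(x, y, beta=0.0)

    def test_full_regressor_mode(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 100))
        u = rng.normal(size=(3, 100))
        y = rng.normal(size=(3, 100))
        readout = esn.train_readout(x, y, beta=1e-6, u=u, mode="full_regressor")
        assert readout.Wout.shape == (3, 1 + 6 + 3)
        pred = readout.predict(x, u)
        assert pred.shape == (3, 100)


class TestNrmse:
    def test_zero_iff_exact(self):
        y = np.random.default_rng(0).normal(size=(3, 50))
        assert esn.nrmse(y, y) == 0.0
        assert esn.nrmse(y, y + 0.1) > 0

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, a):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(3, 40))
        yhat = y + rng.normal(size=(3, 40))
        assert esn.nrmse(a * y, a * yhat) == pytest.approx(esn.nrmse(y, yhat))

    def test_closed_form_constant_offset(self):
        # constant target norm c, offset d on one coordinate -> d / (c sqrt 3)
        c, d, t = 2.0, 0.3, 64
        y = np.zeros((3, t))
        y[0] = c
        yhat = y.copy()
        yhat[1] += d
        assert esn.nrmse(y, yhat) == pytest.approx(d / (c * np.sqrt(3)))

    def test_zero_targets_error(self):
        with pytest.raises(ValueError):
            esn.nrmse(np.zeros((3, 10)), np.ones((3, 10)))


class TestForecastTrial:
    CFG = dict(washout=50, train=300, test=150)

    def test_constant_trajectory_is_predictable(self):
        traj = _toy_trajectory(600, constant=(0.5, 0.3, 0.2))
        rng = np.random.default_rng(0)
        from connres.selection import rescale_spectral

        w = rescale_spectral(rng.normal(size=(30, 30)) *
                             (rng.random((30, 30)) < 0.3))
        trial = esn.forecast_trial(
            w, EsnConfig(beta=1e-9, horizon=1, **self.CFG), traj,
            rng=np.random.default_rng(1),
        )
        assert trial.test_nrmse <= 1e-6

    def test_seed_determinism(self):
        traj = _toy_trajectory(600)
        rng = np.random.default_rng(2)
        from connres.selection import rescale_spectral

        w = rescale_spectral(rng.normal(size=(40, 40)) *
                             (rng.random((40, 40)) < 0.2))
        cfg = EsnConfig(beta=1e-6, horizon=3, **self.CFG)
        a = esn.forecast_trial(w, cfg, traj, rng=np.random.default_rng(7))
        b = esn.forecast_trial(w, cfg, traj, rng=np.random.default_rng(7))
        assert a.train_nrmse == b.train_nrmse
        assert a.test_nrmse == b.test_nrmse

    def test_parameter_count_is_three_per_visible_neuron(self):
        traj = _toy_trajectory(600)
        rng = np.random.default_rng(3)
        from connres.selection import rescale_spectral

        w = rescale_spectral(rng.normal(size=(25, 25)))
        cfg = EsnConfig(beta=1e-6, horizon=1, **self.CFG)
        full = esn.forecast_trial(w, cfg, traj, rng=np.random.default_rng(0))
        assert full.n_parameters == 3 * 25
        restricted = esn.forecast_trial(
            w, cfg, traj, rng=np.random.default_rng(0),
            visible_index=np.arange(10),
        )
        assert restricted.n_parameters == 3 * 10

    def test_horizon_validation(self):
        traj = _toy_trajectory(600)
        with pytest.raises(ValueError, match="horizon"):
            esn.forecast_trial(
                np.eye(5) * 0.5,
                EsnConfig(beta=1e-6, horizon=200, **self.CFG), traj,
                rng=np.random.default_rng(0),
            )

    def test_sanity_on_cr3bp(self, reference_trajectory):
        # a modest reservoir forecasts one step ahead far better than the
        # target scale, and training error does not exceed test error
        rng = np.random.default_rng(10)
        from connres.selection import rescale_spectral

        w = rescale_spectral(rng.normal(size=(200, 200)) *
                             (rng.random((200, 200)) < 0.05))
        trial = esn.forecast_trial(
            w, EsnConfig(beta=1e-6, horizon=1), reference_trajectory,
            rng=np.random.default_rng(11),
        )
        assert np.isfinite(trial.train_nrmse)
        assert trial.test_nrmse < 1.0
        assert trial.train_nrmse <= trial.test_nrmse
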