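"""Backprop network: initialisation, forward pass, training, sweep."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import neurodim as nd
from neurodim.errors import ConfigError, ScalingError
from neurodim.network import (
    NetworkConfig,
    NetworkState,
    SweepCell,
    forward_batch,
    loss_and_gradients,
    sigmoid,
    sweep_table,
)


def xor_data(reps=10):
    pats = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    targ = np.array([[0.0], [1.0], [1.0], [0.0]])
    return np.tile(pats, (reps, 1)), np.tile(targ, (reps, 1))


class TestInit:
    def test_weights_within_halfwidth(self):
        state = nd.init_network(NetworkConfig(seed=3))
        for w in (state.w_hidden, state.w_output):
            assert np.abs(w).max() <= 0.5

    def test_same_seed_identical(self):
        a = nd.init_network(NetworkConfig(seed=11))
        b = nd.init_network(NetworkConfig(seed=11))
        assert np.array_equal(a.w_hidden, b.w_hidden)
        assert np.array_equal(a.w_output, b.w_output)

    def test_shapes_include_bias_rows(self):
        state = nd.init_network(NetworkConfig(n_inputs=10, n_hidden=5, n_outputs=3))
        assert state.w_hidden.shape == (11, 5)
        assert state.w_output.shape == (6, 3)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            nd.init_network(NetworkConfig(n_hidden=0))


class TestForward:
    def test_zero_weights_give_half(self):
        state = NetworkState(np.zeros((11, 10)), np.zeros((11, 9)))
        _, out = nd.forward(state, np.full(10, 0.3))
        assert np.allclose(out, 0.5)

    def test_hand_computed_single_hidden_unit(self):
        # 1 input, 1 hidden, 1 output with hand-set weights
        state = NetworkState(
            np.array([[0.4], [0.1]]),        # w=0.4, bias=0.1
            np.array([[-0.3], [0.2]]),       # v=-0.3, bias=0.2
        )
        h_expected = sigmoid(np.array(0.4 * 0.5 + 0.1))
        o_expected = sigmoid(-0.3 * h_expected + 0.2)
        h, o = nd.forward(state, np.array([0.5]))
        assert h[0] == pytest.approx(float(h_expected), abs=1e-15)
        assert o[0] == pytest.approx(float(o_expected), abs=1e-15)

    def test_saturation(self):
        state = NetworkState(np.full((2, 1), 50.0), np.full((2, 1), 50.0))
        _, out = nd.forward(state, np.array([1.0]))
        assert out[0] == pytest.approx(1.0, abs=1e-12)

    def test_non_finite_input_rejected(self):
        state = nd.init_network(NetworkConfig())
        with pytest.raises(ValueError):
            nd.forward(state, np.full(10, np.nan))


class TestTraining:
    def test_zero_learning_rate_is_inert(self, rng):
        X = rng.random((40, 10))
        Y = rng.random((40, 9))
        cfg = NetworkConfig(learning_rate=0.0, epochs=5, seed=1)
        state = nd.init_network(cfg)
        trained, trace = nd.train(state, X, Y, cfg)
        assert np.array_equal(trained.w_hidden, state.w_hidden)
        assert np.array_equal(trained.w_output, state.w_output)
        assert len(set(trace.sse)) == 1

    def test_trace_length_and_nonnegative(self, rng):
        X = rng.random((30, 10))
        Y = rng.random((30, 9))
        cfg = NetworkConfig(epochs=7, train_sample_size=20, seed=2)
        _, trace = nd.train(nd.init_network(cfg), X, Y, cfg)
        assert len(trace.sse) == 7
        assert min(trace.sse) >= 0.0
        assert trace.final_rmse == pytest.approx(np.sqrt(trace.sse[-1] / 30))

    def test_bit_reproducible(self, rng):
        X = rng.random((30, 10))
        Y = rng.random((30, 9))
        cfg = NetworkConfig(epochs=10, train_sample_size=15, seed=5)
        a_state, a_trace = nd.train(nd.init_network(cfg), X, Y, cfg)
        b_state, b_trace = nd.train(nd.init_network(cfg), X, Y, cfg)
        assert np.array_equal(a_state.w_hidden, b_state.w_hidden)
        assert a_trace.sse == b_trace.sse

    def test_unscaled_targets_rejected(self, rng):
        X = rng.random((30, 10))
        Y = rng.standard_normal((30, 9)) * 3
        cfg = NetworkConfig(epochs=2)
        with pytest.raises(ScalingError):
            nd.train(nd.init_network(cfg), X, Y, cfg)

    def test_gradient_matches_finite_differences_small_net(self, rng):
        cfg = NetworkConfig(n_inputs=3, n_hidden=4, n_outputs=2, seed=9)
        state = nd.init_network(cfg)
        X = rng.random((4, 3))
        Y = rng.random((4, 2))
        loss, g_hid, g_out = loss_and_gradients(state, X, Y)
        eps = 1e-6
        for W, G in ((state.w_hidden, g_hid), (state.w_output, g_out)):
            it = np.nditer(W, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = W[idx]
                W[idx] = orig + eps
                lp, *_ = loss_and_gradients(state, X, Y)
                W[idx] = orig - eps
                lm, *_ = loss_and_gradients(state, X, Y)
                W[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert G[idx] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_xor_is_learnable(self):
        X, Y = xor_data()
        cfg = NetworkConfig(
            n_inputs=2, n_hidden=10, n_outputs=1, learning_rate=0.5,
            epochs=2000, train_sample_size=40, seed=2,
        )
        _, trace = nd.train(nd.init_network(cfg), X, Y, cfg)
        assert trace.sse[-1] < 0.1 * trace.sse[0]

    def test_fixed_multiset_mode_reproducible_and_distinct(self, rng):
        X = rng.random((50, 10))
        Y = rng.random((50, 9))
        base = NetworkConfig(epochs=10, train_sample_size=25, seed=4)
        fixed = NetworkConfig(
            epochs=10, train_sample_size=25, seed=4, resample_each_epoch=False
        )
        _, tr_a = nd.train(nd.init_network(base), X, Y, base)
        _, tr_b = nd.train(nd.init_network(fixed), X, Y, fixed)
        _, tr_b2 = nd.train(nd.init_network(fixed), X, Y, fixed)
        assert tr_b.sse == tr_b2.sse
        assert tr_a.sse != tr_b.sse


class TestEvaluate:
    def test_perfect_predictions(self):
        state = NetworkState(np.full((2, 1), 50.0), np.full((2, 1), 50.0))
        X = np.ones((5, 1))
        Y = np.ones((5, 1))  # saturated output ~ 1
        result = nd.evaluate(state, X, Y)
        assert result.sse == pytest.approx(0.0, abs=1e-10)
        assert result.rmse == pytest.approx(0.0, abs=1e-5)

    @pytest.mark.parametrize("sse,n,expected", [(34.76, 400, 0.29), (14.02, 400, 0.19)])
    def test_rmse_convention(self, sse, n, expected):
        assert nd.rmse_from_sse(sse, n) == pytest.approx(expected, abs=0.005)

    def test_scaling_round_trip_identity(self, rng):
        table = rng.standard_normal((50, 4)) * np.array([1, 5, 0.1, 100])
        spec = nd.ScalingSpec.fit(table)
        scaled = spec.transform(table)
        assert scaled.min() >= 0 and scaled.max() <= 1
        assert np.abs(spec.inverse(scaled) - table).max() < 1e-12

    def test_constant_column_rejected(self, rng):
        table = rng.standard_normal((20, 3))
        table[:, 1] = 2.0
        with pytest.raises(ScalingError):
            nd.ScalingSpec.fit(table)

    def test_correlation_invariant_to_inverse_transform(self, rng):
        cfg = NetworkConfig(epochs=5, train_sample_size=20, seed=8)
        X = rng.random((40, 10))
        targets_raw = rng.standard_normal((40, 9)) * 4 + 2
        spec = nd.ScalingSpec.fit(targets_raw)
        Y = spec.transform(targets_raw)
        state, _ = nd.train(nd.init_network(cfg), X, Y, cfg)
        result = nd.evaluate(state, X, Y, spec)
        for j in range(9):
            r_scaled = np.corrcoef(result.predictions_scaled[:, j], Y[:, j])[0, 1]
            r_raw = np.corrcoef(result.predictions[:, j], targets_raw[:, j])[0, 1]
            assert r_scaled == pytest.approx(r_raw, abs=1e-12)


@pytest.fixture(scope="module")
def sweep_data():
    cohort = nd.generate_cohort(
        nd.CohortConfig(
            n_cases=200, seed=55, effect_mode="interactive",
            effect_size=1.0, noise_sd=0.5,
        )
    )
    X = cohort.predictors()
    Xz = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
    Y = nd.ScalingSpec.fit(cohort.domains()).transform(cohort.domains())
    return Xz, Y


class TestSweep:
    def test_degenerate_grid_equals_single_run(self, sweep_data):
        Xz, Y = sweep_data
        cfg = NetworkConfig(epochs=20, train_sample_size=50, seed=3)
        grid = nd.sensitivity_sweep(Xz, Y, [0.03], [10], cfg)
        _, direct = nd.train(nd.init_network(cfg), Xz, Y, cfg)
        assert grid[(0.03, 10)].trace.sse == direct.sse

    def test_grid_shape(self, sweep_data):
        Xz, Y = sweep_data
        cfg = NetworkConfig(epochs=5, train_sample_size=50, seed=3)
        grid = nd.sensitivity_sweep(Xz, Y, [0.01, 0.5], [5, 20], cfg)
        assert len(grid) == 4
        assert all(
            isinstance(c, SweepCell) and len(c.trace.sse) == 5 for c in grid.values()
        )
        tidy = sweep_table(grid)
        assert len(tidy) == 20
        assert set(tidy.columns) == {"learning_rate", "n_hidden", "epoch", "sse"}

    def test_capacity_ordering_on_interactive_data(self, sweep_data):
        # more hidden units should not end with clearly larger error
        Xz, Y = sweep_data
        finals = {5: [], 20: []}
        for seed in range(5):
            cfg = NetworkConfig(epochs=300, train_sample_size=100, seed=seed)
            grid = nd.sensitivity_sweep(Xz, Y, [0.03], [5, 20], cfg)
            for h in (5, 20):
                finals[h].append(grid[(0.03, h)].trace.sse[-1])
        assert np.mean(finals[20]) <= np.mean(finals[5]) + 2.0

    def test_empty_grid_rejected(self, sweep_data):
        Xz, Y = sweep_data
        with pytest.raises(ConfigError):
            nd.sensitivity_sweep(Xz, Y, [], [10], NetworkConfig())


@given(
    n_in=st.integers(1, 4),
    n_hid=st.integers(1, 4),
    n_out=st.integers(1, 3),
    seed=st.integers(0, 1000),
)
def test_forward_batch_agrees_with_row_forward(n_in, n_hid, n_out, seed):
    cfg = NetworkConfig(n_inputs=n_in, n_hidden=n_hid, n_outputs=n_out, seed=seed)
    state = nd.init_network(cfg)
    X = np.random.default_rng(seed).random((6, n_in))
    batch = forward_batch(state, X)
    for i in range(6):
        _, row = nd.forward(state, X[i])
        assert np.allclose(batch[i], row, atol=1e-12)


def test_plot_trace_writes_figure(tmp_path):
    from neurodim.network import TrainingTrace, plot_trace

    trace = TrainingTrace(sse=[50.0, 30.0, 20.0, 15.0], final_rmse=0.19, n_eval_cases=400)
    out = tmp_path / "trace.png"
    plot_trace(trace, out)
    assert out.stat().st_size > 0
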