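"""Controller layers: sigmoid units, CTRNN integration, parameter container."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from minibrains.neural_controller import (NeuralParams, NeuralState,
                                          actuator_transform, ctrnn_step,
                                          initial_state, sensor_transform,
                                          sigmoid)

SIG1 = 0.7310585786  # 1 / (1 + e^-1)


def make_params(n=1, w_rec=None, w_sens=None, w_act=None, tau=1.0, theta=0.0,
                gain=1.0, sensor_gain=1.0, sensor_bias=0.0, actuator_bias=0.0):
    return NeuralParams(
        n_neurons=n,
        w_rec=np.zeros((n, n)) if w_rec is None else np.asarray(w_rec, float),
        w_sens=np.zeros((2, n)) if w_sens is None else np.asarray(w_sens, float),
        w_act=np.zeros((n, 3)) if w_act is None else np.asarray(w_act, float),
        tau=np.full(n, tau), theta=np.full(n, theta), gain=np.full(n, gain),
        sensor_gain=sensor_gain, sensor_bias=sensor_bias,
        actuator_bias=actuator_bias)


class TestSigmoid:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.5),
        (1.0, SIG1),
        (-1.0, 1.0 - SIG1),
    ])
    def test_values(self, x, expected):
        assert sigmoid(x) == pytest.approx(expected, abs=1e-9)

    def test_saturation(self):
        assert sigmoid(1000.0) == 1.0
        assert sigmoid(-1000.0) == 0.0

    @given(st.floats(-20, 20), st.floats(0.01, 5))
    def test_strictly_increasing(self, x, dx):
        # restricted to the range where the slope exceeds float64 spacing
        assert sigmoid(x + dx) > sigmoid(x)


class TestSensorTransform:
    def test_zero_intensity_zero_bias(self):
        p = make_params(sensor_gain=3.0, sensor_bias=0.0)
        assert sensor_transform([0.0, 0.0], p) == pytest.approx([0.5, 0.5])

    def test_zero_intensity_is_sigmoid_of_bias(self):
        p = make_params(sensor_bias=-2.0)
        expected = sigmoid(-2.0)
        assert sensor_transform([0.0, 0.0], p) == pytest.approx(
            [expected, expected])

    def test_gain_and_bias(self):
        p = make_params(sensor_gain=2.0, sensor_bias=-1.0)
        out = sensor_transform([1.0, 0.0], p)
        assert out[0] == pytest.approx(SIG1, abs=1e-9)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            sensor_transform([-0.1, 0.0], make_params())


class TestCtrnnStep:
    def test_euler_decay(self):
        p = make_params(tau=1.0)
        state = NeuralState(y=np.array([1.0]), sensor_out=np.zeros(2),
                            neuron_out=np.array([sigmoid(1.0)]))
        new = ctrnn_step(state, np.zeros(2), p, dt=0.1)
        assert new.y[0] == pytest.approx(0.9)

    def test_origin_fixed_point(self):
        p = make_params(gain=4.0)
        state = initial_state(p)
        for _ in range(10):
            state = ctrnn_step(state, np.zeros(2), p, dt=0.1)
        assert state.y[0] == 0.0
        assert state.neuron_out[0] == 0.5

    def test_zero_weights_state_constant(self):
        """With zero weights everywhere and y0 = 0 the state never moves."""
        p = make_params(n=2, theta=1.5, gain=2.0, sensor_bias=0.3)
        s0 = initial_state(p)
        s1 = ctrnn_step(s0, s0.sensor_out, p, dt=0.1)
        s2 = ctrnn_step(s1, s1.sensor_out, p, dt=0.1)
        np.testing.assert_array_equal(s1.y, s0.y)
        np.testing.assert_array_equal(s2.neuron_out, s1.neuron_out)

    @pytest.mark.parametrize("w,theta,g,I", [
        (2.0, 0.0, 1.0, 0.3),
        (-3.0, 1.0, 2.0, 0.0),
        (1.5, -0.5, 3.0, -0.2),
    ])
    def test_fixed_point_matches_root_finding(self, w, theta, g, I):
        """Iterated updates converge to the root of y = w*sigma(g(y+theta)) + I."""
        # constant external drive I delivered through sensor channel 1
        p = make_params(w_rec=[[w]], w_sens=[[I], [0.0]], gain=g, theta=theta)
        sensor = np.array([1.0, 0.0])
        state = initial_state(p)
        for _ in range(20000):
            state = ctrnn_step(state, sensor, p, dt=0.05)
        y_star = brentq(lambda y: -y + w * sigmoid(g * (y + theta)) + I,
                        -50, 50, xtol=1e-13)
        assert abs(-state.y[0] + w * sigmoid(g * (state.y[0] + theta)) + I) < 1e-9
        assert state.y[0] == pytest.approx(y_star, abs=1e-8)

    def test_linear_closed_form_convergence(self):
        """With frozen constant input I the potential follows
        y(t) = y0 exp(-t/tau) + (1 - exp(-t/tau)) I, and the Euler error
        shrinks roughly linearly with dt."""
        tau, I, y0, T = 1.5, 0.8, 2.0, 3.0
        errors = []
        for dt in (0.1, 0.05, 0.025):
            p = make_params(tau=tau, w_sens=[[I], [0.0]])
            state = NeuralState(y=np.array([y0]), sensor_out=np.zeros(2),
                                neuron_out=np.array([0.5]))
            steps = int(round(T / dt))
            for _ in range(steps):
                state = ctrnn_step(state, np.array([1.0, 0.0]), p, dt=dt)
            exact = y0 * np.exp(-T / tau) + (1 - np.exp(-T / tau)) * I
            errors.append(abs(state.y[0] - exact))
        assert errors[0] > errors[1] > errors[2]
        assert errors[1] / errors[0] == pytest.approx(0.5, abs=0.15)

    def test_nonfinite_potential_rejected(self):
        p = make_params()
        state = NeuralState(y=np.array([np.inf]), sensor_out=np.zeros(2),
                            neuron_out=np.array([1.0]))
        with pytest.raises(FloatingPointError):
            ctrnn_step(state, np.zeros(2), p)


class TestActuatorTransform:
    def test_zero_weights(self):
        out = actuator_transform(np.array([0.3, 0.8]), make_params(n=2))
        assert out == pytest.approx([0.5, 0.5, 0.5])

    def test_bias_only(self):
        p = make_params(n=2, actuator_bias=-1.0)
        out = actuator_transform(np.array([0.0, 0.0]), p)
        assert out == pytest.approx(3 * [1.0 - SIG1], abs=1e-9)

    def test_weighted_example(self):
        w_act = np.zeros((2, 3))
        w_act[:, 0] = (2.0, -2.0)
        p = make_params(n=2, w_act=w_act)
        out = actuator_transform(np.array([1.0, 0.0]), p)
        assert out[0] == pytest.approx(0.8807970780, abs=1e-9)


class TestInvariants:
    @given(st.integers(0, 1000))
    def test_outputs_stay_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 4))
        p = make_params(
            n=n, w_rec=rng.uniform(-8, 8, (n, n)),
            w_sens=rng.uniform(-8, 8, (2, n)), w_act=rng.uniform(-8, 8, (n, 3)),
            tau=float(rng.uniform(1, 2)), theta=float(rng.uniform(-8, 8)),
            gain=float(rng.uniform(1, 5)), sensor_gain=float(rng.uniform(1, 5)),
            sensor_bias=float(rng.uniform(-8, 8)))
        state = initial_state(p)
        for _ in range(50):
            state = ctrnn_step(state, rng.uniform(0, 1, 2), p, dt=0.1)
            out = actuator_transform(state.neuron_out, p)
            assert np.all(state.neuron_out >= 0) and np.all(state.neuron_out <= 1)
            assert np.all(out >= 0) and np.all(out <= 1)
            assert np.all(np.isfinite(state.y))


class TestNeuralParams:
    @pytest.mark.parametrize("n,expected", [(2, 20), (3, 30)])
    def test_parameter_count(self, n, expected):
        assert make_params(n=n).n_parameters == expected

    def test_tau_must_be_positive(self):
        with pytest.raises(ValueError):
            make_params(tau=0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            NeuralParams(n_neurons=2, w_rec=np.zeros((3, 3)),
                         w_sens=np.zeros((2, 2)), w_act=np.zeros((2, 3)),
                         tau=np.ones(2), theta=np.zeros(2), gain=np.ones(2),
                         sensor_gain=1.0, sensor_bias=0.0, actuator_bias=0.0)

    def test_json_round_trip(self, rng):
        n = 3
        p = make_params(n=n, w_rec=rng.uniform(-8, 8, (n, n)),
                        w_sens=rng.uniform(-8, 8, (2, n)),
                        w_act=rng.uniform(-8, 8, (n, 3)),
                        tau=1.37, theta=-2.2, gain=4.1,
                        sensor_gain=2.5, sensor_bias=0.7, actuator_bias=-3.3)
        q = NeuralParams.from_json(p.to_json())
        for name in ("w_rec", "w_sens", "w_act", "tau", "theta", "gain"):
            np.testing.assert_array_equal(getattr(p, name), getattr(q, name))
        assert float(q.sensor_gain) == 2.5
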