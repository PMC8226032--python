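"""Trial setup, the batched engine vs. the step-by-step layer operations,
and the coupled / decoupled testing modes."""

import numpy as np
import pytest

from minibrains import embodiment as emb
from minibrains import neural_controller as nc
from minibrains.evolution import decode_genotype
from minibrains.experiments import (DT, SE_PARTNER_DISTANCE, make_trials,
                                    run_trial, simulate_batch, stack_params)
from minibrains.experiments import test_mode as run_test_mode


def random_params(rng, n=2):
    return decode_genotype(rng.uniform(-1, 1, 20 if n == 2 else 30),
                           n_neurons=n)


def reference_trial(params_list, init_poses, n_steps, dt=DT, sense=True):
    """Trial integration composed from the public per-layer operations;
    independent of the compiled engine."""
    body = emb.BodyConfig()
    acoustics = emb.AcousticsConfig()
    A = len(params_list)
    states = [nc.initial_state(p) for p in params_list]
    world = emb.WorldState(
        poses=np.array(init_poses, float),
        emitters=np.array([s.actuator_out[2] for s in states]))
    out_hist, y_hist, pose_hist, int_hist = [], [], [], []
    for _ in range(n_steps):
        intensities = [emb.sensor_intensities(world, a, body, acoustics)
                       if sense else np.zeros(2) for a in range(A)]
        acts = []
        for a in range(A):
            sens = nc.sensor_transform(intensities[a], params_list[a])
            states[a] = nc.ctrnn_step(states[a], sens, params_list[a], dt)
            acts.append(nc.actuator_transform(states[a].neuron_out,
                                              params_list[a]))
        world = emb.world_step(world, np.array(acts), dt, body)
        out_hist.append([s.neuron_out for s in states])
        y_hist.append([s.y for s in states])
        pose_hist.append(world.poses.copy())
        int_hist.append(intensities)
    return (np.array(y_hist), np.array(out_hist), np.array(pose_hist),
            np.array(int_hist))


class TestMakeTrials:
    def test_se_partner_placement(self):
        trials = make_trials("SE")
        assert trials[0].init_poses[1][:2] == pytest.approx([20.0, 0.0])
        assert trials[1].init_poses[1][:2] == pytest.approx([0.0, 20.0])
        assert trials[2].init_poses[1][:2] == pytest.approx([-20.0, 0.0])
        assert trials[3].init_poses[1][:2] == pytest.approx([0.0, -20.0])
        for t in trials:
            assert np.all(t.init_poses[:, 2] == 0.0)  # heading right
            assert np.hypot(*t.init_poses[1][:2]) == pytest.approx(
                SE_PARTNER_DISTANCE)

    def test_ie_trials_identical(self):
        trials = make_trials("IE")
        assert len(trials) == 4
        for t in trials:
            np.testing.assert_array_equal(t.init_poses, np.zeros((1, 3)))

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            make_trials("XX")


class TestRunTrial:
    def test_trace_length_is_2000_steps(self, rng):
        trace = run_trial(make_trials("IE")[0], [random_params(rng)])
        assert trace.time.size == 2000
        assert trace.time[0] == pytest.approx(0.1)
        assert trace.time[-1] == pytest.approx(200.0)

    def test_solitary_trace_has_zero_input(self, rng):
        trace = run_trial(make_trials("IE")[0], [random_params(rng)])
        np.testing.assert_array_equal(trace.intensity, 0.0)

    def test_bit_reproducible(self, rng):
        params = [random_params(rng, 3), random_params(rng, 3)]
        a = run_trial(make_trials("SE")[1], params)
        b = run_trial(make_trials("SE")[1], params)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.pose, b.pose)

    def test_dataframe_schema(self, rng):
        trace = run_trial(make_trials("SE")[0],
                          [random_params(rng), random_params(rng)])
        df = trace.to_dataframe()
        assert list(df.columns) == ["time", "agent_id", "x", "y", "phi",
                                    "sensor1", "sensor2", "emitter",
                                    "y1", "y2", "out1", "out2"]
        assert set(df["agent_id"]) == {1, 2}
        assert len(df) == 2 * 2000


class TestEngineAgainstLayerOps:
    """The compiled batch engine must reproduce the trajectory obtained by
    composing the public sensor/CTRNN/actuator/kinematics operations."""

    @pytest.mark.parametrize("condition,n,steps", [
        ("IE", 2, 500),
        ("SE", 2, 300),
        ("SE", 3, 300),
    ])
    def test_trajectories_agree(self, condition, n, steps):
        rng = np.random.default_rng(42)
        A = 1 if condition == "IE" else 2
        params_list = [random_params(rng, n) for _ in range(A)]
        spec = make_trials(condition)[0]
        res = simulate_batch(stack_params(params_list), spec.init_poses[None],
                             steps, sense=(condition == "SE"),
                             record=("y", "neuron_out", "pose", "intensity"))
        y_ref, out_ref, pose_ref, int_ref = reference_trial(
            params_list, spec.init_poses, steps, sense=(condition == "SE"))
        np.testing.assert_allclose(res["y"][:, 0, 0], y_ref, atol=1e-9)
        np.testing.assert_allclose(res["neuron_out"][:, 0, 0], out_ref,
                                   atol=1e-9)
        np.testing.assert_allclose(res["pose"][:, 0, 0], pose_ref, atol=1e-9)
        np.testing.assert_allclose(res["intensity"][:, 0, 0], int_ref,
                                   atol=1e-9)


class TestMirrorSymmetry:
    def test_reflection_equivariance(self):
        """Reflecting the initial configuration about the x-axis while
        swapping the two sensor channels and the two motor channels yields
        the mirrored trajectory."""
        rng = np.random.default_rng(3)
        params = [random_params(rng), random_params(rng)]
        mirrored = [
            nc.NeuralParams(
                n_neurons=p.n_neurons, w_rec=p.w_rec,
                w_sens=p.w_sens[::-1].copy(),
                w_act=p.w_act[:, [1, 0, 2]].copy(), tau=p.tau,
                theta=p.theta, gain=p.gain, sensor_gain=p.sensor_gain,
                sensor_bias=p.sensor_bias, actuator_bias=p.actuator_bias)
            for p in params
        ]
        spec = make_trials("SE")[1]  # partner at (0, 20)
        reflected = spec.init_poses * np.array([1.0, -1.0, -1.0])
        a = simulate_batch(stack_params(params), spec.init_poses[None], 400,
                           record=("pose", "neuron_out"))
        b = simulate_batch(stack_params(mirrored), reflected[None], 400,
                           record=("pose", "neuron_out"))
        np.testing.assert_allclose(
            b["pose"][:, 0, 0] * np.array([1.0, -1.0, -1.0]),
            a["pose"][:, 0, 0], atol=1e-9)
        np.testing.assert_allclose(b["neuron_out"][:, 0, 0],
                                   a["neuron_out"][:, 0, 0], atol=1e-9)


class TestTestMode:
    def test_decoupled_has_zero_input(self, rng):
        trace = run_test_mode([random_params(rng), random_params(rng)],
                          "decoupled", "SE")
        np.testing.assert_array_equal(trace.intensity, 0.0)
        assert trace.n_agents == 1

    def test_decoupled_independent_of_partner(self, rng):
        agent = random_params(rng)
        t1 = run_test_mode([agent, random_params(rng)], "decoupled", "SE")
        t2 = run_test_mode([agent, random_params(rng)], "decoupled", "SE")
        np.testing.assert_array_equal(t1.y, t2.y)

    def test_coupled_se_matches_evaluation_trial(self, rng):
        pair = [random_params(rng), random_params(rng)]
        via_mode = run_test_mode(pair, "coupled", "SE", trial_index=1)
        direct = run_trial(make_trials("SE")[0], pair)
        np.testing.assert_array_equal(via_mode.y, direct.y)
        np.testing.assert_array_equal(via_mode.pose, direct.pose)

    def test_coupled_ie_uses_self_clone(self, rng):
        agent = random_params(rng)
        trace = run_test_mode(agent, "coupled", "IE")
        assert trace.n_agents == 2
        assert np.any(trace.intensity > 0)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            run_test_mode(random_params(rng), "open-loop", "IE")
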