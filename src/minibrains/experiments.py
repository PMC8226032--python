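"""Experimental setup: trial definitions for the Individual-Evolution (IE,
solitary agent) and Social-Evolution (SE, interacting pair) conditions, the
simulation engine that integrates controllers and bodies together, and the
post-evolution coupled / decoupled testing modes.

Trial geometry
--------------
Every trial lasts 200 simulation seconds at step 0.1 (2000 steps).  The
(first) agent starts at the origin heading right (+x).  In SE, trial k in
{1..4} places the partner 20 units away at relative angle {0, pi/2, pi,
3*pi/2}, also heading right.  IE trials are all identical (a solitary agent
receives no input), and are still enumerated four times for structural
parity with SE.

Update order per step (synchronous for both agents): (1) sensor intensities
from the previous step's world state, (2) sensor nodes, (3) CTRNN Euler
step, (4) actuator nodes, (5) move bodies and set emitter strengths.
Neuron potentials start at y = 0.

The engine (`simulate_batch`) integrates an arbitrary population batch at
once: parameter arrays carry leading (population, agent) axes and the state
carries (trial, population, agent) axes.  Simulation is fully deterministic,
so traces are bit-reproducible given the genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from ._engine import step_loop
from .embodiment import AcousticsConfig, BodyConfig, wrap_angle
from .neural_controller import N_ACTUATORS, N_SENSORS, NeuralParams

__all__ = [
    "IE",
    "SE",
    "TrialSpec",
    "SimulationTrace",
    "make_trials",
    "simulate_batch",
    "stack_params",
    "run_trial",
    "test_mode",
]

IE = "IE"
SE = "SE"

TRIAL_DURATION = 200.0
DT = 0.1
SE_PARTNER_DISTANCE = 20.0
SE_PARTNER_ANGLES = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)

_RECORD_KEYS = ("y", "neuron_out", "sensor_out", "actuator_out", "intensity", "pose")


@dataclass(frozen=True)
class TrialSpec:
    """One evaluation trial: condition, index (1..4), and initial poses."""

    condition: str
    trial_index: int
    init_poses: np.ndarray          # (A, 3)
    duration: float = TRIAL_DURATION
    dt: float = DT

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_agents(self) -> int:
        return np.asarray(self.init_poses).shape[0]


def make_trials(condition: str, n_trials: int = 4) -> list[TrialSpec]:
    """The trial set of one evaluation.

    IE: one agent at (0, 0) heading right, identical across trials.
    SE: partner placed 20 units away at angle {0, pi/2, pi, 3*pi/2} for
    trials 1..4, both agents heading right.
    """
    if condition not in (IE, SE):
        raise ValueError(f"condition must be {IE!r} or {SE!r}")
    trials = []
    for k in range(n_trials):
        if condition == IE:
            poses = np.zeros((1, 3))
        else:
            theta = SE_PARTNER_ANGLES[k % len(SE_PARTNER_ANGLES)]
            poses = np.array([
                [0.0, 0.0, 0.0],
                [SE_PARTNER_DISTANCE * np.cos(theta),
                 SE_PARTNER_DISTANCE * np.sin(theta), 0.0],
            ])
        trials.append(TrialSpec(condition=condition, trial_index=k + 1,
                                init_poses=poses))
    return trials


def stack_params(params_list: Sequence[NeuralParams]) -> NeuralParams:
    """Stack per-agent parameters into a single batched (1, A, ...) object."""
    n = params_list[0].n_neurons
    if any(p.n_neurons != n for p in params_list):
        raise ValueError("all agents must share the same model size")
    fields = {}
    for name in ("w_rec", "w_sens", "w_act", "tau", "theta", "gain",
                 "sensor_gain", "sensor_bias", "actuator_bias"):
        fields[name] = np.stack([getattr(p, name) for p in params_list])[None]
    return NeuralParams(n_neurons=n, **fields)


def simulate_batch(params: NeuralParams, init_poses, n_steps: int,
                   dt: float = DT, body: BodyConfig = BodyConfig(),
                   acoustics: AcousticsConfig = AcousticsConfig(),
                   sense: bool = True,
                   record: Sequence[str] = ("neuron_out",)) -> dict:
    """Integrate a population batch of embodied controllers.

    Parameters
    ----------
    params : NeuralParams with field shapes (P, A, ...) — population of P
        independent (sets of) agents, A agents each (1 or 2).
    init_poses : (K, A, 3) initial poses for K trials.  Every population
        member runs every trial.
    sense : if False, sensor intensities are forced to zero throughout
        (solitary agents and the "decoupled" testing mode).
    record : subset of {"y", "neuron_out", "sensor_out", "actuator_out",
        "intensity", "pose"}; each recorded array has shape
        (n_steps, K, P, A, ...), sampled *after* each step.

    Returns a dict of the recorded arrays.
    """
    for key in record:
        if key not in _RECORD_KEYS:
            raise ValueError(f"unknown record key {key!r}")
    w_rec = params.w_rec
    P, A, n = w_rec.shape[0], w_rec.shape[1], params.n_neurons

    init_poses = np.asarray(init_poses, dtype=float)
    if init_poses.ndim != 3 or init_poses.shape[1] != A or init_poses.shape[2] != 3:
        raise ValueError("init_poses must have shape (K, A, 3)")
    K = init_poses.shape[0]
    F = K * P
    coupled = sense and A == 2

    # tile parameters across trials and flatten (K, P) -> F for the kernel
    def tile(x):
        out = np.empty((K,) + x.shape)
        out[:] = x[None]
        return out.reshape((F,) + x.shape[1:])

    poses = np.empty((K, P, A, 3))
    poses[:] = init_poses[:, None]
    poses = poses.reshape(F, A, 3)

    full = any(k in record for k in
               ("sensor_out", "actuator_out", "intensity", "pose"))
    rec_y = np.empty((n_steps, F, A, n))
    rec_out = np.empty((n_steps, F, A, n))
    if full:
        rec_sens = np.empty((n_steps, F, A, N_SENSORS))
        rec_act = np.empty((n_steps, F, A, N_ACTUATORS))
        rec_int = np.empty((n_steps, F, A, N_SENSORS))
        rec_pose = np.empty((n_steps, F, A, 3))
    else:
        rec_sens = np.empty((0, F, A, N_SENSORS))
        rec_act = np.empty((0, F, A, N_ACTUATORS))
        rec_int = np.empty((0, F, A, N_SENSORS))
        rec_pose = np.empty((0, F, A, 3))

    off = body.sensor_angles
    step_loop(n_steps, float(dt), coupled,
              tile(w_rec), tile(params.w_sens), tile(params.w_act),
              tile(dt / params.tau), tile(params.theta), tile(params.gain),
              tile(params.sensor_gain), tile(params.sensor_bias),
              tile(params.actuator_bias),
              poses, float(body.radius), float(off[0]), float(off[1]),
              float(acoustics.occlusion_factor),
              float(acoustics.min_distance),
              acoustics.attenuation == "inverse_square",
              acoustics.shadow == "hard",
              rec_y, rec_out, rec_sens, rec_act, rec_int, rec_pose, full)

    if not np.all(np.isfinite(rec_y[-1])):
        raise FloatingPointError("simulation produced non-finite neural state")

    arrays = {"y": rec_y, "neuron_out": rec_out, "sensor_out": rec_sens,
              "actuator_out": rec_act, "intensity": rec_int, "pose": rec_pose}
    return {key: arrays[key].reshape(arrays[key].shape[0], K, P, A, -1)
            for key in record}


@dataclass
class SimulationTrace:
    """Full per-step record of one trial (all agents).

    Arrays are indexed (step, agent, ...); ``time`` holds the simulation time
    at which each row was sampled (after the step).
    """

    time: np.ndarray
    pose: np.ndarray           # (T, A, 3)
    intensity: np.ndarray      # (T, A, 2)
    sensor_out: np.ndarray     # (T, A, 2)
    y: np.ndarray              # (T, A, n)
    neuron_out: np.ndarray     # (T, A, n)
    actuator_out: np.ndarray   # (T, A, 3)
    spec: Optional[TrialSpec] = None

    @property
    def n_agents(self) -> int:
        return self.pose.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.y.shape[2]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per (step, agent).

        Columns: time, agent_id, x, y, phi, sensor1, sensor2, emitter,
        y1..yn (neuron potentials), out1..outn (neuron outputs).
        """
        frames = []
        for a in range(self.n_agents):
            cols = {
                "time": self.time,
                "agent_id": np.full(self.time.shape, a + 1, dtype=int),
                "x": self.pose[:, a, 0],
                "y": self.pose[:, a, 1],
                "phi": wrap_angle(self.pose[:, a, 2]),
                "sensor1": self.sensor_out[:, a, 0],
                "sensor2": self.sensor_out[:, a, 1],
                "emitter": self.actuator_out[:, a, 2],
            }
            for i in range(self.n_neurons):
                cols[f"y{i + 1}"] = self.y[:, a, i]
            for i in range(self.n_neurons):
                cols[f"out{i + 1}"] = self.neuron_out[:, a, i]
            frames.append(pd.DataFrame(cols))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def run_trial(spec: TrialSpec, params_list: Sequence[NeuralParams],
              body: BodyConfig = BodyConfig(),
              acoustics: AcousticsConfig = AcousticsConfig(),
              sense: Optional[bool] = None) -> SimulationTrace:
    """Simulate one trial with full state recording.

    ``params_list`` holds one NeuralParams per agent (1 for IE, 2 for SE).
    ``sense=False`` forces zero sensor intensity (decoupled testing); by
    default solitary agents sense nothing and pairs are coupled.
    """
    spec_agents = spec.n_agents
    if len(params_list) != spec_agents:
        raise ValueError(f"trial expects {spec_agents} agents, "
                         f"got {len(params_list)} parameter sets")
    if sense is None:
        sense = spec_agents == 2
    params = stack_params(params_list)
    res = simulate_batch(params, spec.init_poses[None], spec.n_steps,
                         dt=spec.dt, body=body, acoustics=acoustics,
                         sense=sense, record=_RECORD_KEYS)
    time = spec.dt * np.arange(1, spec.n_steps + 1)
    return SimulationTrace(
        time=time,
        pose=res["pose"][:, 0, 0],
        intensity=res["intensity"][:, 0, 0],
        sensor_out=res["sensor_out"][:, 0, 0],
        y=res["y"][:, 0, 0],
        neuron_out=res["neuron_out"][:, 0, 0],
        actuator_out=res["actuator_out"][:, 0, 0],
        spec=spec,
    )


def test_mode(params, mode: str, condition: str, trial_index: int = 1,
              body: BodyConfig = BodyConfig(),
              acoustics: AcousticsConfig = AcousticsConfig()) -> SimulationTrace:
    """Post-evolution testing of an evolved solution.

    ``params`` is the decoded NeuralParams of an IE agent, or a pair
    (list/tuple of two NeuralParams) for an SE solution.

    decoupled: the (first) agent is simulated in isolation with sensor input
    forced to zero — the trace is independent of any partner.
    coupled: SE solutions run with their co-evolved partner in the SE trial
    geometry; IE agents are paired with a clone of themselves (non-canonical,
    provided for completeness).
    """
    if mode not in ("coupled", "decoupled"):
        raise ValueError("mode must be 'coupled' or 'decoupled'")
    if isinstance(params, NeuralParams):
        pair = [params]
    else:
        pair = list(params)
    if mode == "decoupled":
        spec = make_trials(IE)[trial_index - 1]
        return run_trial(spec, [pair[0]], body=body, acoustics=acoustics,
                         sense=False)
    if len(pair) == 1:
        pair = [pair[0], pair[0]]  # IE coupled: self-clone partner
    spec = make_trials(SE)[trial_index - 1]
    return run_trial(spec, pair, body=body, acoustics=acoustics, sense=True)
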