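"""Three-layer agent controller: sigmoidal sensors, a fully recurrent CTRNN
inner layer, and stateless sigmoidal actuators.

The inner layer follows the standard continuous-time recurrent neural network
(CTRNN) formulation: each neuron ``i`` has a membrane potential ``y_i`` with
leaky-integrator dynamics

    tau_i * dy_i/dt = -y_i + sum_j w_rec[j, i] * sigma(g_j * (y_j + theta_j))
                            + sum_k w_sens[k, i] * s_k

where ``sigma`` is the logistic function, ``g_j`` an output gain, ``theta_j``
a bias, and ``s_k`` the sensor-node outputs.  Neuron outputs are
``sigma(g_i * (y_i + theta_i))``, so every layer output lives in (0, 1).
Integration is explicit Euler with a fixed step (default 0.1 s).

Gains are applied inside the output nonlinearity (Beer-style convention);
sensor and actuator sigmoid parameters are shared across units in the default
genotype layout so that the evolvable-parameter count is exactly
``n^2 + 5n + 6`` (20 for n=2, 30 for n=3).

All operations broadcast over arbitrary leading batch dimensions, which the
simulation engine uses to integrate whole populations at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "sigmoid",
    "NeuralParams",
    "NeuralState",
    "sensor_transform",
    "ctrnn_step",
    "actuator_transform",
    "initial_state",
]

N_SENSORS = 2
N_ACTUATORS = 3  # (left motor, right motor, emitter)


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x)); saturates gracefully for large |x|."""
    return expit(x)


@dataclass
class NeuralParams:
    """Decoded controller parameters.

    Array fields may carry leading batch dimensions; the trailing axes must be
    consistent with ``n_neurons``:

    - ``w_rec``: (..., n, n), ``w_rec[j, i]`` is the weight from neuron j to i
    - ``w_sens``: (..., 2, n) sensor-to-neuron weights
    - ``w_act``: (..., n, 3) neuron-to-actuator weights, actuator order fixed
      as (left motor, right motor, emitter)
    - ``tau``, ``theta``, ``gain``: (..., n) per-neuron time constants
      (seconds, > 0), biases, and output gains (> 0)
    - ``sensor_gain``, ``sensor_bias``, ``actuator_bias``: (...,) sigmoid
      parameters shared across the units of the respective layer
    """

    n_neurons: int
    w_rec: np.ndarray
    w_sens: np.ndarray
    w_act: np.ndarray
    tau: np.ndarray
    theta: np.ndarray
    gain: np.ndarray
    sensor_gain: np.ndarray
    sensor_bias: np.ndarray
    actuator_bias: np.ndarray

    def __post_init__(self):
        n = int(self.n_neurons)
        if n < 1:
            raise ValueError("n_neurons must be >= 1")
        for name in ("w_rec", "w_sens", "w_act", "tau", "theta", "gain",
                     "sensor_gain", "sensor_bias", "actuator_bias"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.w_rec.shape[-2:] != (n, n):
            raise ValueError(f"w_rec must end in shape ({n}, {n})")
        if self.w_sens.shape[-2:] != (N_SENSORS, n):
            raise ValueError(f"w_sens must end in shape ({N_SENSORS}, {n})")
        if self.w_act.shape[-2:] != (n, N_ACTUATORS):
            raise ValueError(f"w_act must end in shape ({n}, {N_ACTUATORS})")
        for name in ("tau", "theta", "gain"):
            if getattr(self, name).shape[-1:] != (n,):
                raise ValueError(f"{name} must end in shape ({n},)")
        if not np.all(self.tau > 0):
            raise ValueError("all time constants must be strictly positive")
        if not np.all(self.gain > 0):
            raise ValueError("all gains must be strictly positive")

    @property
    def n_parameters(self) -> int:
        """Number of evolvable scalars in the default shared-parameter layout."""
        n = self.n_neurons
        return n * n + N_SENSORS * n + N_ACTUATORS * n + 6

    # -- serialization (unbatched parameters only) ---------------------------

    def to_dict(self) -> dict:
        return {
            "n_neurons": self.n_neurons,
            "w_rec": self.w_rec.tolist(),
            "w_sens": self.w_sens.tolist(),
            "w_act": self.w_act.tolist(),
            "tau": self.tau.tolist(),
            "theta": self.theta.tolist(),
            "gain": self.gain.tolist(),
            "sensor_gain": float(self.sensor_gain),
            "sensor_bias": float(self.sensor_bias),
            "actuator_bias": float(self.actuator_bias),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuralParams":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "NeuralParams":
        return cls.from_dict(json.loads(s))


@dataclass
class NeuralState:
    """Controller state at one time step.

    ``y`` are the neuron potentials; the ``*_out`` fields are the most recent
    layer outputs, each in [0, 1].  ``actuator_out`` is ``None`` until
    :func:`actuator_transform` has been applied for the step.
    """

    y: np.ndarray
    sensor_out: np.ndarray
    neuron_out: np.ndarray
    actuator_out: Optional[np.ndarray] = None


def sensor_transform(intensity, params: NeuralParams) -> np.ndarray:
    """Map non-negative acoustic intensities to sensor-node outputs.

    Each sensor node applies ``sigmoid(sensor_gain * intensity + sensor_bias)``.
    Acoustics can never produce a negative intensity, so one is rejected.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("sensor intensity must be non-negative")
    sg = np.asarray(params.sensor_gain)[..., None]
    sb = np.asarray(params.sensor_bias)[..., None]
    return sigmoid(sg * intensity + sb)


def ctrnn_step(state: NeuralState, sensor_out, params: NeuralParams,
               dt: float = 0.1) -> NeuralState:
    """One explicit-Euler step of the CTRNN layer.

    The recurrent drive uses the neuron outputs of the *previous* step, so the
    update is synchronous across neurons.  Raises if the update produces a
    non-finite potential (a sign of mis-scaled parameters, since outputs are
    bounded).
    """
    sensor_out = np.asarray(sensor_out, dtype=float)
    y = np.asarray(state.y, dtype=float)
    out_prev = sigmoid(params.gain * (y + params.theta))
    rec = np.einsum("...ji,...j->...i", params.w_rec, out_prev)
    ext = np.einsum("...ki,...k->...i", params.w_sens, sensor_out)
    with np.errstate(invalid="ignore", over="ignore"):
        y_new = y + (dt / params.tau) * (-y + rec + ext)
    if not np.all(np.isfinite(y_new)):
        raise FloatingPointError("CTRNN update produced non-finite potentials")
    neuron_out = sigmoid(params.gain * (y_new + params.theta))
    return NeuralState(y=y_new, sensor_out=sensor_out, neuron_out=neuron_out)


def actuator_transform(neuron_out, params: NeuralParams) -> np.ndarray:
    """Stateless sigmoidal actuator layer.

    Output order is fixed as (left motor, right motor, emitter).
    """
    neuron_out = np.asarray(neuron_out, dtype=float)
    drive = np.einsum("...io,...i->...o", params.w_act, neuron_out)
    return sigmoid(drive + np.asarray(params.actuator_bias)[..., None])


def initial_state(params: NeuralParams, y0: Optional[np.ndarray] = None) -> NeuralState:
    """State at trial start: potentials at ``y0`` (default 0), zero intensity.

    With zero intensity the sensor nodes output ``sigmoid(sensor_bias)``.
    """
    if y0 is None:
        y = np.zeros_like(params.theta)
    else:
        y = np.broadcast_to(np.asarray(y0, dtype=float), params.theta.shape).copy()
    zero_intensity = np.zeros(params.theta.shape[:-1] + (N_SENSORS,))
    sensor_out = sensor_transform(zero_intensity, params)
    neuron_out = sigmoid(params.gain * (y + params.theta))
    actuator_out = actuator_transform(neuron_out, params)
    return NeuralState(y=y, sensor_out=sensor_out, neuron_out=neuron_out,
                       actuator_out=actuator_out)
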