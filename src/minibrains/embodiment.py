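"""Embodiment: circular two-wheeled agents in an open 2-D arena.

Covers differential-drive kinematics, the geometry of the two frontal
acoustic sensors (at +-45 degrees on the body perimeter) and the central
emitter, and the acoustic channel between agents: an attenuation law in
distance plus a "self-shadowing" factor by which the receiving agent's own
body occludes sound arriving from behind a sensor.

Units: one world length unit, one simulation second.  Motor outputs are used
unscaled, so the maximum linear speed is 1 unit/s.  With body radius 4 the
angular velocity is (right - left) / radius, i.e. at most 0.25 rad/s.

The attenuation and shadowing laws are configurable (`AcousticsConfig`);
the defaults are an inverse-square law with the distance clamped at 1 (to
avoid a singularity when bodies overlap — there is no collision handling in
an empty open-ended arena) and a hard shadow: full transmission when the
source is in the sensor's outward half-plane, a 0.1 multiplier otherwise.

All geometry functions broadcast over leading batch dimensions; poses are
(..., 3) arrays of (x, y, phi) with phi = 0 pointing along +x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BodyConfig",
    "AcousticsConfig",
    "Pose",
    "WorldState",
    "wrap_angle",
    "motor_to_velocity",
    "update_pose",
    "sensor_positions",
    "sensor_outward_directions",
    "attenuation",
    "shadow_factor",
    "signal_intensity",
    "sensor_intensities",
    "world_step",
]


def wrap_angle(phi):
    """Wrap angles to (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    return -((-phi + np.pi) % (2.0 * np.pi) - np.pi)


@dataclass(frozen=True)
class BodyConfig:
    """Circular body: radius 4 units, sensors at +-45 deg, emitter at center."""

    radius: float = 4.0
    sensor_half_angle: float = np.pi / 4

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("body radius must be positive")

    @property
    def sensor_angles(self) -> np.ndarray:
        """Sensor bearings relative to heading: (+45 deg, -45 deg)."""
        return np.array([self.sensor_half_angle, -self.sensor_half_angle])


@dataclass(frozen=True)
class AcousticsConfig:
    """Signal attenuation model.

    attenuation: "inverse_square" (1/d^2) or "inverse" (1/d), with the
        distance clamped below at ``min_distance``.
    shadow: "hard" (1 in the sensor's outward half-plane, ``occlusion_factor``
        behind it) or "cosine" (smooth (1 + cos psi) / 2).
    """

    attenuation: str = "inverse_square"
    min_distance: float = 1.0
    shadow: str = "hard"
    occlusion_factor: float = 0.1

    def __post_init__(self):
        if self.attenuation not in ("inverse_square", "inverse"):
            raise ValueError(f"unknown attenuation law {self.attenuation!r}")
        if self.shadow not in ("hard", "cosine"):
            raise ValueError(f"unknown shadow model {self.shadow!r}")
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")


@dataclass
class Pose:
    """Agent pose: position (length units) and heading (radians, 0 = +x)."""

    x: float = 0.0
    y: float = 0.0
    phi: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.phi], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Pose":
        a = np.asarray(a, dtype=float)
        return cls(x=float(a[0]), y=float(a[1]), phi=float(a[2]))

    @property
    def wrapped(self) -> "Pose":
        return Pose(self.x, self.y, float(wrap_angle(self.phi)))


@dataclass
class WorldState:
    """Poses and current emitter strengths of the 1 (solitary) or 2 agents."""

    poses: np.ndarray          # (A, 3)
    emitters: np.ndarray       # (A,), each in [0, 1]

    def __post_init__(self):
        self.poses = np.atleast_2d(np.asarray(self.poses, dtype=float))
        self.emitters = np.atleast_1d(np.asarray(self.emitters, dtype=float))
        if self.poses.shape[0] not in (1, 2) or self.poses.shape[1] != 3:
            raise ValueError("poses must be (A, 3) with A in {1, 2}")
        if self.emitters.shape != (self.poses.shape[0],):
            raise ValueError("one emitter strength per agent required")

    @property
    def n_agents(self) -> int:
        return self.poses.shape[0]


def motor_to_velocity(left_out, right_out, radius: float = 4.0):
    """Differential-drive map: v = (l + r) / 2, omega = (r - l) / radius."""
    left_out = np.asarray(left_out, dtype=float)
    right_out = np.asarray(right_out, dtype=float)
    v = 0.5 * (left_out + right_out)
    omega = (right_out - left_out) / radius
    return v, omega


def update_pose(pose, v, omega, dt: float = 0.1):
    """Euler unicycle step: translate along the current heading, then rotate."""
    pose = np.asarray(pose, dtype=float)
    v = np.asarray(v, dtype=float)
    omega = np.asarray(omega, dtype=float)
    phi = pose[..., 2]
    out = np.empty(np.broadcast_shapes(pose.shape, v.shape + (3,)))
    out[..., 0] = pose[..., 0] + v * np.cos(phi) * dt
    out[..., 1] = pose[..., 1] + v * np.sin(phi) * dt
    out[..., 2] = phi + omega * dt
    return out


def sensor_positions(pose, body: BodyConfig = BodyConfig()) -> np.ndarray:
    """World coordinates of the two sensors, shape (..., 2, 2).

    Sensor k sits on the body perimeter at bearing phi + (+-45 deg); index 0
    is the left (counter-clockwise, +45 deg) sensor.
    """
    pose = np.asarray(pose, dtype=float)
    ang = pose[..., 2, None] + body.sensor_angles
    offs = body.radius * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    return pose[..., None, :2] + offs


def sensor_outward_directions(pose, body: BodyConfig = BodyConfig()) -> np.ndarray:
    """Unit radial (outward) directions of the two sensors, shape (..., 2, 2)."""
    pose = np.asarray(pose, dtype=float)
    ang = pose[..., 2, None] + body.sensor_angles
    return np.stack([np.cos(ang), np.sin(ang)], axis=-1)


def attenuation(d, cfg: AcousticsConfig = AcousticsConfig()):
    """Distance attenuation D(d) with the distance clamped at cfg.min_distance."""
    d_eff = np.maximum(np.asarray(d, dtype=float), cfg.min_distance)
    if cfg.attenuation == "inverse_square":
        return 1.0 / (d_eff * d_eff)
    return 1.0 / d_eff


def shadow_factor(cos_psi, cfg: AcousticsConfig = AcousticsConfig()):
    """Self-shadowing S(psi) from the cosine of the sensor/source angle."""
    cos_psi = np.asarray(cos_psi, dtype=float)
    if cfg.shadow == "hard":
        return np.where(cos_psi >= 0.0, 1.0, cfg.occlusion_factor)
    return 0.5 * (1.0 + cos_psi)


def signal_intensity(emitter_strength, source, sensor, receiver_pose,
                     body: BodyConfig = BodyConfig(),
                     cfg: AcousticsConfig = AcousticsConfig()):
    """Received intensity at one sensor point from one emitting source.

    intensity = emitter * D(d) * S(psi), with d the source-to-sensor distance
    and psi the angle between the sensor's outward radial direction and the
    direction from sensor to source.
    """
    emitter_strength = np.asarray(emitter_strength, dtype=float)
    if np.any(emitter_strength < 0):
        raise ValueError("emitter strength must be non-negative")
    source = np.asarray(source, dtype=float)
    sensor = np.asarray(sensor, dtype=float)
    receiver_pose = np.asarray(receiver_pose, dtype=float)
    delta = source - sensor
    d = np.sqrt(np.sum(delta * delta, axis=-1))
    outward = (sensor - receiver_pose[..., :2]) / body.radius
    cos_psi = np.sum(delta * outward, axis=-1) / np.maximum(d, 1e-300)
    return emitter_strength * attenuation(d, cfg) * shadow_factor(cos_psi, cfg)


def sensor_intensities(world: WorldState, agent_index: int,
                       body: BodyConfig = BodyConfig(),
                       cfg: AcousticsConfig = AcousticsConfig()) -> np.ndarray:
    """Intensities at the two sensors of one agent.

    Agents never sense their own signal; a solitary agent therefore receives
    identically zero input.
    """
    pose = world.poses[agent_index]
    sensors = sensor_positions(pose, body)
    total = np.zeros(2)
    for j in range(world.n_agents):
        if j == agent_index:
            continue
        total += signal_intensity(world.emitters[j], world.poses[j, :2],
                                  sensors, pose, body, cfg)
    return total


def world_step(world: WorldState, actuator_outs, dt: float = 0.1,
               body: BodyConfig = BodyConfig()) -> WorldState:
    """Advance all agents synchronously by one step.

    ``actuator_outs`` is (A, 3): (left motor, right motor, emitter) per agent.
    Emitter strengths are replaced by the new emitter outputs; bodies may
    overlap (no collisions in the open arena).
    """
    actuator_outs = np.atleast_2d(np.asarray(actuator_outs, dtype=float))
    if actuator_outs.shape != (world.n_agents, 3):
        raise ValueError("need one (left, right, emitter) triple per agent")
    v, omega = motor_to_velocity(actuator_outs[:, 0], actuator_outs[:, 1],
                                 body.radius)
    poses = update_pose(world.poses, v, omega, dt)
    return WorldState(poses=poses, emitters=actuator_outs[:, 2].copy())
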