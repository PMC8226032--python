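"""Configuration presets, run-directory serialization, and generators of
canonical dynamical-system time series.

The fixture generators (sine, Henon map, Lorenz system, white noise) provide
series with known attractor structure that serve as oracles for the entropy
and embedding estimators: a sine embeds in the plane with an MI minimum near
a quarter period, the Henon attractor needs dimension 2, the Lorenz
attractor dimension 3, and white noise never embeds.

Run directories are plain text: ``config.json`` (with a schema version),
``fitness.csv`` (generation, best, mean), ``best_genotype.json``.  Floats
are written at full precision so a round-trip is bit-exact, and every
stochastic entry point takes an explicit seed so a run is reproducible from
its config alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .entropy_fitness import EntropyConfig
from .evolution import EvolutionRecord, GAConfig, ScalingRanges

__all__ = [
    "SCHEMA_VERSION",
    "FULL_SCALE",
    "DESK_SCALE",
    "RunConfig",
    "generate_fixture",
    "save_run",
    "load_run",
]

SCHEMA_VERSION = 1

# Scale presets: "full" is the published study's scale; "desk" is a reduced
# configuration sized for a single-CPU workstation session.
FULL_SCALE = {"population_size": 96, "generations": 2000, "n_runs": 10}
DESK_SCALE = {"population_size": 24, "generations": 200, "n_runs": 5}
_PRESETS = {"full": FULL_SCALE, "desk": DESK_SCALE}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one evolutionary run."""

    condition: str = "IE"
    n_neurons: int = 2
    seed: int = 0
    scale: str = "full"
    ga: GAConfig = field(default_factory=GAConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    ranges: ScalingRanges = field(default_factory=ScalingRanges)

    @classmethod
    def from_preset(cls, condition: str, n_neurons: int, seed: int,
                    scale: str = "full", **overrides) -> "RunConfig":
        if scale not in _PRESETS:
            raise ValueError(f"unknown scale preset {scale!r}")
        preset = _PRESETS[scale]
        ga = GAConfig(population_size=preset["population_size"],
                      generations=preset["generations"])
        return cls(condition=condition, n_neurons=n_neurons, seed=seed,
                   scale=scale, ga=ga, **overrides)

    @property
    def n_runs(self) -> int:
        return _PRESETS[self.scale]["n_runs"]

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "condition": self.condition,
            "n_neurons": self.n_neurons,
            "seed": self.seed,
            "scale": self.scale,
            "ga": dataclasses.asdict(self.ga),
            "entropy": dataclasses.asdict(self.entropy),
            "ranges": {k: list(v) for k, v in
                       dataclasses.asdict(self.ranges).items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(f"config schema version {version!r} is not "
                             f"supported (expected {SCHEMA_VERSION})")
        return cls(condition=d["condition"], n_neurons=d["n_neurons"],
                   seed=d["seed"], scale=d["scale"],
                   ga=GAConfig(**d["ga"]),
                   entropy=EntropyConfig(**d["entropy"]),
                   ranges=ScalingRanges(**{k: tuple(v) for k, v in
                                           d["ranges"].items()}))


def generate_fixture(system: str, length: int, params: dict | None = None,
                     seed: int | None = None) -> np.ndarray:
    """Deterministic reference time series from a canonical system.

    sine: ``sin(2*pi*t/period + phase)`` sampled at integer t
        (params: period=40.0, phase=0.0, amplitude=1.0).
    henon: x-coordinate of the Henon map, a=1.4, b=0.3, 100-step transient.
    lorenz: x-coordinate of the Lorenz system (sigma=10, rho=28, beta=8/3)
        sampled at dt=0.01 after a 5-time-unit transient.
    white_noise: i.i.d. standard normal samples (requires a seed).
    """
    if length < 100:
        raise ValueError("length must be >= 100")
    params = dict(params or {})
    if system == "sine":
        period = params.pop("period", 40.0)
        phase = params.pop("phase", 0.0)
        amplitude = params.pop("amplitude", 1.0)
        t = np.arange(length)
        # reduce mod period before evaluating so an integer period yields
        # bit-exact periodic samples
        return amplitude * np.sin(2 * np.pi * (t % period) / period + phase)
    if system == "henon":
        a = params.pop("a", 1.4)
        b = params.pop("b", 0.3)
        transient = params.pop("transient", 100)
        x, y = params.pop("x0", 0.0), params.pop("y0", 0.0)
        out = np.empty(length)
        for i in range(-transient, length):
            x, y = 1.0 - a * x * x + y, b * x
            if i >= 0:
                out[i] = x
        return out
    if system == "lorenz":
        sigma = params.pop("sigma", 10.0)
        rho = params.pop("rho", 28.0)
        beta = params.pop("beta", 8.0 / 3.0)
        dt = params.pop("dt", 0.01)
        transient = params.pop("transient", 5.0)

        def rhs(_t, s):
            x, y, z = s
            return [sigma * (y - x), x * (rho - z) - y, x * y - beta * z]

        t_eval = transient + dt * np.arange(length)
        sol = solve_ivp(rhs, (0.0, t_eval[-1]), [1.0, 1.0, 1.0],
                        t_eval=t_eval, rtol=1e-10, atol=1e-12,
                        method="RK45", max_step=0.05)
        return sol.y[0]
    if system == "white_noise":
        if seed is None:
            raise ValueError("white_noise requires a seed")
        return np.random.default_rng(seed).standard_normal(length)
    raise ValueError(f"unknown fixture system {system!r}")


def save_run(run_dir, config: RunConfig, record: EvolutionRecord) -> None:
    """Write one run to disk: config.json, fitness.csv, best_genotype.json."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2))
    curve = pd.DataFrame({
        "generation": np.arange(record.best_fitness.size),
        "best": record.best_fitness,
        "mean": record.mean_fitness,
    })
    curve.to_csv(run_dir / "fitness.csv", index=False)  # shortest repr round-trips
    (run_dir / "best_genotype.json").write_text(json.dumps({
        "seed": record.seed,
        "condition": record.condition,
        "n_neurons": record.n_neurons,
        "values": record.best_genotype.tolist(),
    }))


def load_run(run_dir) -> tuple[RunConfig, EvolutionRecord]:
    """Read a run directory back; exact inverse of `save_run`."""
    run_dir = Path(run_dir)
    cfg_path = run_dir / "config.json"
    if not cfg_path.exists():
        raise FileNotFoundError(f"missing config.json in {run_dir}")
    config = RunConfig.from_dict(json.loads(cfg_path.read_text()))
    fit_path = run_dir / "fitness.csv"
    if not fit_path.exists():
        raise FileNotFoundError(f"missing fitness.csv in {run_dir}")
    curve = pd.read_csv(fit_path, float_precision="round_trip")
    geno_path = run_dir / "best_genotype.json"
    if not geno_path.exists():
        raise FileNotFoundError(f"missing best_genotype.json in {run_dir}")
    geno = json.loads(geno_path.read_text())
    record = EvolutionRecord(
        seed=geno["seed"], condition=geno["condition"],
        n_neurons=geno["n_neurons"],
        best_fitness=curve["best"].to_numpy(),
        mean_fitness=curve["mean"].to_numpy(),
        best_genotype=np.array(geno["values"], dtype=float))
    return config, record
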