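"""Real-valued genetic algorithm maximizing neural entropy.

Genotypes are vectors in [-1, 1]^L.  One solution encodes one agent in the
solitary condition (L = 20 for the 2-neuron model, 30 for the 3-neuron
model) or a concatenated pair (2L) in the social condition.  Each gene is
linearly rescaled to its parameter class's range at decode time.

Default genotype layout per agent (fixed order):

    w_rec (n^2) | w_sens (2n) | w_act (3n) | tau | theta | gain
    | sensor_gain | sensor_bias | actuator_bias

with the six trailing scalars shared across the units of their layer, giving
exactly n^2 + 5n + 6 genes (20 / 30).  Default ranges (configurable):
weights and biases [-8, 8], time constants [1, 2] s, gains [1, 5].

Selection is elitist: the top 4% (ceiling, so 4 of 96) pass unchanged; the
rest are children of two elite parents (uniform with replacement, distinct
when possible) produced by per-gene swap crossover (p = 0.1), zero-mean
Gaussian mutation (variance 0.1) on every gene, and clipping to [-1, 1].

Evaluation is deterministic (simulation has no noise), so the best fitness
per generation is non-decreasing and runs are bit-reproducible from their
seed.  `evolve_runs` evolves several independently seeded runs at once,
stacking their populations so the simulation engine integrates them in a
single batch.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import experiments
from .embodiment import AcousticsConfig, BodyConfig
from .entropy_fitness import EntropyConfig, batch_entropy
from .experiments import IE, SE, make_trials, simulate_batch
from .neural_controller import N_ACTUATORS, N_SENSORS, NeuralParams

__all__ = [
    "ScalingRanges",
    "GAConfig",
    "EvolutionRecord",
    "model_genotype_length",
    "genotype_length",
    "decode_genotype",
    "random_genotype",
    "evaluate",
    "evaluate_population",
    "next_generation",
    "evolve_run",
    "evolve_runs",
]


@dataclass(frozen=True)
class ScalingRanges:
    """(min, max) per parameter class used when decoding genotypes."""

    weights: tuple = (-8.0, 8.0)
    biases: tuple = (-8.0, 8.0)
    taus: tuple = (1.0, 2.0)
    gains: tuple = (1.0, 5.0)

    def __post_init__(self):
        for name in ("weights", "biases", "taus", "gains"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"range {name} must have min < max")
        if self.taus[0] <= 0:
            raise ValueError("time-constant range must be strictly positive")
        if self.gains[0] <= 0:
            raise ValueError("gain range must be strictly positive")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (defaults are the full-scale study)."""

    population_size: int = 96
    generations: int = 2000
    elite_fraction: float = 0.04
    mutation_variance: float = 0.1
    crossover_prob: float = 0.1
    trials: int = 4
    trial_duration: float = 200.0
    dt: float = 0.1

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("elite_fraction", "crossover_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_variance < 0:
            raise ValueError("mutation_variance must be >= 0")

    @property
    def elite_count(self) -> int:
        """Ceiling of elite_fraction * population (at least the stated
        fraction survives; 4% of 96 -> 4)."""
        return max(1, math.ceil(self.elite_fraction * self.population_size))

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_duration / self.dt))


def model_genotype_length(n_neurons: int) -> int:
    """Evolvable scalars per agent: n^2 + 5n + 6 (20 for n=2, 30 for n=3)."""
    n = int(n_neurons)
    return n * n + N_SENSORS * n + N_ACTUATORS * n + 6


def genotype_length(n_neurons: int, condition: str) -> int:
    """Length of one GA solution: one agent (IE) or a concatenated pair (SE)."""
    L = model_genotype_length(n_neurons)
    return L if condition == IE else 2 * L


def _scale(v, lo_hi):
    lo, hi = lo_hi
    return lo + (v + 1.0) * 0.5 * (hi - lo)


def decode_genotype(values, ranges: ScalingRanges = ScalingRanges(),
                    n_neurons: int = 2) -> NeuralParams:
    """Decode genotype(s) in [-1, 1]^L into controller parameters.

    ``values`` may carry leading batch dimensions; the last axis must have
    length ``model_genotype_length(n_neurons)``.
    """
    values = np.asarray(values, dtype=float)
    n = int(n_neurons)
    L = model_genotype_length(n)
    if values.shape[-1] != L:
        raise ValueError(f"genotype length {values.shape[-1]} != {L} "
                         f"for the {n}-neuron model")
    lead = values.shape[:-1]
    i = 0

    def take(count):
        nonlocal i
        chunk = values[..., i:i + count]
        i += count
        return chunk

    w_rec = _scale(take(n * n), ranges.weights).reshape(lead + (n, n))
    w_sens = _scale(take(N_SENSORS * n), ranges.weights).reshape(lead + (N_SENSORS, n))
    w_act = _scale(take(n * N_ACTUATORS), ranges.weights).reshape(lead + (n, N_ACTUATORS))
    tau = np.repeat(_scale(take(1), ranges.taus), n, axis=-1)
    theta = np.repeat(_scale(take(1), ranges.biases), n, axis=-1)
    gain = np.repeat(_scale(take(1), ranges.gains), n, axis=-1)
    sensor_gain = _scale(take(1), ranges.gains)[..., 0]
    sensor_bias = _scale(take(1), ranges.biases)[..., 0]
    actuator_bias = _scale(take(1), ranges.biases)[..., 0]
    return NeuralParams(n_neurons=n, w_rec=w_rec, w_sens=w_sens, w_act=w_act,
                        tau=tau, theta=theta, gain=gain,
                        sensor_gain=sensor_gain, sensor_bias=sensor_bias,
                        actuator_bias=actuator_bias)


def random_genotype(rng: np.random.Generator, n_neurons: int,
                    condition: str = IE) -> np.ndarray:
    return rng.uniform(-1.0, 1.0, genotype_length(n_neurons, condition))


def evaluate_population(genotypes, condition: str, n_neurons: int,
                        cfg: GAConfig = GAConfig(),
                        entropy_cfg: EntropyConfig = EntropyConfig(),
                        ranges: ScalingRanges = ScalingRanges(),
                        body: BodyConfig = BodyConfig(),
                        acoustics: AcousticsConfig = AcousticsConfig(),
                        return_details: bool = False):
    """Fitness of a population batch; deterministic given the genotypes.

    ``genotypes``: (P, L_solution).  Returns (P,) fitnesses, or with
    ``return_details`` a tuple (fitness (P,), per_agent (P, A),
    per_trial (K, P, A)).
    """
    genotypes = np.atleast_2d(np.asarray(genotypes, dtype=float))
    P = genotypes.shape[0]
    L = model_genotype_length(n_neurons)
    A = 1 if condition == IE else 2
    if genotypes.shape[1] != A * L:
        raise ValueError(f"solution length {genotypes.shape[1]} != {A * L}")
    params = decode_genotype(genotypes.reshape(P, A, L), ranges, n_neurons)
    specs = make_trials(condition, cfg.trials)
    init_poses = np.stack([s.init_poses for s in specs])
    res = simulate_batch(params, init_poses, cfg.n_steps, dt=cfg.dt,
                         body=body, acoustics=acoustics,
                         sense=(condition == SE), record=("neuron_out",))
    out = res["neuron_out"]                                    # (T, K, P, A, n)
    per_trial = batch_entropy(out, entropy_cfg)                # (K, P, A)
    if entropy_cfg.pool_trials:
        # one histogram per agent over the outputs of all trials
        # (burn-in is discarded per trial, before pooling)
        trimmed = out[entropy_cfg.burn_in:]
        pooled = np.moveaxis(trimmed, 1, 0).reshape((-1,) + out.shape[2:])
        per_agent = batch_entropy(
            pooled, dataclasses.replace(entropy_cfg, burn_in=0))  # (P, A)
    else:
        per_agent = per_trial.mean(axis=0)                     # (P, A)
    fitness = per_agent.mean(axis=1)                           # (P,)
    if return_details:
        return fitness, per_agent, per_trial
    return fitness


def evaluate(genotype, condition: str, n_neurons: int, **kwargs) -> float:
    """Fitness of a single solution (agent fitness in IE, pair mean in SE)."""
    return float(evaluate_population(np.asarray(genotype)[None],
                                     condition, n_neurons, **kwargs)[0])


def next_generation(population, fitnesses, cfg: GAConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Produce the next population: elites verbatim, the rest bred from them.

    Children are generated in pairs: two elite parents (distinct when at
    least two elites exist), per-gene swap with ``crossover_prob``, then
    Gaussian mutation on every gene, then clipping to [-1, 1].
    """
    population = np.asarray(population, dtype=float)
    fitnesses = np.asarray(fitnesses, dtype=float)
    N, L = population.shape
    if fitnesses.shape != (N,):
        raise ValueError("one fitness per solution required")
    order = np.argsort(-fitnesses, kind="stable")
    E = max(1, math.ceil(cfg.elite_fraction * N))
    elites = population[order[:E]]
    sd = math.sqrt(cfg.mutation_variance)
    children = []
    while len(children) < N - E:
        if E >= 2:
            i = rng.integers(E)
            j = rng.integers(E - 1)
            if j >= i:
                j += 1
        else:
            i = j = 0
        pa, pb = elites[i], elites[j]
        swap = rng.random(L) < cfg.crossover_prob
        child_a = np.where(swap, pb, pa)
        child_b = np.where(swap, pa, pb)
        noise = rng.normal(0.0, sd, (2, L)) if sd > 0 else np.zeros((2, L))
        children.append(np.clip(child_a + noise[0], -1.0, 1.0))
        children.append(np.clip(child_b + noise[1], -1.0, 1.0))
    return np.vstack([elites, np.array(children[:N - E])])


@dataclass
class EvolutionRecord:
    """Outcome of one evolutionary run.

    ``best_fitness[g]`` / ``mean_fitness[g]`` are population statistics of
    generation g (generation 0 is the initial random population), so the
    arrays have ``generations + 1`` entries.  ``best_genotype`` is the
    highest-fitness solution of the final generation.
    """

    seed: int
    condition: str
    n_neurons: int
    best_fitness: np.ndarray
    mean_fitness: np.ndarray
    best_genotype: np.ndarray

    @property
    def final_best_fitness(self) -> float:
        return float(self.best_fitness[-1])

    def best_params(self, ranges: ScalingRanges = ScalingRanges()):
        """Decoded parameters of the best solution: a NeuralParams for IE,
        a list of two for SE."""
        L = model_genotype_length(self.n_neurons)
        if self.condition == IE:
            return decode_genotype(self.best_genotype, ranges, self.n_neurons)
        return [decode_genotype(self.best_genotype[:L], ranges, self.n_neurons),
                decode_genotype(self.best_genotype[L:], ranges, self.n_neurons)]


def evolve_runs(condition: str, n_neurons: int, cfg: GAConfig,
                seeds: Sequence[int],
                entropy_cfg: EntropyConfig = EntropyConfig(),
                ranges: ScalingRanges = ScalingRanges(),
                body: BodyConfig = BodyConfig(),
                acoustics: AcousticsConfig = AcousticsConfig(),
                progress: bool = False) -> list[EvolutionRecord]:
    """Evolve one independent run per seed (batched simulation).

    Each run draws all randomness from its own seeded generator, so results
    are identical to running the seeds one at a time.
    """
    if condition not in (IE, SE):
        raise ValueError(f"condition must be {IE!r} or {SE!r}")
    seeds = list(seeds)
    S = len(seeds)
    N = cfg.population_size
    L = genotype_length(n_neurons, condition)
    rngs = [np.random.default_rng(s) for s in seeds]
    pops = np.stack([rng.uniform(-1.0, 1.0, (N, L)) for rng in rngs])

    best = np.empty((S, cfg.generations + 1))
    mean = np.empty((S, cfg.generations + 1))
    final_best_geno = [None] * S
    for g in range(cfg.generations + 1):
        fits = evaluate_population(
            pops.reshape(S * N, L), condition, n_neurons, cfg=cfg,
            entropy_cfg=entropy_cfg, ranges=ranges, body=body,
            acoustics=acoustics).reshape(S, N)
        best[:, g] = fits.max(axis=1)
        mean[:, g] = fits.mean(axis=1)
        if g == cfg.generations:
            for s in range(S):
                final_best_geno[s] = pops[s, np.argmax(fits[s])].copy()
        else:
            pops = np.stack([next_generation(pops[s], fits[s], cfg, rngs[s])
                             for s in range(S)])
        if progress and g % 20 == 0:
            print(f"  gen {g:5d}  best {best[:, g].max():.4f}", flush=True)
    return [EvolutionRecord(seed=seeds[s], condition=condition,
                            n_neurons=n_neurons, best_fitness=best[s],
                            mean_fitness=mean[s],
                            best_genotype=final_best_geno[s])
            for s in range(S)]


def evolve_run(condition: str, n_neurons: int, cfg: GAConfig, seed: int,
               **kwargs) -> EvolutionRecord:
    """Single evolutionary run (see `evolve_runs`)."""
    return evolve_runs(condition, n_neurons, cfg, [seed], **kwargs)[0]
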