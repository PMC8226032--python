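"""Performance measure: normalized multi-dimensional Shannon entropy of the
neuron-layer output time series.

A trial's neuron outputs form a T x n matrix with every value in [0, 1].
The unit hypercube is partitioned into B equal-width bins per dimension
(B^n cells); with occupancy probabilities p_c the raw entropy is
H = -sum_c p_c ln p_c, normalized by its maximum ln(B^n) so the fitness is
in [0, 1].  Values exactly on the upper edge fall into the last bin.

An agent's fitness pools the outputs recorded over its evaluation trials
into one histogram by default (a per-trial histogram with trial averaging
is available via config); a pair's fitness is the mean of the two agents'
fitnesses, keeping the measure comparable between solitary and social
conditions.

`multidim_entropy` is the reference implementation (numpy.histogramdd);
`batch_entropy` computes the same quantity for many series at once via a
sort/run-length scheme and is what the genetic algorithm's inner loop uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EntropyConfig",
    "EntropyResult",
    "multidim_entropy",
    "batch_entropy",
    "agent_fitness",
    "pair_fitness",
]


@dataclass(frozen=True)
class EntropyConfig:
    """Histogram settings.

    ``bins_per_dim``: equal-width bins per dimension (>= 2).
    ``burn_in``: initial samples discarded per trial (default 0).
    ``pool_trials``: if True (default), an agent's outputs from all trials
    are pooled into one histogram and scored once — the outputs are
    "recorded in order to calculate their normalized neural entropy".  If
    False, each trial is scored separately and the trial entropies averaged.
    """

    bins_per_dim: int = 50
    burn_in: int = 0
    pool_trials: bool = True

    def __post_init__(self):
        if self.bins_per_dim < 2:
            raise ValueError("bins_per_dim must be >= 2")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass
class EntropyResult:
    """Per-trial normalized entropies and the aggregated fitness of one
    evaluation (for a pair, ``per_agent`` holds each agent's own fitness)."""

    per_trial: np.ndarray      # (n_trials,) or (n_trials, n_agents)
    fitness: float
    per_agent: np.ndarray | None = None


def _bin_indices(series: np.ndarray, bins: int) -> np.ndarray:
    idx = (series * bins).astype(np.int64)
    return np.minimum(idx, bins - 1)  # upper edge -> last bin


def multidim_entropy(series, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Normalized joint Shannon entropy of a T x n series in [0, 1]^n."""
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if series.ndim != 2:
        raise ValueError("series must be a T x n matrix")
    series = series[cfg.burn_in:]
    if series.shape[0] < 1:
        raise ValueError("series is empty (after burn-in)")
    if np.any(series < 0) or np.any(series > 1):
        raise ValueError("all values must lie in [0, 1]")
    n = series.shape[1]
    B = cfg.bins_per_dim
    counts, _ = np.histogramdd(series, bins=n * [B], range=n * [(0.0, 1.0)])
    p = counts[counts > 0].ravel() / series.shape[0]
    raw = -np.sum(p * np.log(p))
    return float(raw / (n * np.log(B)) + 0.0)  # +0.0 avoids -0.0


def batch_entropy(series, cfg: EntropyConfig = EntropyConfig()) -> np.ndarray:
    """Normalized entropy of many series at once.

    ``series`` has shape (T, ..., n); the result has shape (...,).  Uses a
    single sort over flattened (series-id, cell-id) keys and run-length
    counting, avoiding one dense B^n histogram per series.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim < 2:
        raise ValueError("series must have shape (T, ..., n)")
    series = series[cfg.burn_in:]
    T = series.shape[0]
    if T < 1:
        raise ValueError("series is empty (after burn-in)")
    n = series.shape[-1]
    B = cfg.bins_per_dim
    batch_shape = series.shape[1:-1]
    M = int(np.prod(batch_shape)) if batch_shape else 1
    idx = _bin_indices(series.reshape(T, M, n), B)
    cell = idx[..., 0]
    for k in range(1, n):
        cell = cell * B + idx[..., k]
    # offset cells per series so runs never cross series boundaries
    key = cell + np.arange(M, dtype=np.int64) * (B ** n)
    key = np.sort(key, axis=0)
    flat = key.T.ravel()
    starts = np.flatnonzero(np.r_[True, flat[1:] != flat[:-1]])
    counts = np.diff(np.r_[starts, flat.size])
    p = counts / T
    term = -p * np.log(p)
    H = np.bincount(starts // T, weights=term, minlength=M)
    H = H / (n * np.log(B)) + 0.0
    return H.reshape(batch_shape) if batch_shape else float(H[0])


def agent_fitness(per_trial_entropies) -> float:
    """Mean normalized entropy across an agent's trials (4 by default)."""
    values = np.asarray(per_trial_entropies, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise ValueError("per-trial entropies must be a non-empty vector")
    return float(values.mean())


def pair_fitness(agent_a: float, agent_b: float) -> float:
    """Fitness of an interacting pair: mean of the two agents' fitnesses."""
    return 0.5 * (float(agent_a) + float(agent_b))
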