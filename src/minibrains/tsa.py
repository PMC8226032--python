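"""Nonlinear time-series analysis: delay-coordinate attractor reconstruction.

Two standard estimators, applied to the neuron-1 potential series of evolved
agents to quantify the effective degrees of freedom of neural activity:

1. Embedding delay tau: first local minimum of the time-lagged mutual
   information I(x_t; x_{t+tau}), estimated from an equal-width joint
   histogram (64 bins by default).  If the curve has no interior local
   minimum, the first lag at which MI drops below MI(0)/e is used, and
   failing that the largest lag examined (the fallback chain is logged).
2. Embedding dimension m: the false-nearest-neighbor (FNN) criterion.  For
   each candidate dimension the series is embedded as vectors
   (x_t, x_{t+tau}, ..., x_{t+(m-1)tau}); a point's nearest neighbor
   (excluding temporal neighbors within a Theiler window, default tau) is
   declared false if the extra (m+1)-th coordinate stretches the distance by
   more than Rtol = 10, or if the augmented distance exceeds Atol = 2 times
   the series' standard deviation.  m is the smallest dimension whose false
   fraction falls below 1%.

Nearest neighbors are found with a k-d tree; the test suite cross-checks
the FNN fractions against a brute-force O(T^2) search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingResult",
    "mutual_information_curve",
    "select_delay",
    "delay_embedding",
    "fnn_fractions",
    "embedding_dimension",
    "analyze_best_agents",
]


@dataclass
class EmbeddingResult:
    """Delay-embedding analysis of one series."""

    tau: int
    mi_curve: np.ndarray
    fnn: np.ndarray            # false fraction for m = 1..m_max
    m: int
    rtol: float = 10.0
    atol: float = 2.0
    threshold: float = 0.01
    delay_method: str = "local_minimum"   # or "mi_drop", "tau_max"
    saturated: bool = False    # FNN never fell below threshold
    degenerate: bool = False   # (near-)constant series; m = 1 by convention


def mutual_information_curve(series, tau_max: int, n_bins: int = 64) -> np.ndarray:
    """Histogram estimate of I(x_t; x_{t+tau}) in nats for tau = 0..tau_max.

    Marginals are taken from the same pair sample as the joint, so the
    estimate is exactly non-negative and MI(0) equals the marginal entropy
    of the binned series.  A constant series has no information at any lag;
    it yields an all-zero curve with a warning.
    """
    x = np.asarray(series, dtype=float).ravel()
    T = x.size
    if T <= tau_max + 1:
        raise ValueError("series must be longer than tau_max + 1")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant series: mutual information is identically 0")
        return np.zeros(tau_max + 1)
    idx = np.minimum(((x - lo) / (hi - lo) * n_bins).astype(np.int64), n_bins - 1)
    mi = np.empty(tau_max + 1)
    for tau in range(tau_max + 1):
        a = idx[:T - tau]
        b = idx[tau:]
        joint = np.bincount(a * n_bins + b, minlength=n_bins * n_bins).astype(float)
        joint /= a.size
        pj = joint.reshape(n_bins, n_bins)
        pa = pj.sum(axis=1)
        pb = pj.sum(axis=0)
        mask = pj > 0
        mi[tau] = np.sum(pj[mask] * np.log(pj[mask] /
                                           np.outer(pa, pb)[mask]))
    return mi


def select_delay(mi_curve) -> tuple[int, str]:
    """Embedding delay from an MI curve: first interior local minimum.

    Fallbacks (logged): first lag with MI < MI(0)/e, else the last lag.
    Returns (tau, method).
    """
    mi = np.asarray(mi_curve, dtype=float)
    if mi.size < 3:
        raise ValueError("MI curve must have at least 3 points")
    for tau in range(1, mi.size - 1):
        if mi[tau - 1] > mi[tau] < mi[tau + 1]:
            return tau, "local_minimum"
    drop = np.flatnonzero(mi[1:] < mi[0] / np.e)
    if drop.size:
        tau = int(drop[0]) + 1
        logger.info("MI has no local minimum; using 1/e drop at tau=%d", tau)
        return tau, "mi_drop"
    tau = mi.size - 1
    logger.warning("MI has no local minimum and never drops below MI(0)/e; "
                   "using tau_max=%d", tau)
    return tau, "tau_max"


def delay_embedding(series, tau: int, m: int) -> np.ndarray:
    """Delay vectors (x_t, x_{t+tau}, ..., x_{t+(m-1)tau}), shape (M, m)."""
    x = np.asarray(series, dtype=float).ravel()
    M = x.size - (m - 1) * tau
    if M < 2:
        raise ValueError("series too short for this embedding")
    return np.stack([x[k * tau: k * tau + M] for k in range(m)], axis=1)


def _nearest_excluding_window(emb: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest neighbor of each row excluding indices within the Theiler
    window; returns (neighbor index, distance)."""
    M = emb.shape[0]
    tree = cKDTree(emb)
    nn_idx = np.full(M, -1, dtype=np.int64)
    nn_dist = np.empty(M)
    pending = np.arange(M)
    k = min(M, 2 * window + 3)
    while pending.size:
        dists, idxs = tree.query(emb[pending], k=k)
        valid = np.abs(idxs - pending[:, None]) > window
        has = valid.any(axis=1)
        first = np.argmax(valid, axis=1)
        rows = pending[has]
        nn_idx[rows] = idxs[has, first[has]]
        nn_dist[rows] = dists[has, first[has]]
        pending = pending[~has]
        if k == M:
            break
        k = min(M, 2 * k)
    if pending.size:  # no admissible neighbor at all (pathological window)
        raise ValueError("Theiler window leaves some points without neighbors")
    return nn_idx, nn_dist


def fnn_fractions(series, tau: int, m_max: int = 6, rtol: float = 10.0,
                  atol: float = 2.0, theiler: Optional[int] = None) -> np.ndarray:
    """False-nearest-neighbor fraction for each dimension m = 1..m_max.

    Both standard criteria are applied: the ratio of the added-coordinate
    separation to the m-dimensional neighbor distance exceeding ``rtol``,
    and the augmented distance exceeding ``atol`` times the series' standard
    deviation.
    """
    x = np.asarray(series, dtype=float).ravel()
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if theiler is None:
        theiler = tau
    r_attractor = x.std()
    if r_attractor == 0:
        raise ValueError("constant series has no meaningful FNN statistics")
    fractions = np.empty(m_max)
    for m in range(1, m_max + 1):
        M = x.size - m * tau  # need the (m+1)-th coordinate as well
        if M < 10:
            raise ValueError(
                f"series too short for m={m} with tau={tau}: "
                f"need at least {m * tau + 10} points, have {x.size}")
        emb = delay_embedding(x[: x.size - tau], tau, m)[:M]
        nn_idx, nn_dist = _nearest_excluding_window(emb, theiler)
        extra = np.abs(x[np.arange(M) + m * tau] - x[nn_idx + m * tau])
        # floor the neighbor distance at rounding-noise scale so exactly
        # recurring points (e.g. a periodic orbit) are not flagged false by
        # a ratio of two numbers that are zero up to floating-point error
        denom = np.maximum(nn_dist, 1e-12 * r_attractor)
        false1 = extra / denom > rtol
        false2 = np.sqrt(nn_dist ** 2 + extra ** 2) / r_attractor > atol
        fractions[m - 1] = np.mean(false1 | false2)
    return fractions


def embedding_dimension(series, tau_max: int = 50, n_bins: int = 64,
                        m_max: int = 6, rtol: float = 10.0, atol: float = 2.0,
                        threshold: float = 0.01, theiler: Optional[int] = None,
                        tau: Optional[int] = None) -> EmbeddingResult:
    """Full delay-embedding analysis: MI delay, then FNN dimension.

    ``tau`` overrides the MI delay selection (the convention for discrete
    maps, whose MI curves flatten without a meaningful minimum, is a delay
    of 1).  A (near-)constant series (fixed-point attractor) is reported as
    dimension 1 with the ``degenerate`` flag.  If the false fraction never
    falls below ``threshold`` the dimension at the global minimum is
    returned with the ``saturated`` flag.
    """
    x = np.asarray(series, dtype=float).ravel()
    if np.ptp(x) < 1e-12 or x.std() < 1e-12:
        return EmbeddingResult(tau=1, mi_curve=np.zeros(tau_max + 1),
                               fnn=np.zeros(m_max), m=1, rtol=rtol, atol=atol,
                               threshold=threshold, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mi = mutual_information_curve(x, tau_max, n_bins)
    if tau is not None:
        method = "fixed"
    else:
        tau, method = select_delay(mi)
    fnn = fnn_fractions(x, tau, m_max=m_max, rtol=rtol, atol=atol,
                        theiler=theiler)
    below = np.flatnonzero(fnn < threshold)
    if below.size:
        m = int(below[0]) + 1
        saturated = False
    else:
        m = int(np.argmin(fnn)) + 1
        saturated = True
    return EmbeddingResult(tau=tau, mi_curve=mi, fnn=fnn, m=m, rtol=rtol,
                           atol=atol, threshold=threshold,
                           delay_method=method, saturated=saturated)


def analyze_best_agents(records, mode: str, ranges=None,
                        neuron: int = 1, trial_index: int = 1,
                        use_potentials: bool = True,
                        **embed_kwargs) -> list[EmbeddingResult]:
    """Embedding analysis of the best agent of each evolutionary run.

    For every record the best solution's trace is generated in the requested
    testing mode (coupled / decoupled) and the neuron-``neuron`` potential
    series of trial ``trial_index`` (agent 1) is analyzed.  Neural *states*
    (potentials y) are used by default; set ``use_potentials=False`` to
    analyze the sigmoid outputs instead.
    """
    from .evolution import ScalingRanges
    from .experiments import test_mode

    if ranges is None:
        ranges = ScalingRanges()
    results = []
    for rec in records:
        params = rec.best_params(ranges)
        trace = test_mode(params, mode, rec.condition, trial_index=trial_index)
        series = (trace.y if use_potentials else trace.neuron_out)[:, 0, neuron - 1]
        results.append(embedding_dimension(series, **embed_kwargs))
    return results
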