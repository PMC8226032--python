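"""End-to-end study driver: evolve all four cells of the 2x2 design
(condition IE/SE x model 2/3 neurons), build the design table, and run the
embedding analysis of the best agents.

Per-cell seeds are derived deterministically from one base seed via
`numpy.random.SeedSequence`, so the whole study is reproducible from a
single integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy_fitness import EntropyConfig
from .evolution import EvolutionRecord, GAConfig, ScalingRanges, evolve_runs
from .experiments import IE, SE
from .tsa import analyze_best_agents

__all__ = ["StudyResult", "cell_seeds", "run_study", "rescore_entropy"]

CELLS = [(IE, 2), (IE, 3), (SE, 2), (SE, 3)]


@dataclass
class StudyResult:
    """All four cells of one study."""

    records: dict            # (condition, n_neurons) -> list[EvolutionRecord]
    table: pd.DataFrame      # one row per run: condition, model, seed, entropy
    embedding: pd.DataFrame  # condition, model, seed, mode, tau, m, degenerate

    def cell_mean_entropy(self, condition: str, n_neurons: int) -> float:
        sel = self.table[(self.table["condition"] == condition)
                         & (self.table["model"] == n_neurons)]
        return float(sel["entropy"].mean())

    def mean_embedding_dim(self, condition: str, n_neurons: int,
                           mode: str) -> float:
        sel = self.embedding[(self.embedding["condition"] == condition)
                             & (self.embedding["model"] == n_neurons)
                             & (self.embedding["mode"] == mode)]
        return float(sel["m"].mean())


def cell_seeds(base_seed: int, n_runs: int) -> dict:
    """Independent per-cell run seeds (< 2**31) derived from one base seed."""
    root = np.random.SeedSequence(base_seed)
    children = root.spawn(len(CELLS))
    return {cell: [int(s) % (2 ** 31) for s in child.generate_state(n_runs)]
            for cell, child in zip(CELLS, children)}


def run_study(cfg: GAConfig, n_runs: int, base_seed: int,
              entropy_cfg: EntropyConfig = EntropyConfig(),
              ranges: ScalingRanges = ScalingRanges(),
              analyze: bool = True, progress: bool = False) -> StudyResult:
    """Evolve all four design cells and analyze the best agent of each run.

    The embedding analysis covers the decoupled mode for every cell and the
    coupled mode for the SE cells (the modes the study's conclusions rest
    on); coupled testing of IE agents against a self-clone remains available
    through `experiments.test_mode`.
    """
    seeds = cell_seeds(base_seed, n_runs)
    records = {}
    rows = []
    embed_rows = []
    for cell in CELLS:
        condition, n_neurons = cell
        if progress:
            print(f"evolving {condition} {n_neurons}-neuron "
                  f"({n_runs} runs)...", flush=True)
        recs = evolve_runs(condition, n_neurons, cfg, seeds[cell],
                           entropy_cfg=entropy_cfg, ranges=ranges,
                           progress=False)
        records[cell] = recs
        for rec in recs:
            rows.append({"condition": condition, "model": n_neurons,
                         "seed": rec.seed,
                         "entropy": rec.final_best_fitness})
        if analyze:
            modes = ["decoupled"] + (["coupled"] if condition == SE else [])
            for mode in modes:
                for rec, res in zip(recs, analyze_best_agents(
                        recs, mode, ranges=ranges)):
                    embed_rows.append({
                        "condition": condition, "model": n_neurons,
                        "seed": rec.seed, "mode": mode, "tau": res.tau,
                        "m": res.m, "degenerate": res.degenerate,
                        "saturated": res.saturated})
    return StudyResult(records=records, table=pd.DataFrame(rows),
                       embedding=pd.DataFrame(embed_rows))


def rescore_entropy(result: StudyResult, bins: int,
                    ranges: ScalingRanges = ScalingRanges()) -> pd.DataFrame:
    """Re-score each best agent's neuron-output series under a different
    histogram resolution (evolution itself is not re-run).

    Used to check that the qualitative entropy ordering between cells does
    not hinge on the default bin count.
    """
    from .evolution import evaluate_population

    rows = []
    cfg = EntropyConfig(bins_per_dim=bins)
    for (condition, n_neurons), recs in result.records.items():
        genos = np.stack([r.best_genotype for r in recs])
        fits = evaluate_population(genos, condition, n_neurons,
                                   entropy_cfg=cfg, ranges=ranges)
        for rec, f in zip(recs, fits):
            rows.append({"condition": condition, "model": n_neurons,
                         "seed": rec.seed, "bins": bins,
                         "entropy": float(f)})
    return pd.DataFrame(rows)
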