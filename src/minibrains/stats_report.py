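"""Statistical comparison of best-of-run entropies across the 2x2 design
(condition IE/SE x model size 2/3 neurons).

The design table has one row per run: the best solution's fitness in the
final generation (best agent for IE, best pair for SE), 10 runs per cell at
full scale.  Outliers are never removed.  The comparisons are a balanced
fixed-effects two-way ANOVA with interaction (residual df = 40 - 4 = 36 at
full scale) and a Bonferroni-corrected two-sample t-test between the
(SE, 2-neuron) and (IE, 3-neuron) cells — the planned comparison between
smaller-brained social and larger-brained solitary agents.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "make_design_table",
    "two_way_anova",
    "posthoc_ttest",
    "summarize",
]

ALPHA = 0.05


def make_design_table(records) -> pd.DataFrame:
    """Design table from evolution records: one row per run with columns
    ``condition`` (IE/SE), ``model`` (2/3), ``seed``, ``entropy``."""
    rows = [{"condition": r.condition, "model": r.n_neurons, "seed": r.seed,
             "entropy": r.final_best_fitness} for r in records]
    return pd.DataFrame(rows)


def _check_design(table: pd.DataFrame) -> None:
    required = {"condition", "model", "entropy"}
    if not required.issubset(table.columns):
        raise ValueError(f"design table needs columns {sorted(required)}")
    counts = table.groupby(["condition", "model"]).size()
    if len(counts) != 4:
        raise ValueError("design must contain all 4 condition x model cells")
    if counts.nunique() != 1:
        raise ValueError("design must be balanced (equal runs per cell)")
    if counts.iloc[0] < 2:
        raise ValueError("need at least 2 runs per cell")


def two_way_anova(table: pd.DataFrame) -> dict:
    """Balanced fixed-effects 2x2 ANOVA with interaction.

    Returns F statistics, degrees of freedom, and p-values for the two main
    effects and their interaction.  With all values identical the F ratios
    are undefined; they are reported as NaN with ``zero_variance`` set.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    _check_design(table)
    df = table.copy()
    df["condition"] = df["condition"].astype(str)
    df["model"] = df["model"].astype(str)
    n_cells = 4
    df_resid = len(df) - n_cells
    if np.ptp(df["entropy"].to_numpy()) == 0:
        return {"F_condition": np.nan, "F_model": np.nan,
                "F_interaction": np.nan, "df_effect": 1, "df_resid": df_resid,
                "p_condition": np.nan, "p_model": np.nan,
                "p_interaction": np.nan, "zero_variance": True}
    model = ols("entropy ~ C(condition) * C(model)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    return {
        "F_condition": float(anova.loc["C(condition)", "F"]),
        "F_model": float(anova.loc["C(model)", "F"]),
        "F_interaction": float(anova.loc["C(condition):C(model)", "F"]),
        "df_effect": int(anova.loc["C(condition)", "df"]),
        "df_resid": int(anova.loc["Residual", "df"]),
        "p_condition": float(anova.loc["C(condition)", "PR(>F)"]),
        "p_model": float(anova.loc["C(model)", "PR(>F)"]),
        "p_interaction": float(anova.loc["C(condition):C(model)", "PR(>F)"]),
        "zero_variance": False,
    }


def posthoc_ttest(table: pd.DataFrame, cell_a=("SE", 2), cell_b=("IE", 3),
                  n_comparisons: int = 1) -> dict:
    """Two-sample t-test between two design cells, Bonferroni-corrected.

    The corrected p is the raw p multiplied by ``n_comparisons`` (the size of
    the planned-comparison family; default 1), capped at 1.  Two identical
    zero-variance samples are a zero difference (t = 0, p = 1).
    """
    def cell(c):
        vals = table[(table["condition"].astype(str) == str(c[0]))
                     & (table["model"].astype(int) == int(c[1]))]["entropy"]
        return vals.to_numpy(dtype=float)

    a, b = cell(cell_a), cell(cell_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each cell needs at least 2 values")
    if a.var() == 0 and b.var() == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=True)
    p_bonf = min(1.0, float(p) * n_comparisons)
    return {"t": float(t), "p_raw": float(p), "p_bonferroni": p_bonf,
            "df": int(a.size + b.size - 2), "n_comparisons": n_comparisons}


def summarize(records, embedding: pd.DataFrame | None = None) -> dict:
    """Aggregate a completed study: design table, cell means, ANOVA, and the
    planned post-hoc comparison.  ``embedding`` may carry per-run embedding
    dimensions (columns condition, model, mode, m) to include their means.
    """
    table = make_design_table(records)
    cell_means = (table.groupby(["condition", "model"])["entropy"]
                  .mean().to_dict())
    out = {
        "design_table": table,
        "cell_means": {f"{c}_{m}n": v for (c, m), v in cell_means.items()},
        "anova": two_way_anova(table),
        "posthoc_se2_vs_ie3": posthoc_ttest(table),
    }
    if embedding is not None:
        out["embedding_means"] = (
            embedding.groupby(["condition", "model", "mode"])["m"]
            .mean().to_dict())
    return out
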