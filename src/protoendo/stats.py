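"""Summary statistics for per-vesicle internal-compartment counts.

Input tables carry one row per vesicle: the stimulus condition
(dC_V, dC_A), a replicate id and the number of internal compartments
counted for that vesicle.  Summaries report, per condition, the fraction
of vesicles with any compartment and with two or more, averaged across
replicates with the sample standard deviation across replicate-level
fractions (matching how replicate error bars are reported), plus a
pooled count histogram.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConditionSummary", "summarize", "histogram", "COUNT_COLUMNS"]

COUNT_COLUMNS = ["dcv_mM", "dca_mM", "replicate", "n_compartments"]


@dataclass
class ConditionSummary:
    """Per-condition summary; sd fields are NaN for a single replicate."""

    dcv_mM: float
    dca_mM: float
    n_total: int
    n_replicates: int
    frac_any: float
    sd_any: float
    frac_multi: float
    sd_multi: float
    histogram: dict


def _validate(table: pd.DataFrame):
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("count table is empty")
    if (table["n_compartments"] < 0).any():
        raise ValueError("n_compartments must be >= 0")


def summarize(table: pd.DataFrame, weighted: bool = False) -> pd.DataFrame:
    """Per-condition summaries of a vesicle count table.

    Replicate-level fractions are computed first; their mean and sample
    SD (ddof=1) form the condition summary.  `weighted=True` weights the
    replicate means by vesicle count instead (the SD stays unweighted).
    Returns one row per condition with columns matching ConditionSummary.
    """
    _validate(table)
    rows = []
    for (dcv, dca), cond in table.groupby(["dcv_mM", "dca_mM"], sort=True):
        per_rep = cond.groupby("replicate")["n_compartments"].agg(
            frac_any=lambda c: float(np.mean(c >= 1)),
            frac_multi=lambda c: float(np.mean(c >= 2)),
            n="size",
        )
        if weighted:
            w = per_rep["n"] / per_rep["n"].sum()
            mean_any = float((per_rep["frac_any"] * w).sum())
            mean_multi = float((per_rep["frac_multi"] * w).sum())
        else:
            mean_any = float(per_rep["frac_any"].mean())
            mean_multi = float(per_rep["frac_multi"].mean())
        n_rep = len(per_rep)
        sd_any = float(per_rep["frac_any"].std(ddof=1)) if n_rep > 1 else np.nan
        sd_multi = (float(per_rep["frac_multi"].std(ddof=1))
                    if n_rep > 1 else np.nan)
        counts = cond["n_compartments"].value_counts().sort_index()
        rows.append({
            "dcv_mM": dcv, "dca_mM": dca,
            "n_total": int(len(cond)), "n_replicates": n_rep,
            "frac_any": mean_any, "sd_any": sd_any,
            "frac_multi": mean_multi, "sd_multi": sd_multi,
            "histogram": {int(k): int(v) for k, v in counts.items()},
        })
    return pd.DataFrame(rows)


def histogram(table: pd.DataFrame, dcv_mM: float, dca_mM: float,
              max_bin: int | None = 3) -> dict:
    """Pooled compartment-count histogram for one condition.

    Bins 0, 1, 2, ..., with counts >= max_bin pooled into the last bin
    (keys are ints; the pooled bin key is max_bin).  max_bin=None keeps
    every count separate.
    """
    _validate(table)
    cond = table[(table["dcv_mM"] == dcv_mM) & (table["dca_mM"] == dca_mM)]
    if len(cond) == 0:
        raise ValueError(f"no records for condition ({dcv_mM}, {dca_mM})")
    counts = cond["n_compartments"].to_numpy()
    if max_bin is not None:
        counts = np.minimum(counts, max_bin)
    vals, freq = np.unique(counts, return_counts=True)
    return {int(v): int(f) for v, f in zip(vals, freq)}
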