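"""Metabolite dry-weight normalisation and condition/time contrasts.

Intracellular metabolite measurements scale with the biomass extracted,
so each replicate value is divided by its culture's dry weight before any
comparison.  Extracellular (supernatant) values pass through unchanged.
Two contrasts are computed, both with the proteome module's t-test at
alpha = 0.01: nitrogen-limited vs replete at 9 h, and 9 h vs 1 h within
the nitrogen-limited culture.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quant import AbundanceMatrix, differential

CONTRASTS = {
    # name: ((condition, timepoint) treated as lowN, (condition, timepoint) as highN)
    "CN150_vs_CN10_9h": (("CN150", "9h"), ("CN10", "9h")),
    "CN150_9h_vs_1h": (("CN150", "9h"), ("CN150", "1h")),
}


def dry_weight_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Divide intracellular replicate values by their dry weight (mg).

    A missing or non-positive dry weight on an intracellular row is an
    error; extracellular rows are returned unchanged.
    """
    out = table.copy()
    intra = out["compartment"] == "intracellular"
    dw = out.loc[intra, "dry_weight"]
    if dw.isna().any() or (dw <= 0).any():
        bad = out.loc[intra & (dw.isna() | (dw <= 0)), "metabolite"].unique()
        raise ValueError(f"missing or non-positive dry weight for {list(bad)[:5]}")
    out.loc[intra, "value"] = out.loc[intra, "value"] / dw
    return out


def _arm_matrix(table, arm, compartment):
    condition, timepoint = arm
    sub = table[
        (table["condition"] == condition)
        & (table["timepoint"] == timepoint)
        & (table["compartment"] == compartment)
    ]
    return sub.pivot_table(index="metabolite", columns="replicate", values="value")


def metabolite_contrast(
    table: pd.DataFrame,
    contrast: str,
    alpha: float = 0.01,
    compartment: str = "intracellular",
) -> pd.DataFrame:
    """One named contrast on dry-weight-normalised log2 values.

    Values are log2-transformed and handed, uncentred, to
    ``quant.differential`` — the metabolite table holds absolute
    quantifications, so there is no per-column loading to remove.
    Metabolites absent from one arm are reported with status 'untested'.
    """
    low_arm, high_arm = CONTRASTS[contrast]
    norm = dry_weight_normalize(table)
    low = _arm_matrix(norm, low_arm, compartment)
    high = _arm_matrix(norm, high_arm, compartment)
    features = sorted(set(low.index) | set(high.index))
    low = low.reindex(features)
    high = high.reindex(features)
    low.columns = [f"low_r{c}" for c in low.columns]
    high.columns = [f"high_r{c}" for c in high.columns]
    values = pd.concat([np.log2(low.where(low > 0)), np.log2(high.where(high > 0))], axis=1)
    conditions = pd.Series(
        ["lowN"] * low.shape[1] + ["highN"] * high.shape[1], index=values.columns
    )
    matrix = AbundanceMatrix(values=values, conditions=conditions, centred=False)
    out = differential(matrix, alpha=alpha)
    out = out.rename(columns={"feature_id": "metabolite"})
    out.insert(1, "contrast", contrast)
    return out


def metabolite_contrasts(table: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Both standard contrasts, concatenated."""
    return pd.concat(
        [metabolite_contrast(table, name, alpha=alpha) for name in CONTRASTS],
        ignore_index=True,
    )
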