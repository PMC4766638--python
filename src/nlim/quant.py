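"""Peptide→protein roll-up, normalisation and differential abundance.

The quantification scheme follows standard isobaric-label practice:
reporter-ion intensities of all peptides are summed per protein (using
only the first protein reference of shared peptides), each sample column
is log2-transformed and mean-centred, and condition contrasts use a
two-tailed two-sample t-test.  Positive log2 fold changes are up in the
nitrogen-limited (lowN, C/N = 150) condition.

The same differential machinery is reused for phosphopeptide matrices and
for metabolite contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .io_formats import PeptideRecord

CONDITIONS = ("highN", "lowN")


@dataclass
class AbundanceMatrix:
    """Feature × sample matrix with per-sample condition labels.

    ``values`` rows are features, columns samples.  ``conditions`` maps
    each sample column to 'highN' or 'lowN'; ``replicates`` (optional)
    maps each sample to its biological replicate, used only for the
    reported per-replicate-difference standard deviation.
    ``centred`` records whether columns were mean-centred.
    """

    values: pd.DataFrame
    conditions: pd.Series
    replicates: pd.Series | None = None
    centred: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]


def design_series(design: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    conditions = pd.Series(design["condition"].values, index=design["sample"].values)
    replicates = pd.Series(design["replicate"].values, index=design["sample"].values)
    return conditions, replicates


def rollup(peptides: list[PeptideRecord], source: str = "global") -> pd.DataFrame:
    """Sum reporter intensities per protein over its peptides.

    Shared peptides contribute only to their *first* mapped protein.
    Returns a raw (protein × sample) intensity matrix; proteins with no
    peptide in ``source`` are absent.
    """
    selected = [p for p in peptides if p.source == source]
    if not selected:
        return pd.DataFrame()
    samples = sorted({s for p in selected for s in p.intensities})
    rows: dict[str, np.ndarray] = {}
    for p in selected:
        vec = rows.setdefault(p.first_protein, np.zeros(len(samples)))
        for i, s in enumerate(samples):
            vec[i] += p.intensities.get(s, 0.0)
    proteins = sorted(rows)
    return pd.DataFrame(
        np.vstack([rows[pid] for pid in proteins]), index=proteins, columns=samples
    )


def normalize(
    raw: pd.DataFrame,
    conditions: pd.Series,
    replicates: pd.Series | None = None,
    center: bool = True,
) -> AbundanceMatrix:
    """log2-transform and (by default) mean-centre each sample column.

    Zero or negative raw intensities are treated as missing (NaN); they
    never enter the log.  Centring subtracts each column's mean over its
    non-missing entries, so every centred column has mean 0.  A column
    with no usable value at all is an error.
    """
    if raw.empty:
        raise ValueError("empty intensity matrix")
    values = raw.astype(float).where(raw > 0)
    if values.isna().all(axis=0).any():
        dead = list(values.columns[values.isna().all(axis=0)])
        raise ValueError(f"sample columns entirely missing: {dead}")
    logged = np.log2(values)
    if center:
        logged = logged - logged.mean(axis=0, skipna=True)
    return AbundanceMatrix(
        values=logged, conditions=conditions, replicates=replicates, centred=center
    )


def differential(
    matrix: AbundanceMatrix, alpha: float, welch: bool = False
) -> pd.DataFrame:
    """Two-tailed two-sample t-test of lowN vs highN per feature.

    log2fc = mean(lowN) − mean(highN) (positive = up under nitrogen
    limitation).  ``sd`` is the standard deviation of per-replicate
    (lowN − highN) differences when replicate structure is known, else
    NaN.  Features with <2 observations in either condition are reported
    with status 'untested'.
    """
    low = matrix.samples_for("lowN")
    high = matrix.samples_for("highN")
    res = stats.two_sample_t(
        matrix.values[low].to_numpy(), matrix.values[high].to_numpy(), welch=welch
    )
    sd = _paired_replicate_sd(matrix, low, high)
    out = pd.DataFrame(
        {
            "feature_id": matrix.values.index,
            "log2fc": res.diff,
            "sd": sd,
            "t": res.t,
            "p": res.p,
            "n_low": res.n_a,
            "n_high": res.n_b,
            "status": res.status,
        }
    )
    out["significant"] = (out["p"] < alpha).fillna(False)
    return out


def _paired_replicate_sd(matrix, low, high):
    if matrix.replicates is None:
        return np.full(len(matrix.values), np.nan)
    reps = sorted(set(matrix.replicates))
    diffs = []
    for rep in reps:
        low_r = [s for s in low if matrix.replicates[s] == rep]
        high_r = [s for s in high if matrix.replicates[s] == rep]
        if not low_r or not high_r:
            continue
        diffs.append(
            matrix.values[low_r].mean(axis=1, skipna=True)
            - matrix.values[high_r].mean(axis=1, skipna=True)
        )
    if len(diffs) < 2:
        return np.full(len(matrix.values), np.nan)
    return pd.concat(diffs, axis=1).std(axis=1, ddof=1).to_numpy()


def proteome_coverage(n_detected: int, n_total: int) -> float:
    """Percent of annotated coding sequences with quantified peptides."""
    if n_total <= 0 or n_detected < 0 or n_detected > n_total:
        raise ValueError("bad coverage counts")
    return round(100.0 * n_detected / n_total, 1)
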