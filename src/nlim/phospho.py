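"""Phosphoproteomics: IMAC filtering, protein-controlled fractional
phosphosite changes, and regulatory-class phosphorylation enrichment.

A phosphopeptide's abundance confounds protein amount with phosphorylation
occupancy.  Subtracting the parent protein's log2 change (estimated from
the global, non-enriched run) from the phosphopeptide's log2 change leaves
the change in the phosphorylated *fraction* of the protein — the quantity
of regulatory interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .io_formats import PeptideRecord
from .quant import AbundanceMatrix

REGULATORY_CLASSES = ("kinase", "phosphatase", "dna_binding")

PEPTIDE_KEY_SEP = "|"


def peptide_key(record: PeptideRecord) -> str:
    """Stable feature id for a phosphopeptide: protein|sequence|sites."""
    sites = ";".join(f"{r}{p}" for r, p in record.phospho_sites)
    return PEPTIDE_KEY_SEP.join((record.first_protein, record.sequence, sites))


def filter_imac(
    peptides: list[PeptideRecord],
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Partition IMAC-enriched peptides into phosphopeptides and contaminants.

    Peptides identified after enrichment but carrying no phosphosite are
    treated as co-purifying contamination from abundant proteins and are
    excluded from all downstream analysis.
    """
    imac = [p for p in peptides if p.source == "imac"]
    kept = [p for p in imac if p.is_phosphopeptide]
    contaminants = [p for p in imac if not p.is_phosphopeptide]
    return kept, contaminants


def contaminant_report(contaminants: list[PeptideRecord]) -> pd.DataFrame:
    """Contaminants ranked by total reporter intensity (1 = most abundant)."""
    rows = [
        {"sequence": p.sequence, "protein": p.first_protein, "total_intensity": p.total_intensity()}
        for p in contaminants
    ]
    df = pd.DataFrame(rows, columns=["sequence", "protein", "total_intensity"])
    df = df.sort_values("total_intensity", ascending=False, kind="stable").reset_index(drop=True)
    df["abundance_rank"] = np.arange(1, len(df) + 1)
    return df


def phosphopeptide_matrix(phosphopeptides: list[PeptideRecord]) -> pd.DataFrame:
    """Raw (phosphopeptide × sample) intensity matrix, one row per peptide key.

    Identical peptide keys (same protein, sequence and site set, e.g. from
    repeated observations) are summed, mirroring the protein roll-up.
    """
    if not phosphopeptides:
        return pd.DataFrame()
    samples = sorted({s for p in phosphopeptides for s in p.intensities})
    rows: dict[str, np.ndarray] = {}
    for p in phosphopeptides:
        vec = rows.setdefault(peptide_key(p), np.zeros(len(samples)))
        for i, s in enumerate(samples):
            vec[i] += p.intensities.get(s, 0.0)
    keys = sorted(rows)
    return pd.DataFrame(np.vstack([rows[k] for k in keys]), index=keys, columns=samples)


def fractional_change(
    phos: AbundanceMatrix,
    prot: AbundanceMatrix,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Protein-controlled phosphopeptide changes.

    For each phosphopeptide row (keyed protein|sequence|sites) the parent
    protein's normalised values are subtracted sample-by-sample and the
    resulting per-replicate differences are compared between conditions
    with a two-sample t-test.  ``frac_log2change`` is therefore
    phospho log2fc − protein log2fc.  Peptides whose protein is absent
    from the global data get status 'no_global_reference' and no value.
    """
    if phos.values.empty:
        return pd.DataFrame(
            columns=["feature_id", "protein", "frac_log2change", "p", "status", "significant"]
        )
    if list(phos.values.columns) != list(prot.values.columns):
        raise ValueError("phospho and protein matrices have mismatched samples")
    if any(phos.conditions[s] != prot.conditions[s] for s in phos.values.columns):
        raise ValueError("phospho and protein matrices have mismatched conditions")

    proteins = [key.split(PEPTIDE_KEY_SEP, 1)[0] for key in phos.values.index]
    known = prot.values.index
    has_ref = np.array([pid in known for pid in proteins])

    diffs = np.full(phos.values.shape, np.nan)
    if has_ref.any():
        prot_rows = prot.values.loc[[p for p, ok in zip(proteins, has_ref) if ok]].to_numpy()
        diffs[has_ref] = phos.values.to_numpy()[has_ref] - prot_rows

    low = phos.samples_for("lowN")
    high = phos.samples_for("highN")
    low_idx = [phos.values.columns.get_loc(s) for s in low]
    high_idx = [phos.values.columns.get_loc(s) for s in high]
    res = stats.two_sample_t(diffs[:, low_idx], diffs[:, high_idx], welch=welch)

    status = np.where(has_ref, res.status, "no_global_reference").astype(object)
    frac = np.where(has_ref, res.diff, np.nan)
    p = np.where(has_ref, res.p, np.nan)
    out = pd.DataFrame(
        {
            "feature_id": phos.values.index,
            "protein": proteins,
            "sequence": [k.split(PEPTIDE_KEY_SEP)[1] for k in phos.values.index],
            "sites": [k.split(PEPTIDE_KEY_SEP)[2] for k in phos.values.index],
            "frac_log2change": frac,
            "p": p,
            "status": status,
        }
    )
    out["significant"] = (out["p"] < alpha).fillna(False)
    return out


@dataclass
class ClassEnrichment:
    cls: str
    k: int
    n: int
    percent_raw: float
    percent: int
    fisher_p: float


def class_phospho_enrichment(
    classes: dict[str, str], phosphoproteins: set[str]
) -> pd.DataFrame:
    """Per-regulatory-class phosphorylation rates vs the genome.

    For each class the fraction of members with at least one phosphosite
    is reported (rounded percent alongside the raw value) with a two-sided
    Fisher's exact p for class vs rest-of-genome × phosphorylated vs not.
    A 'genome' row gives the overall rate.
    """
    unknown = set(phosphoproteins) - set(classes)
    if unknown:
        raise ValueError(f"phosphoproteins missing from class table: {sorted(unknown)[:5]}")
    total_n = len(classes)
    total_k = len(phosphoproteins)
    rows = []
    for cls in REGULATORY_CLASSES + ("other",):
        members = {p for p, c in classes.items() if c == cls}
        n = len(members)
        k = len(members & phosphoproteins)
        if n == 0:
            rows.append((cls, k, n, np.nan, np.nan, np.nan))
            continue
        p = stats.fisher_exact_two_sided(k, n, total_k, total_n)
        rows.append((cls, k, n, 100.0 * k / n, round(100.0 * k / n), float(p)))
    rows.append(
        ("genome", total_k, total_n, 100.0 * total_k / total_n,
         round(100.0 * total_k / total_n), np.nan)
    )
    return pd.DataFrame(
        rows, columns=["class", "k", "n", "percent_raw", "percent", "fisher_p"]
    )


def unique_sites(phosphopeptides: list[PeptideRecord]) -> dict[str, set[tuple[str, int]]]:
    """Deduplicated phosphosites per protein, keyed (residue, position)."""
    sites: dict[str, set[tuple[str, int]]] = {}
    for p in phosphopeptides:
        sites.setdefault(p.first_protein, set()).update(p.phospho_sites)
    return sites


def sites_per_protein(
    phosphopeptides: list[PeptideRecord], classes: dict[str, str]
) -> pd.DataFrame:
    """Histogram of unique phosphosite counts per protein, by class.

    Proteins without any phosphopeptide are excluded.  The 'proteome'
    rows pool every phosphoprotein regardless of class.
    """
    per_protein = {pid: len(s) for pid, s in unique_sites(phosphopeptides).items()}
    rows = []
    groups: dict[str, list[int]] = {"proteome": list(per_protein.values())}
    for pid, count in per_protein.items():
        cls = classes.get(pid, "other")
        groups.setdefault(cls, []).append(count)
    for cls, counts in groups.items():
        for n_sites in sorted(set(counts)):
            rows.append((cls, n_sites, counts.count(n_sites)))
    return pd.DataFrame(rows, columns=["class", "n_sites", "n_proteins"])
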