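"""Fisher's-exact gene-ontology enrichment with Benjamini–Hochberg FDR.

Used for differentially abundant proteins, motif-associated gene sets and
regulatory-class phosphorylation.  Terms are tested as annotated; no
ontology-graph propagation is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import stats


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def go_enrichment(
    study: set[str], population: set[str], go_table: pd.DataFrame
) -> pd.DataFrame:
    """Two-sided Fisher's exact enrichment of GO terms in a study set.

    ``go_table`` has columns gene, term (one row per annotation).  Only
    annotations of population genes are considered; terms annotating no
    population gene are not tested.  Returns one row per tested term with
    the 2×2 counts, two-sided p, BH FDR across tested terms, and an
    over/under direction label.
    """
    study = set(study)
    population = set(population)
    if not study <= population:
        raise ValueError("study set is not a subset of the population")
    anno = go_table[go_table["gene"].isin(population)]
    pop_n = len(population)
    study_n = len(study)
    rows = []
    for term, genes in anno.groupby("term")["gene"]:
        term_genes = set(genes)
        pop_k = len(term_genes)
        study_k = len(term_genes & study)
        rows.append((term, study_k, pop_k))
    if not rows:
        return pd.DataFrame(
            columns=["term", "study_k", "study_n", "pop_k", "pop_n", "p", "fdr", "direction"]
        )
    terms, study_k, pop_k = zip(*rows)
    study_k = np.array(study_k)
    pop_k = np.array(pop_k)
    p = stats.fisher_exact_two_sided(study_k, study_n, pop_k, pop_n)
    p = np.atleast_1d(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        over = study_k / max(study_n, 1) > pop_k / pop_n
    out = pd.DataFrame(
        {
            "term": terms,
            "study_k": study_k,
            "study_n": study_n,
            "pop_k": pop_k,
            "pop_n": pop_n,
            "p": p,
            "fdr": bh_fdr(p),
            "direction": np.where(over, "over", "under"),
        }
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)
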