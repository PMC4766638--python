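"""GO enrichment of the differential proteins and of motif gene sets.

Tests up- and down-regulated proteins against the genome (two-sided
Fisher with BH FDR), then the genes carrying each profiled motif within
0.5 kb of their TSS (terms reported at p < 0.005).  Writes
results/go_up.tsv, results/go_down.tsv and results/motif_go.tsv.
"""

from pathlib import Path

import pandas as pd

from nlim import enrich, io_formats, motif, quant
from nlim import tss_promoter as tp

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "dataset"
RESULTS = ROOT / "results"


def main() -> None:
    go_table = io_formats.read_go_table(DATA / "go.tsv")
    peptides = io_formats.read_peptide_table(DATA / "peptides.tsv")
    conditions, replicates = quant.design_series(io_formats.read_design(DATA / "design.tsv"))
    matrix = quant.normalize(quant.rollup(peptides, "global"), conditions, replicates)
    res = quant.differential(matrix, alpha=0.001)
    population = set(res["feature_id"])

    RESULTS.mkdir(exist_ok=True)
    for direction, sign in (("up", 1), ("down", -1)):
        study = set(res[(res["significant"]) & (sign * res["log2fc"] > 0)]["feature_id"])
        out = enrich.go_enrichment(study, population, go_table)
        out.to_csv(RESULTS / f"go_{direction}.tsv", sep="\t", index=False)
        top = out[out["fdr"] < 0.05]
        print(f"{direction}-regulated ({len(study)} genes): {len(top)} terms at FDR<0.05")
        if not top.empty:
            print(top.head(3)[["term", "fdr", "direction"]].to_string(index=False))

    annotation = io_formats.read_gff(DATA / "genes.gff3")
    coverage = io_formats.read_bedgraph(DATA / "coverage.bedgraph", annotation)
    genome = io_formats.read_fasta(DATA / "genome.fa")
    tp.call_all_tss(annotation, coverage)
    prom_full = tp.extract_promoters(annotation, genome, tp.TO_NEXT_TRANSCRIPT)

    rows = []
    for pattern in ["G[AC]TAAGC", "CACGTG[AC]"]:
        hits = motif.nearest_upstream(prom_full, pattern)
        out = motif.motif_go(hits, go_table, population)
        out.insert(0, "motif", pattern)
        rows.append(out)
        terms = ", ".join(out["term"].head(3)) if not out.empty else "none"
        print(f"{pattern} within 0.5 kb: enriched terms (p<0.005): {terms}")
    pd.concat(rows, ignore_index=True).to_csv(RESULTS / "motif_go.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
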