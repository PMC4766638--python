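"""Phosphoproteome: IMAC filtering, protein-controlled fractional changes,
and regulatory-class phosphorylation enrichment.

Writes results/phospho_diff.tsv, results/class_enrichment.tsv and
results/sites_per_protein.tsv.  The class-enrichment step is also run on
the published-count fixture, reproducing the printed percentages
(kinases 37 %, DNA binding 18 %, genome 9 %, phosphatases 9 %).
"""

from pathlib import Path

from nlim import io_formats, phospho, quant
from nlim import synthetic_data as sd

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "dataset"
RESULTS = ROOT / "results"


def main() -> None:
    peptides = io_formats.read_peptide_table(DATA / "peptides.tsv")
    conditions, replicates = quant.design_series(io_formats.read_design(DATA / "design.tsv"))
    classes = io_formats.read_class_table(DATA / "classes.tsv")

    kept, contaminants = phospho.filter_imac(peptides)
    print(f"IMAC: kept {len(kept)} phosphopeptides, dropped {len(contaminants)} contaminants")

    prot = quant.normalize(quant.rollup(peptides, "global"), conditions, replicates)
    phos = quant.normalize(phospho.phosphopeptide_matrix(kept), conditions, replicates)
    frac = phospho.fractional_change(phos, prot, alpha=0.05)
    RESULTS.mkdir(exist_ok=True)
    frac.to_csv(RESULTS / "phospho_diff.tsv", sep="\t", index=False)
    up = ((frac["significant"]) & (frac["frac_log2change"] > 0)).sum()
    down = ((frac["significant"]) & (frac["frac_log2change"] < 0)).sum()
    print(f"{up} peptides with increased and {down} with decreased phosphorylation (p<0.05)")

    phosphoproteins = {p.first_protein for p in kept}
    table = phospho.class_phospho_enrichment(classes, phosphoproteins)
    table.to_csv(RESULTS / "class_enrichment.tsv", sep="\t", index=False)
    print("synthetic dataset class enrichment:")
    print(table.to_string(index=False))

    fixture_classes, fixture_phospho, _ = sd.fixture_published_counts()
    printed = phospho.class_phospho_enrichment(fixture_classes, fixture_phospho)
    print("published-count fixture percentages:")
    print(printed[["class", "k", "n", "percent"]].to_string(index=False))

    hist = phospho.sites_per_protein(kept, classes)
    hist.to_csv(RESULTS / "sites_per_protein.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
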