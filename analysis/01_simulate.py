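"""Generate the benchmark dataset every later step analyses.

Writes a synthetic multi-omics experiment (genome, gene models, RNA-seq
coverage, global + IMAC peptide reports, metabolite table, GO and
regulatory-class annotations) with its ground-truth table to
scratch/dataset/.  All downstream scripts read those files back through
the package's I/O layer, exactly as they would a real deposit.
"""

from pathlib import Path

from nlim import synthetic_data as sd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "dataset"
SEED = 42


def main() -> None:
    config = sd.SimConfig()
    dataset = sd.generate(config, SEED, OUT)
    n_phos = sum(1 for p in dataset.peptides if p.source == "imac" and p.is_phosphopeptide)
    n_cont = sum(1 for p in dataset.peptides if p.source == "imac" and not p.is_phosphopeptide)
    print(f"dataset written to {OUT}")
    print(f"  genome: {len(dataset.genome['chr1']):,} bp, {config.n_genes} genes")
    print(f"  global peptides: {sum(p.source == 'global' for p in dataset.peptides)}")
    print(f"  IMAC peptides: {n_phos} phosphorylated + {n_cont} contaminants")
    print(f"  metabolite rows: {len(dataset.metabolites)}")


if __name__ == "__main__":
    main()
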