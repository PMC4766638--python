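# nlim — multi-omics analysis of the nitrogen-limitation response

`nlim` re-implements, as a tested and reusable pipeline, the multi-omics
analysis of how the oleaginous yeast *Yarrowia lipolytica* responds to
nitrogen limitation (molar C/N = 150, vs the replete C/N = 10). Nitrogen
limitation triggers storage-lipid accumulation in this organism, and the
analysis connects four data layers to the regulators behind it:

* **Proteome** — 4-plex isobaric (iTRAQ) reporter-ion intensities are
  summed per protein (shared peptides count only for their first mapped
  protein), each sample is log2-transformed and mean-centred, and
  proteins are tested with a two-tailed pooled t-test at *p* < 0.001.
  Positive log2 fold changes are up under nitrogen limitation.
* **Phosphoproteome** — IMAC-enriched peptides without a phosphosite are
  discarded as contamination from abundant proteins. For each
  phosphopeptide the parent protein's log2 change is subtracted
  (`Δφ = Δphospho − Δprotein`), so what is tested (*p* < 0.05) is the
  change in the *phosphorylated fraction* of the protein, not its
  abundance. Regulatory classes (kinases, phosphatases, DNA-binding
  proteins) are then tested for phosphorylation enrichment with
  Fisher's exact test.
* **Metabolome** — intracellular metabolites are dry-weight normalised
  and contrasted (limited vs replete at 9 h; 9 h vs 1 h within the
  limited culture) at *p* < 0.01.
* **Promoters** — each gene's TSS is annotated from RNA-seq coverage as
  the last base 5' of the start codon whose read count stays above the
  intergenic background. Degenerate DNA motifs (e.g. the GATA-factor
  site `G[AC]TAAGC`, the E-box `CACGTG[AC]`) are discovered
  discriminatively in the 500 bp promoters of regulated genes, located
  in the full TSS-to-next-transcript promoters, and their effect on
  expression is profiled as mean protein log2 fold change in 0.1 kb
  distance bins up to 1.5 kb. Gene sets defined by a motif within
  0.5 kb of the TSS are tested for GO enrichment (Fisher's exact test,
  Benjamini–Hochberg FDR).

Because no public accessions accompany the study, the package ships a
first-class synthetic-data generator (`nlim.synthetic_data`) that
emulates the full study design — log-normal protein abundances with
planted condition effects, peptide-level channel noise, planted
phospho-occupancy effects independent of protein effects, a toy genome
with planted TSS offsets and promoter motifs whose effect decays with
distance — and persists every planted parameter in a truth table, so
every stage is tested for parameter recovery and null calibration.

## Worked example

```
python analysis/01_simulate.py     # writes scratch/dataset/ (seed 42)
python analysis/02_proteome.py
python analysis/05_tss_promoters.py
python analysis/06_motifs.py
```

prints, among other things:

```
300 proteins tested; 172 significant at p<0.001
  recovered 120/120 planted |log2fc|>=1 effects
  empirical FDR 0.6%
estimated background: 2.0 reads/base (intergenic median)
called 300 TSSs; 97.3% within 2 bp of the planted offset
top enriched motifs:
    pattern  k_pos  n_total            p
 GCTTA[GT]C     64       84 4.376452e-28
 G[AC]TAAGC     64       84 4.376452e-28
G[AC]TAAGC: 149 genes with a site; occupancy peaks in [100,200) bp (mean log2fc there +0.89)
CACGTG[AC]: 154 genes with a site; occupancy peaks in [200,300) bp (mean log2fc there -0.77)
```

The discovered top motif is exactly the planted GATA site (reported in
both orientations), its nearest-occurrence distances peak in the
planted 100–300 bp window, and genes carrying it near their TSS show
the planted positive fold-change effect. Analyses 03, 04 and 07 do the
same for the phosphoproteome, metabolome and GO layers; every table
lands under `results/`.

A `nlim` console command exposes the same steps individually
(`nlim simulate`, `nlim quant`, `nlim phospho`, `nlim metabolome`,
`nlim tss`, `nlim motif-profile`, `nlim enrich`, `nlim validate`).

## Layout

```
src/nlim/        library: io_formats, quant, phospho, metabolome,
                 tss_promoter, motif, enrich, synthetic_data, stats, cli
analysis/        numbered narrative drivers (01_simulate ... 07_go_enrichment)
tests/           pytest suite incl. brute-force oracles and acceptance checks
scripts/         acceptance.py
docs/methods.md  models, parameter choices, numerical conventions, limitations
```
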