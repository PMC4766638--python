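# Methods

This note documents the models and procedures implemented in `nlim`,
the parameter choices that matter, the generative models behind the
synthetic benchmark, and the numerical conventions — in the order the
pipeline runs.

## Quantification and differential abundance (`quant`)

**Roll-up.** Reporter-ion intensities of all peptides are summed per
protein and sample. A peptide mapping to several proteins contributes
only to the *first* protein in its report order; this keeps the roll-up
intensity-conserving (the sum over proteins equals the sum over
peptides) at the cost of occasionally crediting a shared peptide to the
wrong paralogue. Proteins with no peptide are absent rather than zero.

**Normalisation.** Each sample column is log2-transformed and then
mean-centred over its non-missing entries. The transform order matters:
centring raw intensities before taking logs is ill-defined (it can
produce negatives), so the pipeline always logs first — the behaviour of
the standard proteomics normalisation tools. Zero or negative reporter
intensities are treated as missing at random and excluded; nothing is
imputed. Column mean-centring removes per-sample loading differences
under the assumption that most features do not change, or that changes
are symmetric; the synthetic generator plants symmetric ± effects so
this assumption holds by construction, and the residual per-dataset
centring offset (shared by all features of one sample) is mean-zero
across simulations, which is what the unbiasedness tests measure.

**Differential test.** Two-tailed two-sample Student t with pooled
variance, lowN (C/N = 150) minus highN (C/N = 10), so positive log2
fold changes are up under nitrogen limitation. Welch's form is
available behind a flag. Thresholds follow the published analysis: raw
*p* < 0.001 for proteins, *p* < 0.05 for phosphopeptides, *p* < 0.01
for metabolites, with no multiple-testing correction at these stages;
FDR control is applied only where enrichment tables are reported (GO,
motif discovery). Features with fewer than two observations in a
condition are reported `untested`. Zero pooled variance with equal
means yields *p* = 1; with unequal means the limit *p* = 0 is reported
with a `degenerate` flag rather than silently claiming significance.
The reported `sd` column is the standard deviation of per-replicate
(lowN − highN) differences, averaging the condition's channels within
each replicate first — the report layout does not define this quantity,
so the definition is fixed here.

**Design.** The 4-plex labelling is encoded in an explicit design table
(sample = `r<replicate>_<channel>`): within each of the 3 biological
replicates, reporter channels 114/115 carry the replete and 116/117 the
limited condition. The t-test treats samples as independent
observations grouped by condition; the design file is the single place
where channel-to-condition pairing is defined.

## Phosphoproteomics (`phospho`)

IMAC-enriched peptides without any S/T/Y phosphosite are partitioned
out as co-purification contaminants (they are logged with their
abundance rank but excluded from analysis). Phosphopeptides are
quantified per peptide — a peptide carrying several sites is one test,
with its sites reported alongside — keyed `protein|sequence|sites`.

The fractional phosphorylation change is computed in log space:
`Δφ = log2FC(phosphopeptide) − log2FC(protein)`, i.e. a ratio of
ratios, consistent with every downstream quantity being a log2 change.
Its p-value comes from a two-sample t-test on the per-sample
differences (phosphopeptide value − matched protein value) between
conditions. Peptides whose parent protein was not quantified in the
global run get status `no_global_reference` and no value — their
occupancy change cannot be separated from protein-level change.

Class enrichment builds, per regulatory class, the 2×2 table
(class membership × has ≥1 phosphosite) against the rest of the genome
and reports the two-sided Fisher's exact p with the percentage of
phosphorylated members (raw value retained, integer-rounded for
reporting). A protein counts as phosphorylated if it has at least one
phosphopeptide in either condition; site counts per protein
deduplicate on (residue, position) across peptides.

## Metabolomics (`metabolome`)

Intracellular replicate values are divided by that culture's dry weight
(mg); extracellular values pass through unchanged — whether the
original supernatant values were volume- or OD-normalised is not
recoverable, so no further scaling is invented. Both contrasts
(limited vs replete at 9 h; 9 h vs 1 h within the limited culture)
delegate to `quant.differential` on log2 values *without* column
centring: mean-centring is an isobaric within-plex normalisation, and
the metabolite table holds absolute quantifications. The
arginine/ornithine pool that GC-MS cannot separate is modelled in the
generator as a summed pair carrying a `pooled` flag; no analytical
unpooling is attempted.

## TSS calling and promoters (`tss_promoter`)

The TSS is found by walking base-by-base 5' from the start codon along
strand-agnostic per-base coverage; it is the last base whose count
exceeds the background before the first base at or below it. The
comparison is `≤ background` and a single sub-background base
terminates the scan — the literal reading of the rule; an optional
moving-average smoothing window (default off) is provided for noisy
tracks, since the appropriate choice for real tracks is data-dependent.
The scan never crosses the upstream neighbouring transcript: plateaus
reaching it give a `clipped` call at the boundary. If the first
upstream base is already at background the TSS falls back to the start
codon with a `degenerate` flag; such genes are kept (flags propagate to
outputs) so downstream motif analysis covers all genes.

The background level is not defined by the rule itself; the default is
the median per-base count over intergenic space — outside all gene
bodies and 1 kb flanks (which absorb unannotated UTR coverage) — and
can be overridden with an explicit value.

Two promoter definitions are extracted per gene: `fixed500` (at most
500 bp immediately upstream of the TSS, clipped at the upstream
boundary — used for motif discovery) and `to_next_transcript` (the full
region from the TSS to the neighbouring transcript — used for motif
location). Sequences read 5'→3' on the gene's strand (− strand
promoters are reverse-complemented), so the last base of every
promoter sequence abuts the TSS; motif-to-TSS distances are measured
from that end to the match edge nearest the TSS.

## Motifs (`motif`)

Patterns are IUPAC codes plus explicit bracket classes (`G[AC]TAAGC`).
Scanning tests every position on both strands (a reverse-strand match
is reported at its forward coordinate; double-strand palindrome matches
collapse to one position); `N` in a sequence matches nothing.
Overlapping matches are all reported. Per gene, the nearest upstream
occurrence defines the distance; profiles bin genes in half-open 0.1 kb
windows `[0,100), [100,200) …` up to 1.5 kb and summarise mean and
interquartile range of the protein log2 fold change per bin. Both the
half-open binning and the nearest-edge distance convention are fixed
here; neither is externally specified.

Motif *discovery* is deliberately not a DREME re-implementation but a
transparent stand-in operating in the same candidate space: every exact
word of length k ∈ {6,7,8} present in the positive promoters is tested
for presence/absence against the background promoters with two-sided
Fisher's exact p, and the best words are generalised one position at a
time to two-letter bracket classes, kept when the p improves. The
E-value is p times the number of candidates examined. The background
set is all non-positive promoters (a shuffled-control mode exists
behind the `MotifEnricher` API). The printed motif shapes of interest
— one bracket class each — are expressible in this space, and the
location/profile analyses accept any pattern directly, so discovery is
a convenience, not a dependency.

Motif→GO association takes genes whose nearest occurrence is within
0.5 kb of the TSS as the study set against all genes, delegating to the
enrichment module, and reports terms with *p* < 0.005.

## Enrichment (`enrich`)

GO terms are tested as annotated (no ontology-graph propagation), each
with a two-sided Fisher's exact test of the 2×2 study/population ×
term/no-term table; direction is labelled `over`/`under` by comparing
study and population frequencies, and Benjamini–Hochberg step-up FDR is
computed across the tested terms. Terms annotating no population gene
are not tested. Two-sided testing with direction labels (rather than
separate one-sided tests) is the documented choice.

The two-sided Fisher p sums hypergeometric probabilities of all tables
whose probability is at most the observed one times (1 + 1e-7) — the
standard relative tie tolerance — evaluated from a cached log-factorial
table so that calibration sweeps over tens of thousands of tables stay
fast. The test-suite oracles recompute the same sum with exact integer
combinatorics, and the pooled-t p by numeric quadrature of the t
density, so agreement (≤1e-12) checks numerics rather than shared code.

## Synthetic benchmark (`synthetic_data`)

The generator emulates the study design: two conditions (C/N = 10 vs
150), three biological replicates, 4-plex labelling, triplicate
metabolite measurements with dry weights.

* Peptide intensity = protein abundance × per-peptide ionisation factor
  (log-normal, σ = 1.5 log2 units) × per-channel noise (log-normal,
  σ = 0.2 log2 units). This is the minimal model under which
  "sum, log2, centre" is a sensible estimator. 70 % of proteins are
  null; the rest carry symmetric ± effects of 1–2.5 log2 units.
* Phosphopeptide intensity = protein abundance × occupancy (base 0.25),
  with occupancy ratio 2^φ across conditions and φ drawn independently
  of the protein's δ — making log-space subtraction exactly unbiased,
  so bias tests are sharp. IMAC contaminants (0.72 per phosphopeptide,
  the observed ratio) are non-phospho peptides drawn from the top
  abundance quintile.
* Genome: 300 genes of 300–900 bp on both strands, TSS offsets
  u ~ U[20, 800] bp, coverage = depth-50 plateau over [TSS, gene end]
  plus Poisson(λ = 2) noise everywhere. Intergenic gaps are drawn from
  U[1700, 2600] bp with a 25 % admixture of U[2600, 3600]: gaps must
  exceed ~1.6 kb so that the coverage plateaus of adjacent
  opposite-strand genes can never merge (which would corrupt TSS
  calls), and a fraction must exceed 2 kb so intergenic bases survive
  the 1 kb flanks and the background median is estimable. The genome
  length (~0.9 Mb) follows from the packing. With these defaults the
  TSS caller lands within ±2 bp for ≥95 % of genes — the step off the
  plateau overshoots only while consecutive background bases exceed
  λ = 2, a geometric tail with success probability
  P[Poisson(2) ≤ 2] ≈ 0.68.
* Motifs: two planted plans by default — `G[AC]TAAGC` (GATA-type, 60
  genes, distances ~N(150, 30) bp, effect +2·exp(−d/300 bp) log2) and
  `CACGTG[AC]` (E-box, 60 genes, ~N(250, 60) bp, −2·exp(−d/300 bp)).
  A random realisation of each pattern is stamped into the promoter at
  the drawn distance (reverse-complemented for − strand genes), and
  the gene's planted δ is set to the distance-decayed effect.
* Metabolites: three measured cells (replete 9 h, limited 1 h and 9 h),
  log-normal concentrations, replicate noise σ = 0.25 log2 units,
  dry weights ~N(10, 0.7) mg; 60 % null, effects 1–3 log2 units.
  Intracellular raw values are concentration × dry weight, so
  normalisation must undo the dry weight to recover the planted folds.
* Annotations: 20 kinases, 12 phosphatases, 40 DNA-binding proteins
  with class-dependent phosphorylation probabilities (0.75 / 0.25 /
  0.45 vs 0.25 baseline); GO terms are assigned randomly with two
  planted couplings (the GATA-motif genes to "amino-acid biosynthesis",
  up-regulated genes to "proteolysis").

Identical seeds reproduce byte-identical output directories; the truth
table stores every planted parameter.

What the generator does **not** emulate: missed cleavages, isotope
impurity between reporter channels, batch effects, peptide-level
missingness that depends on abundance, transcript structure beyond a
single TSS, metabolite identification ambiguity beyond the one pooled
pair. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated models, not robustness to these real-data
pathologies.

A separate deterministic fixture (`fixture_paper_counts`) reproduces
the published genome-scale counts exactly — 6448 models; 89/45/279
class sizes with 33/4/49 phosphorylated members; 599 phosphoproteins;
3567 models quantified in all replicates — so the printed
class-phosphorylation percentages (37/18/9/9 %) and the 55.3 % proteome
coverage are recomputed, not transcribed.

## Problem sizes used in the checks

Unbiasedness of protein log2FC and fractional phospho changes is
measured over 200 independent 48-gene simulations (pooling >500
phosphopeptides for the φ–δ independence check); TSS recovery on one
500-gene genome; motif recovery and distance profiles on one
default 300-gene dataset through the full pipeline; null calibration
on 10,000-feature simulations per stage, 200 × 50 null GO terms and 200
label shuffles for motif discovery. These sizes give the binomial and
3·SE margins quoted in the tests while keeping the default suite in the
minutes range.

## Known limitations

* The first-protein rule makes shared-peptide attribution order-
  dependent; real paralogue families would need protein inference.
* Strand-agnostic coverage cannot separate overlapping antisense
  transcription from a gene's own 5' UTR; TSS calls inherit this.
* The discovery stand-in explores only exact words plus one bracket
  class; motifs with two or more degenerate positions are found only
  via their best one-bracket approximation.
* No site-localisation scoring: a phosphopeptide's sites are taken as
  reported.
* The peptide-report TSV layout (`sequence, proteins, phospho_sites,
  source, r<rep>_<channel>…`) is this repository's own definition, as
  is the long-format metabolite table.
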