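"""TSS calling from RNA-seq coverage and promoter extraction.

The transcription start site of a gene is annotated by walking base by
base 5' from the start codon along (strand-agnostic) read coverage: the
TSS is the last base whose count stays above the background level before
the first base at or below it.  Background defaults to the median
per-base count over intergenic space.

Two promoter definitions are supported: the fixed 500 bp immediately
upstream of the TSS (used for motif discovery) and the full region from
the TSS to the nearest neighbouring transcript (used for motif location
analysis).  Promoter sequences are returned 5'→3' on the gene's strand,
so the *last* base of each sequence is adjacent to the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CoverageTrack, GeneModel, GenomeAnnotation

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FIXED500 = "fixed500"
TO_NEXT_TRANSCRIPT = "to_next_transcript"


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class TssCall:
    gene_id: str
    tss: int
    offset: int          # bp from start codon to TSS, transcript orientation
    flag: str            # 'ok' | 'degenerate' | 'clipped'


@dataclass
class Promoter:
    gene_id: str
    chrom: str
    start: int           # genomic, 0-based half-open
    end: int
    strand: str
    sequence: str        # 5'->3' on the gene strand; last base abuts the TSS
    definition: str

    def __len__(self) -> int:
        return len(self.sequence)


def call_tss(
    gene: GeneModel,
    coverage: CoverageTrack,
    background: float,
    smooth: int = 0,
) -> TssCall:
    """Scan 5' from the start codon until coverage drops to background.

    The comparison is ``count <= background``; a single sub-background
    base terminates the scan (no smoothing by default; ``smooth`` gives
    an optional centred moving-average window for noisy tracks).  The
    scan never crosses the gene's upstream boundary: a plateau reaching
    it yields a 'clipped' call at the boundary.  If the very first
    upstream base is already at background the TSS falls back to the
    start codon and the call is flagged 'degenerate'.
    """
    if gene.chrom not in coverage:
        raise ValueError(f"{gene.gene_id}: no coverage for chromosome {gene.chrom}")
    if gene.upstream_boundary is None:
        raise ValueError(f"{gene.gene_id}: upstream boundary not computed")
    counts = coverage[gene.chrom].astype(float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        counts = np.convolve(counts, kernel, mode="same")

    anchor = gene.start_codon_5prime
    if gene.strand == "+":
        positions = range(anchor - 1, gene.upstream_boundary - 1, -1)
    else:
        positions = range(anchor + 1, gene.upstream_boundary)

    last_good = None
    clipped = True
    for pos in positions:
        if counts[pos] <= background:
            clipped = False
            break
        last_good = pos
    if last_good is None:
        return TssCall(gene.gene_id, anchor, 0, "degenerate")
    offset = abs(last_good - anchor)
    return TssCall(gene.gene_id, last_good, offset, "clipped" if clipped else "ok")


def call_all_tss(
    annotation: GenomeAnnotation,
    coverage: CoverageTrack,
    background: float | None = None,
    smooth: int = 0,
) -> list[TssCall]:
    """Call and attach a TSS for every gene; returns the calls."""
    if background is None:
        background = estimate_background(coverage, annotation)
    calls = []
    for gene in annotation.genes:
        call = call_tss(gene, coverage, background, smooth=smooth)
        gene.tss = call.tss
        gene.tss_flag = call.flag
        calls.append(call)
    return calls


def estimate_background(
    coverage: CoverageTrack, annotation: GenomeAnnotation, flank: int = 1000
) -> float:
    """Median per-base count over intergenic space.

    Intergenic = outside every gene body and its ``flank`` bp on both
    sides (the flanks absorb UTR coverage around unannotated TSSs).
    Raises if no intergenic base remains, in which case an explicit
    background must be supplied.
    """
    values = []
    for chrom, length in annotation.chromosomes.items():
        mask = np.ones(length, dtype=bool)
        for g in annotation.genes:
            if g.chrom != chrom:
                continue
            mask[max(0, g.cds_start - flank): min(length, g.cds_end + flank)] = False
        if mask.any():
            values.append(coverage[chrom][mask])
    if not values:
        raise ValueError(
            "no intergenic bases outside gene bodies and flanks; "
            "supply an explicit background level"
        )
    return float(np.median(np.concatenate(values)))


def extract_promoters(
    annotation: GenomeAnnotation,
    genome: dict[str, str],
    definition: str = FIXED500,
    length: int = 500,
) -> dict[str, Promoter]:
    """Extract promoter sequences for every gene with a called TSS.

    fixed500 promoters span at most ``length`` bp upstream of the TSS,
    clipped at the upstream boundary; to_next_transcript promoters span
    the whole region from the TSS to the neighbouring transcript.
    Sequences of − strand genes are reverse-complemented so they read
    5'→3' on the gene strand (last base adjacent to the TSS).
    """
    if definition not in (FIXED500, TO_NEXT_TRANSCRIPT):
        raise ValueError(f"unknown promoter definition {definition!r}")
    unset = [g.gene_id for g in annotation.genes if g.tss is None]
    if unset:
        raise ValueError(f"genes without a called TSS: {unset[:5]}")
    promoters = {}
    for g in annotation.genes:
        if g.strand == "+":
            end = g.tss
            start = g.upstream_boundary
            if definition == FIXED500:
                start = max(start, end - length)
            seq = genome[g.chrom][start:end]
        else:
            start = g.tss + 1
            end = g.upstream_boundary
            if definition == FIXED500:
                end = min(end, start + length)
            seq = reverse_complement(genome[g.chrom][start:end])
        promoters[g.gene_id] = Promoter(
            gene_id=g.gene_id,
            chrom=g.chrom,
            start=start,
            end=end,
            strand=g.strand,
            sequence=seq,
            definition=definition,
        )
    return promoters
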