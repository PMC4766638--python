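"""TSS calling from coverage step functions and promoter extraction."""

import numpy as np
import pytest

from nlim import tss_promoter as tp
from nlim.io_formats import CoverageTrack, GeneModel, GenomeAnnotation


def _setup(counts, strand="+", cds=(500, 800), length=1000, boundary=None):
    gene = GeneModel("g", "chr1", strand, *cds)
    annotation = GenomeAnnotation(chromosomes={"chr1": length}, genes=[gene])
    annotation.compute_upstream_boundaries()
    if boundary is not None:
        gene.upstream_boundary = boundary
    track = CoverageTrack(counts={"chr1": np.asarray(counts)})
    return gene, track


class TestCallTss:
    def test_step_function_recovers_offset(self):
        counts = np.ones(1000)
        counts[380:800] = 50  # plateau starts 120 bp upstream of start codon (500)
        gene, track = _setup(counts)
        call = tp.call_tss(gene, track, background=2)
        assert call.offset == 120
        assert call.tss == 380
        assert call.flag == "ok"

    def test_all_background_upstream_is_degenerate_at_start_codon(self):
        counts = np.ones(1000)
        counts[500:800] = 50
        gene, track = _setup(counts)
        call = tp.call_tss(gene, track, background=2)
        assert call.flag == "degenerate"
        assert call.tss == 500
        assert call.offset == 0

    def test_plateau_reaching_boundary_is_clipped(self):
        counts = np.full(1000, 50)
        gene, track = _setup(counts, boundary=450)
        call = tp.call_tss(gene, track, background=2)
        assert call.flag == "clipped"
        assert call.tss == 450

    def test_minus_strand_walks_rightward(self):
        counts = np.ones(1000)
        counts[200:580] = 50  # gene at [200,500), TSS 80 bp right of cds_end-1
        gene, track = _setup(counts, strand="-", cds=(200, 500))
        call = tp.call_tss(gene, track, background=2)
        assert call.tss == 579
        assert call.offset == 80

    def test_single_base_dip_terminates_scan(self):
        counts = np.ones(1000)
        counts[380:800] = 50
        counts[420] = 1  # dip inside the plateau
        gene, track = _setup(counts)
        call = tp.call_tss(gene, track, background=2)
        assert call.tss == 421

    def test_missing_chromosome_coverage_is_an_error(self):
        gene, _ = _setup(np.ones(1000))
        with pytest.raises(ValueError, match="coverage"):
            tp.call_tss(gene, CoverageTrack(counts={"chr2": np.ones(10)}), 2)


class TestBackground:
    def test_constant_intergenic_coverage(self):
        counts = np.full(5000, 3)
        gene = GeneModel("g", "chr1", "+", 1000, 1500)
        annotation = GenomeAnnotation(chromosomes={"chr1": 5000}, genes=[gene])
        assert tp.estimate_background(CoverageTrack(counts={"chr1": counts}), annotation) == 3

    def test_all_zero_track(self):
        annotation = GenomeAnnotation(chromosomes={"chr1": 3000}, genes=[])
        track = CoverageTrack(counts={"chr1": np.zeros(3000)})
        assert tp.estimate_background(track, annotation) == 0

    def test_no_intergenic_space_is_an_error(self):
        gene = GeneModel("g", "chr1", "+", 0, 1000)
        annotation = GenomeAnnotation(chromosomes={"chr1": 1000}, genes=[gene])
        track = CoverageTrack(counts={"chr1": np.ones(1000)})
        with pytest.raises(ValueError, match="background"):
            tp.estimate_background(track, annotation)

    def test_poisson_background_estimated_within_one(self, dataset):
        bg = tp.estimate_background(dataset.coverage, dataset.annotation)
        assert abs(bg - dataset.config.coverage_background) <= 1.0


class TestPromoters:
    GENOME = {"chr1": "".join("ACGT"[(i // 7) % 4] for i in range(2000))}

    def _annotation(self, strand="+", tss=1000, boundary=None):
        cds = (1100, 1400) if strand == "+" else (600, 900)
        gene = GeneModel("g", "chr1", strand, *cds, tss=tss)
        annotation = GenomeAnnotation(chromosomes={"chr1": 2000}, genes=[gene])
        annotation.compute_upstream_boundaries()
        if boundary is not None:
            gene.upstream_boundary = boundary
        return annotation

    def test_plus_strand_fixed500_interval(self):
        annotation = self._annotation()
        prom = tp.extract_promoters(annotation, self.GENOME, tp.FIXED500)["g"]
        assert (prom.start, prom.end) == (500, 1000)
        assert prom.sequence == self.GENOME["chr1"][500:1000]

    def test_minus_strand_sequence_is_reverse_complement(self):
        annotation = self._annotation(strand="-", tss=1000)
        prom = tp.extract_promoters(annotation, self.GENOME, tp.FIXED500)["g"]
        assert (prom.start, prom.end) == (1001, 1501)
        assert prom.sequence == tp.reverse_complement(self.GENOME["chr1"][1001:1501])

    def test_fixed500_clipped_by_neighbour(self):
        annotation = self._annotation(boundary=800)  # neighbour ends 200 bp upstream
        prom = tp.extract_promoters(annotation, self.GENOME, tp.FIXED500)["g"]
        assert len(prom) == 200

    def test_to_next_transcript_reaches_boundary(self):
        annotation = self._annotation(boundary=300)
        prom = tp.extract_promoters(annotation, self.GENOME, tp.TO_NEXT_TRANSCRIPT)["g"]
        assert (prom.start, prom.end) == (300, 1000)

    def test_unset_tss_is_an_error(self):
        annotation = self._annotation(tss=None)
        with pytest.raises(ValueError, match="TSS"):
            tp.extract_promoters(annotation, self.GENOME, tp.FIXED500)

    def test_roundtrip_against_genome_slice(self, dataset):
        for g in dataset.annotation.genes:
            g.tss = dataset.truth["genes"][g.gene_id]["tss"]
        promoters = tp.extract_promoters(dataset.annotation, dataset.genome, tp.FIXED500)
        for gid in list(promoters)[:25]:
            p = promoters[gid]
            raw = dataset.genome[p.chrom][p.start:p.end]
            expected = raw if p.strand == "+" else tp.reverse_complement(raw)
            assert p.sequence == expected
            assert len(p) <= 500


def test_called_tss_recovers_planted_offsets(dataset):
    bg = tp.estimate_background(dataset.coverage, dataset.annotation)
    calls = tp.call_all_tss(dataset.annotation, dataset.coverage, bg)
    errors = np.array(
        [abs(c.tss - dataset.truth["genes"][c.gene_id]["tss"]) for c in calls]
    )
    assert (errors <= 2).mean() >= 0.9
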