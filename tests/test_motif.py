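"""Motif scanning, distances, binned profiles and discriminative enrichment."""

import numpy as np
import pytest

from nlim import enrich, motif
from nlim.tss_promoter import Promoter
from oracles import scan_oracle

RNG = np.random.default_rng(2024)


def _promoter(gene_id, sequence):
    return Promoter(
        gene_id=gene_id, chrom="chr1", start=0, end=len(sequence), strand="+",
        sequence=sequence, definition="to_next_transcript",
    )


class TestScan:
    def test_printed_gata_motif_matches(self):
        assert motif.scan("TTGATAAGCA", "G[AC]TAAGC") == [2]

    def test_palindrome_forward_and_reverse_collapse(self):
        assert motif.scan("AACACGTGAA", "CACGTG") == [2]

    def test_reverse_strand_match_is_reported(self):
        # revcomp of GATAAGC is GCTTATC
        assert motif.scan("AAGCTTATCAA", "GATAAGC") == [2]

    def test_no_occurrence(self):
        assert motif.scan("AAAAAAAAAA", "CACGTG") == []

    def test_sequence_n_matches_nothing(self):
        assert motif.scan("TTGANAAGCA", "G[AC]TAAGC") == []

    def test_invalid_pattern_symbol_is_an_error(self):
        with pytest.raises(ValueError, match="invalid"):
            motif.Motif.parse("GAT?AGC")
        with pytest.raises(ValueError, match="bracket"):
            motif.Motif.parse("GAT[XZ]AGC")
        with pytest.raises(ValueError, match="shorter"):
            motif.Motif.parse("GAT")

    @pytest.mark.parametrize(
        "pattern",
        ["CC[TG]TTAT", "G[AC]TAAGC", "[GA]TGAGTCA", "TGAAAAA", "CACGTG[AC]", "RYSWKM"],
    )
    def test_agrees_with_exhaustive_oracle(self, pattern):
        for _ in range(150):
            seq = "".join(RNG.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=60))
            assert motif.scan(seq, pattern) == scan_oracle(seq, pattern)


class TestNearestUpstream:
    def test_minimum_distance_is_kept(self):
        seq = "T" * 1000
        seq = seq[:300] + "GATAAGC" + seq[307:820] + "GATAAGC" + seq[827:]
        hits = motif.nearest_upstream({"g": _promoter("g", seq)}, "G[AC]TAAGC")
        # occurrences end at 307 and 827; nearest is 1000-827 = 173
        assert hits[0].distance == 173

    def test_match_adjacent_to_tss_has_distance_zero(self):
        seq = "T" * 993 + "GATAAGC"
        hits = motif.nearest_upstream({"g": _promoter("g", seq)}, "G[AC]TAAGC")
        assert hits[0].distance == 0

    def test_gene_without_match_is_omitted(self):
        hits = motif.nearest_upstream({"g": _promoter("g", "T" * 50)}, "G[AC]TAAGC")
        assert hits == []

    def test_truncation_never_shrinks_the_nearest_distance(self):
        seq = "".join(RNG.choice(list("ACGT"), size=1500))
        full = motif.nearest_upstream({"g": _promoter("g", seq)}, "TGAAAAA")
        truncated = motif.nearest_upstream({"g": _promoter("g", seq[500:])}, "TGAAAAA")
        if truncated and full:
            assert truncated[0].distance >= full[0].distance


class TestDistanceProfile:
    def test_bin_mean(self):
        hits = [motif.MotifHit("a", 50, "+"), motif.MotifHit("b", 50, "+")]
        prof = motif.distance_profile(hits, {"a": 1.0, "b": 3.0})
        row = prof[prof.bin_start == 0].iloc[0]
        assert row.mean_fc == 2.0 and row.n == 2

    def test_boundary_distance_falls_in_upper_bin(self):
        prof = motif.distance_profile([motif.MotifHit("a", 100, "+")], {"a": 1.0})
        assert prof[prof.bin_start == 100].iloc[0].n == 1
        assert prof[prof.bin_start == 0].iloc[0].n == 0

    def test_counts_are_conserved(self):
        hits = [motif.MotifHit(f"g{i}", int(d), "+") for i, d in enumerate(RNG.uniform(0, 2000, 300))]
        fc = {f"g{i}": 0.0 for i in range(300)}
        prof = motif.distance_profile(hits, fc)
        in_range = sum(1 for h in hits if h.distance < 1500)
        assert prof["n"].sum() == in_range

    def test_bins_partition_up_to_1500(self):
        prof = motif.distance_profile([], {})
        assert list(prof.bin_start) == list(range(0, 1500, 100))
        assert (prof.bin_end - prof.bin_start == 100).all()


class TestEnrichMotifs:
    def _random_promoters(self, n, length, exclude, rng):
        out = {}
        i = 0
        while len(out) < n:
            seq = "".join(rng.choice(list("ACGT"), size=length))
            if not any(motif.scan(seq, pat) for pat in exclude):
                out[f"p{i}"] = seq
            i += 1
        return out

    def test_planted_word_is_recovered_with_oracle_p(self):
        rng = np.random.default_rng(7)
        bg = self._random_promoters(120, 80, ["GATAAGC"], rng)
        pos = {}
        for i in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            j = rng.integers(0, 73)
            pos[f"q{i}"] = seq[:j] + "GATAAGC" + seq[j + 7:]
        res = motif.enrich_motifs(pos, bg, ks=(7,), generalize=False)
        top = res.iloc[0]
        assert top.pattern in ("GATAAGC", "GCTTATC")
        from oracles import fisher_two_sided_oracle
        k, n = int(top.k_pos), int(top.n_total)
        assert top.p == pytest.approx(fisher_two_sided_oracle(k, 30, n, 150), rel=1e-9)

    def test_bracket_generalisation_beats_both_exact_words(self):
        rng = np.random.default_rng(8)
        bg = self._random_promoters(150, 80, ["GATAAGC", "GCTAAGC"], rng)
        pos = {}
        for i in range(40):
            word = "GATAAGC" if i % 2 == 0 else "GCTAAGC"
            seq = "".join(rng.choice(list("ACGT"), size=80))
            pos[f"q{i}"] = seq[:40] + word + seq[47:]
        res = motif.enrich_motifs(pos, bg, ks=(7,))
        patterns = list(res["pattern"])
        bracket = [p for p in patterns if "[" in p]
        assert bracket, "no generalised pattern returned"
        best_bracket = res[res.pattern.isin(bracket)].iloc[0]
        exact = res[res.pattern.isin(["GATAAGC", "GCTAAGC", "GCTTATC", "GCTTAGC"])]
        if not exact.empty:
            assert best_bracket.p < exact["p"].min()

    def test_shuffled_labels_yield_no_corrected_hit(self, dataset):
        rng = np.random.default_rng(9)
        seqs = ["".join(rng.choice(list("ACGT"), size=120)) for _ in range(60)]
        promoters = {f"p{i}": s for i, s in enumerate(seqs)}
        enricher = motif.MotifEnricher(promoters, ks=(6,))
        positives = set(rng.choice(sorted(promoters), size=15, replace=False))
        res = enricher.test(positives, generalize=False, max_results=10**9)
        q = enrich.bh_fdr(res["p"].to_numpy())
        assert q.min() > 0.05

    def test_empty_positive_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            motif.enrich_motifs({}, {"p1": "ACGTACGT"}, ks=(6,))


class TestMotifGo:
    def _go(self):
        import pandas as pd
        return pd.DataFrame(
            [{"gene": f"g{i}", "term": "T" if i < 20 else "U"} for i in range(100)]
        )

    def test_no_gene_within_half_kb_gives_empty_result(self):
        hits = [motif.MotifHit("g1", 900, "+")]
        res = motif.motif_go(hits, self._go(), {f"g{i}" for i in range(100)})
        assert res.empty

    def test_study_equal_population_finds_nothing(self):
        hits = [motif.MotifHit(f"g{i}", 10, "+") for i in range(100)]
        res = motif.motif_go(hits, self._go(), {f"g{i}" for i in range(100)})
        assert res.empty

    def test_planted_coupling_is_detected(self):
        population = {f"g{i}" for i in range(200)}
        hits = [motif.MotifHit(f"g{i}", 100, "+") for i in range(30)]
        import pandas as pd
        go = pd.DataFrame(
            [{"gene": f"g{i}", "term": "coupled"} for i in range(28)]
            + [{"gene": f"g{i}", "term": "noise"} for i in range(0, 200, 3)]
        )
        res = motif.motif_go(hits, go, population)
        assert "coupled" in set(res["term"])
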