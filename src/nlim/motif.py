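"""Degenerate DNA motif scanning and promoter-position analysis.

Motifs are short patterns over IUPAC one-letter codes, optionally with
explicit bracket classes as conventionally printed (e.g. ``G[AC]TAAGC``,
``CACGTG[AC]``).  Scanning covers both strands: a pattern matches a
position if the forward sequence or its reverse complement matches there.
``N`` in a *sequence* matches nothing.

Distances are measured from the TSS to the match edge nearest the TSS.
Promoter sequences read 5'→3' on the gene strand with the last base
adjacent to the TSS (see tss_promoter), so a match ending at the last
base has distance 0.  Distance profiles bin genes in half-open 0.1 kb
windows up to 1.5 kb and summarise the protein log2 fold change per bin.

Motif discovery proper (DREME-style) is replaced by a transparent
discriminative scan: every exact word of length k in the positive
promoters is Fisher-tested for presence against a background promoter
set, and the best words are generalised by single-position two-letter
bracket classes when that improves the p-value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .tss_promoter import Promoter, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGT", "TGCA")

BIN_WIDTH = 100
MAX_PROFILE_DISTANCE = 1500


@dataclass(frozen=True)
class Motif:
    """A degenerate pattern compiled to per-position nucleotide sets."""

    pattern: str
    symbols: tuple[frozenset, ...]

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def parse(cls, pattern: str) -> "Motif":
        symbols = []
        i = 0
        while i < len(pattern):
            ch = pattern[i]
            if ch == "[":
                j = pattern.find("]", i)
                if j < 0:
                    raise ValueError(f"unterminated bracket class in {pattern!r}")
                letters = pattern[i + 1: j]
                if not letters or any(c not in "ACGT" for c in letters):
                    raise ValueError(f"invalid bracket class [{letters}] in {pattern!r}")
                symbols.append(frozenset(letters))
                i = j + 1
            elif ch in IUPAC:
                symbols.append(frozenset(IUPAC[ch]))
                i += 1
            else:
                raise ValueError(f"invalid motif symbol {ch!r} in {pattern!r}")
        if len(symbols) < 4:
            raise ValueError(f"motif {pattern!r} shorter than 4 positions")
        return cls(pattern=pattern, symbols=tuple(symbols))

    def reverse_complement(self) -> "Motif":
        rc = tuple(
            frozenset(c.translate(_COMP) for c in s) for s in reversed(self.symbols)
        )
        return Motif(pattern=f"revcomp({self.pattern})", symbols=rc)


def _match_positions(seq: str, symbols: tuple[frozenset, ...]) -> list[int]:
    m = len(symbols)
    out = []
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in symbols[j] for j in range(m)):
            out.append(i)
    return out


def scan(sequence: str, motif: Motif | str) -> list[int]:
    """All 0-based positions where the motif matches on either strand.

    A reverse-strand match is reported at its position on the forward
    sequence; a position matching on both strands is reported once.
    Overlapping matches are all reported.
    """
    if isinstance(motif, str):
        motif = Motif.parse(motif)
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN symbols {sorted(bad)}")
    fwd = _match_positions(sequence, motif.symbols)
    rev = _match_positions(sequence, motif.reverse_complement().symbols)
    return sorted(set(fwd) | set(rev))


@dataclass
class MotifHit:
    gene_id: str
    distance: int
    strand: str


def nearest_upstream(
    promoters: dict[str, Promoter], motif: Motif | str
) -> list[MotifHit]:
    """Nearest motif occurrence upstream of the TSS, per gene.

    Distance is from the TSS to the match edge closest to it; genes with
    no occurrence anywhere in the promoter are omitted.
    """
    if isinstance(motif, str):
        motif = Motif.parse(motif)
    m = len(motif)
    rc = motif.reverse_complement().symbols
    hits = []
    for gene_id in sorted(promoters):
        p = promoters[gene_id]
        seq = p.sequence
        fwd = _match_positions(seq, motif.symbols)
        rev = _match_positions(seq, rc)
        if not fwd and not rev:
            continue
        best = max(itertools.chain(fwd, rev))
        strand = "+" if best in fwd else "-"
        hits.append(MotifHit(gene_id=gene_id, distance=len(seq) - (best + m), strand=strand))
    return hits


def distance_profile(
    hits: list[MotifHit],
    fold_changes: dict[str, float],
    bin_width: int = BIN_WIDTH,
    max_distance: int = MAX_PROFILE_DISTANCE,
) -> pd.DataFrame:
    """Binned mean fold change by motif-TSS distance.

    Bins are half-open ``[0,100), [100,200), …`` up to ``max_distance``.
    Genes beyond the last bin or without a fold-change value are
    excluded; empty bins carry NaN summaries and n = 0.
    """
    edges = np.arange(0, max_distance + bin_width, bin_width)
    per_bin: dict[int, list[float]] = {int(e): [] for e in edges[:-1]}
    for hit in hits:
        if hit.distance >= max_distance or hit.gene_id not in fold_changes:
            continue
        fc = fold_changes[hit.gene_id]
        if fc != fc:
            continue
        start = int(hit.distance // bin_width) * bin_width
        per_bin[start].append(fc)
    rows = []
    for start in sorted(per_bin):
        values = np.array(per_bin[start])
        if len(values):
            q1, q3 = np.percentile(values, [25, 75])
            rows.append((start, start + bin_width, len(values), values.mean(), q1, q3))
        else:
            rows.append((start, start + bin_width, 0, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "n", "mean_fc", "q1", "q3"])


# ---------------------------------------------------------------------------
# Discriminative enrichment (motif discovery stand-in)

_TWO_LETTER = [frozenset(c) for c in itertools.combinations("ACGT", 2)]


def _index_words(sequences: list[str], ks: tuple[int, ...]) -> dict[str, set[int]]:
    """word → set of sequence indices containing it on either strand."""
    index: dict[str, set[int]] = {}
    for i, seq in enumerate(sequences):
        both = (seq, reverse_complement(seq))
        for k in ks:
            for s in both:
                for j in range(len(s) - k + 1):
                    w = s[j: j + k]
                    if "N" in w:
                        continue
                    index.setdefault(w, set()).add(i)
    return index


def _bracket_pattern(word: str, pos: int, letters: frozenset) -> str:
    cls = "[" + "".join(sorted(letters)) + "]"
    return word[:pos] + cls + word[pos + 1:]


class MotifEnricher:
    """Word-presence index over a promoter collection, reusable across
    label assignments (e.g. for label-shuffle null calibration)."""

    def __init__(self, promoters: dict[str, str], ks: tuple[int, ...] = (6, 7, 8)):
        self.ids = sorted(promoters)
        self.ks = ks
        self._index = _index_words([promoters[i] for i in self.ids], ks)
        self.words = sorted(self._index)
        n = len(self.ids)
        self._presence = np.zeros((len(self.words), n), dtype=bool)
        for r, w in enumerate(self.words):
            self._presence[r, list(self._index[w])] = True
        self._row = {w: r for r, w in enumerate(self.words)}

    def test(
        self,
        positive_ids: set[str],
        generalize: bool = True,
        n_generalize: int = 50,
        max_results: int = 100,
    ) -> pd.DataFrame:
        """Rank candidate motifs by two-sided Fisher p (positives vs rest).

        Exact words are tested first; the ``n_generalize`` best are then
        expanded with single-position two-letter bracket classes, kept
        when the generalisation improves p.  The E-value multiplies each
        p by the total number of candidates examined.
        """
        positive_ids = set(positive_ids)
        if not positive_ids:
            raise ValueError("positive promoter set is empty")
        unknown = positive_ids - set(self.ids)
        if unknown:
            raise ValueError(f"unknown promoter ids {sorted(unknown)[:5]}")
        pos_mask = np.array([i in positive_ids for i in self.ids])
        K, N = int(pos_mask.sum()), len(self.ids)
        k = self._presence @ pos_mask.astype(np.int64)
        n = self._presence.sum(axis=1)
        p = stats.fisher_exact_two_sided(k, n, K, N)
        n_tested = len(self.words)

        order = np.argsort(p, kind="stable")
        results = {
            self.words[r]: (self.words[r], int(k[r]), int(n[r]), float(p[r]))
            for r in order[:max_results]
        }
        if generalize:
            for r in order[:n_generalize]:
                word = self.words[r]
                best = results[word]
                for pos in range(len(word)):
                    for letters in _TWO_LETTER:
                        if word[pos] not in letters:
                            continue
                        rows = [
                            self._row[word[:pos] + c + word[pos + 1:]]
                            for c in letters
                            if word[:pos] + c + word[pos + 1:] in self._row
                        ]
                        vec = np.any(self._presence[rows], axis=0)
                        kk = int(vec[pos_mask].sum())
                        nn = int(vec.sum())
                        pp = float(stats.fisher_exact_two_sided(kk, nn, K, N))
                        n_tested += 1
                        if pp < best[3]:
                            best = (_bracket_pattern(word, pos, letters), kk, nn, pp)
                if best[0] != word:
                    results[word] = best
        deduped: dict[str, tuple] = {}
        for row in results.values():
            if row[0] not in deduped or row[3] < deduped[row[0]][3]:
                deduped[row[0]] = row
        rows = sorted(deduped.values(), key=lambda t: (t[3], t[0]))
        df = pd.DataFrame(rows, columns=["pattern", "k_pos", "n_total", "p"])
        df["n_pos"] = K
        df["n_promoters"] = N
        df["evalue"] = df["p"] * n_tested
        return df.reset_index(drop=True)


def enrich_motifs(
    positive: dict[str, str],
    background: dict[str, str],
    ks: tuple[int, ...] = (6, 7, 8),
    generalize: bool = True,
) -> pd.DataFrame:
    """Discriminative motif enrichment of positive vs background promoters.

    ``positive`` and ``background`` map promoter ids to sequences; the
    Fisher background is the union, so the test compares presence in the
    positive set against the rest.
    """
    overlap = set(positive) & set(background)
    if overlap:
        raise ValueError(f"promoters in both sets: {sorted(overlap)[:5]}")
    merged = {**positive, **background}
    enricher = MotifEnricher(merged, ks=ks)
    return enricher.test(set(positive), generalize=generalize)


def motif_go(
    hits: list[MotifHit],
    go_table: pd.DataFrame,
    population: set[str],
    max_distance: int = 500,
    p_threshold: float = 0.005,
) -> pd.DataFrame:
    """GO enrichment of genes with a motif within ``max_distance`` of the TSS.

    Delegates to the enrichment module with study = genes whose nearest
    occurrence is at most 0.5 kb upstream; only terms with p below the
    reporting threshold are returned.
    """
    from .enrich import go_enrichment

    study = {h.gene_id for h in hits if h.distance <= max_distance} & set(population)
    if not study:
        return pd.DataFrame(
            columns=["term", "study_k", "study_n", "pop_k", "pop_n", "p", "fdr", "direction"]
        )
    result = go_enrichment(study, set(population), go_table)
    return result[result["p"] < p_threshold].reset_index(drop=True)
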