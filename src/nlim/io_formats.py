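"""Readers and writers for every external format the pipeline touches.

Coordinate conventions
----------------------
Internally everything is 0-based half-open.  On disk, GFF3 is 1-based
inclusive and bedGraph is 0-based half-open (the standard dialects); this
module is the single conversion point.

The peptide report is a fixed-column TSV defined here (the upstream
instrument pipelines do not share a machine-readable layout):

    sequence  proteins  phospho_sites  source  <sample columns...>

``proteins`` is a ``;``-separated, *ordered* list — quantitative roll-up
uses only the first entry.  ``phospho_sites`` uses ``S123;T130`` notation
(residue letter + 1-based position in the protein), empty for unmodified
peptides.  ``source`` is ``global`` or ``imac``.  Sample columns are named
``r<replicate>_<channel>`` (e.g. ``r1_114`` for iTRAQ reporter 114 of
biological replicate 1) and hold non-negative reporter-ion intensities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PHOSPHO_RESIDUES = frozenset("STY")
_SITE_RE = re.compile(r"^([A-Z])(\d+)$")
_SAMPLE_RE = re.compile(r"^r(\d+)_(\w+)$")

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "CoverageTrack",
    "PeptideRecord",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "read_bedgraph",
    "write_bedgraph",
    "read_peptide_table",
    "write_peptide_table",
    "read_design",
    "write_design",
    "read_metabolite_table",
    "write_metabolite_table",
    "read_go_table",
    "read_class_table",
]


@dataclass
class GeneModel:
    """A single-transcript gene model with optional TSS annotation.

    ``cds_start``/``cds_end`` are 0-based half-open genomic coordinates.
    ``start_codon_pos`` is the leftmost base of the start codon
    (``cds_start`` on +, ``cds_end - 3`` on −).  ``tss`` and
    ``upstream_boundary`` are genomic base positions; the upstream boundary
    is the edge of the nearest neighbouring transcript on the gene's
    5' side (chromosome start/end when there is no neighbour).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    tss: int | None = None
    tss_flag: str | None = None
    upstream_boundary: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.cds_start < self.cds_end:
            raise ValueError(f"{self.gene_id}: cds_start must be < cds_end")

    @property
    def start_codon_pos(self) -> int:
        return self.cds_start if self.strand == "+" else self.cds_end - 3

    @property
    def start_codon_5prime(self) -> int:
        """Genomic position of the 5'-most base of the start codon."""
        return self.cds_start if self.strand == "+" else self.cds_end - 1

    def tss_offset(self) -> int | None:
        """Distance (bp) from start codon to TSS in transcript orientation."""
        if self.tss is None:
            return None
        if self.strand == "+":
            return self.start_codon_5prime - self.tss
        return self.tss - self.start_codon_5prime


@dataclass
class GenomeAnnotation:
    chromosomes: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()
        self._by_id = {g.gene_id: g for g in self.genes}

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom not in self.chromosomes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.cds_start < 0 or g.cds_end > self.chromosomes[g.chrom]:
                raise ValueError(f"{g.gene_id}: outside chromosome bounds")
        for chrom in self.chromosomes:
            ordered = sorted(
                (g for g in self.genes if g.chrom == chrom),
                key=lambda g: g.cds_start,
            )
            for a, b in zip(ordered, ordered[1:]):
                if b.cds_start < a.cds_end:
                    raise ValueError(
                        f"overlapping gene models {a.gene_id} and {b.gene_id}"
                    )

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def compute_upstream_boundaries(self) -> None:
        """Set each gene's upstream boundary from its 5'-side neighbour.

        For a + strand gene this is the end of the closest transcript to its
        left (0 at the chromosome start); for a − strand gene the start of
        the closest transcript to its right (chromosome length at the end).
        """
        for chrom, length in self.chromosomes.items():
            ordered = sorted(
                (g for g in self.genes if g.chrom == chrom),
                key=lambda g: g.cds_start,
            )
            for i, g in enumerate(ordered):
                if g.strand == "+":
                    g.upstream_boundary = ordered[i - 1].cds_end if i > 0 else 0
                else:
                    g.upstream_boundary = (
                        ordered[i + 1].cds_start if i + 1 < len(ordered) else length
                    )


@dataclass
class CoverageTrack:
    """Dense per-base read counts, one vector per chromosome."""

    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, vec in self.counts.items():
            vec = np.asarray(vec)
            if vec.ndim != 1:
                raise ValueError(f"{chrom}: coverage must be 1-D")
            if np.any(vec < 0):
                raise ValueError(f"{chrom}: negative coverage")
            self.counts[chrom] = vec.astype(np.int64)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.counts[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.counts


@dataclass
class PeptideRecord:
    """One quantified peptide row.

    ``intensities`` maps sample id (``r<rep>_<channel>``) to a non-negative
    reporter-ion intensity.  ``protein_ids`` preserves the report order:
    the first entry is the protein used for quantitative roll-up.
    """

    sequence: str
    protein_ids: list[str]
    phospho_sites: list[tuple[str, int]]
    intensities: dict[str, float]
    source: str

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValueError(f"peptide {self.sequence}: no protein mapping")
        if self.source not in ("global", "imac"):
            raise ValueError(f"peptide {self.sequence}: bad source {self.source!r}")
        for res, pos in self.phospho_sites:
            if res not in PHOSPHO_RESIDUES:
                raise ValueError(
                    f"peptide {self.sequence}: phospho residue {res!r} is not S/T/Y"
                )
            if pos < 1:
                raise ValueError(f"peptide {self.sequence}: site position must be >=1")
        for sample, value in self.intensities.items():
            if value < 0:
                raise ValueError(f"peptide {self.sequence}: negative intensity in {sample}")

    @property
    def is_phosphopeptide(self) -> bool:
        return len(self.phospho_sites) > 0

    @property
    def first_protein(self) -> str:
        return self.protein_ids[0]

    def total_intensity(self) -> float:
        return float(sum(self.intensities.values()))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def read_gff(path) -> GenomeAnnotation:
    """Read gene models from GFF3 and compute upstream boundaries.

    Chromosome lengths come from ``##sequence-region`` directives.
    GFF 1-based inclusive coordinates are converted to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    chromosomes: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) == 4:
            chromosomes[parts[1]] = int(parts[3])
    genes = []
    for feat in db.features_of_type("gene"):
        if feat.seqid not in chromosomes:
            raise ValueError(f"{feat.id}: unknown chromosome {feat.seqid}")
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                strand=feat.strand,
                cds_start=feat.start - 1,
                cds_end=feat.end,
            )
        )
    annotation = GenomeAnnotation(chromosomes=chromosomes, genes=genes)
    annotation.compute_upstream_boundaries()
    return annotation


def write_gff(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.chromosomes.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.cds_start)):
            fh.write(
                f"{g.chrom}\tnlim\tgene\t{g.cds_start + 1}\t{g.cds_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path, annotation: GenomeAnnotation) -> CoverageTrack:
    """Densify a bedGraph into per-base counts; uncovered bases are 0.

    Overlapping intervals are rejected (malformed input), and intervals
    must lie within the annotated chromosome lengths.
    """
    counts = {
        chrom: np.zeros(length, dtype=np.int64)
        for chrom, length in annotation.chromosomes.items()
    }
    covered = {
        chrom: np.zeros(length, dtype=bool)
        for chrom, length in annotation.chromosomes.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            start, end = int(start), int(end)
            if chrom not in counts:
                raise ValueError(f"line {lineno}: unknown chromosome {chrom}")
            if end > len(counts[chrom]) or start < 0 or start >= end:
                raise ValueError(f"line {lineno}: interval outside chromosome")
            if covered[chrom][start:end].any():
                raise ValueError(f"line {lineno}: overlapping bedGraph intervals")
            covered[chrom][start:end] = True
            counts[chrom][start:end] = int(float(value))
    return CoverageTrack(counts=counts)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write run-length-merged bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.counts):
            vec = track.counts[chrom]
            if len(vec) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# Peptide report

def _parse_sites(text: str) -> list[tuple[str, int]]:
    if not text or text != text:  # empty or NaN
        return []
    sites = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        m = _SITE_RE.match(token)
        if not m:
            raise ValueError(f"malformed phosphosite token {token!r}")
        res, pos = m.group(1), int(m.group(2))
        if res not in PHOSPHO_RESIDUES:
            raise ValueError(f"phospho residue {res!r} is not S/T/Y")
        sites.append((res, pos))
    return sites


def _format_sites(sites) -> str:
    return ";".join(f"{res}{pos}" for res, pos in sites)


def read_peptide_table(path) -> list[PeptideRecord]:
    df = pd.read_csv(
        path, sep="\t", dtype={"phospho_sites": str}, keep_default_na=False,
        float_precision="round_trip",
    )
    fixed = ["sequence", "proteins", "phospho_sites", "source"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in fixed]
    for c in sample_cols:
        if not _SAMPLE_RE.match(c):
            raise ValueError(f"unrecognised peptide table column {c!r}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        intensities = {c: float(d[c]) for c in sample_cols}
        records.append(
            PeptideRecord(
                sequence=d["sequence"],
                protein_ids=[p for p in str(d["proteins"]).split(";") if p],
                phospho_sites=_parse_sites(d["phospho_sites"]),
                intensities=intensities,
                source=d["source"],
            )
        )
    return records


def write_peptide_table(peptides: list[PeptideRecord], path) -> None:
    if not peptides:
        raise ValueError("no peptides to write")
    sample_cols = sorted(
        {s for p in peptides for s in p.intensities},
        key=lambda s: tuple(_SAMPLE_RE.match(s).groups()),
    )
    rows = []
    for p in peptides:
        row = {
            "sequence": p.sequence,
            "proteins": ";".join(p.protein_ids),
            "phospho_sites": _format_sites(p.phospho_sites),
            "source": p.source,
        }
        row.update({c: repr(float(p.intensities.get(c, 0.0))) for c in sample_cols})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Design, metabolites, annotation tables

def read_design(path) -> pd.DataFrame:
    """Sample design: columns sample, replicate, channel, condition."""
    df = pd.read_csv(path, sep="\t", dtype={"channel": str})
    required = {"sample", "replicate", "channel", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table must have columns {sorted(required)}")
    bad = set(df["condition"]) - {"highN", "lowN"}
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_metabolite_table(path) -> pd.DataFrame:
    """Long-format metabolite table.

    Columns: metabolite, compartment (intracellular/extracellular),
    condition (CN10/CN150), timepoint (1h/9h), replicate, value,
    dry_weight (mg; empty for extracellular rows), pooled (0/1).
    """
    df = pd.read_csv(path, sep="\t")
    required = {
        "metabolite", "compartment", "condition", "timepoint",
        "replicate", "value", "dry_weight",
    }
    if not required.issubset(df.columns):
        raise ValueError(f"metabolite table must have columns {sorted(required)}")
    if (df["value"] < 0).any():
        raise ValueError("negative metabolite values")
    return df


def write_metabolite_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_go_table(path) -> pd.DataFrame:
    """Two-column gene → GO term annotation (one row per pair)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "term"}.issubset(df.columns):
        raise ValueError("GO table must have columns gene, term")
    return df


def read_class_table(path) -> dict[str, str]:
    """Regulatory class per protein (kinase/phosphatase/dna_binding/other)."""
    df = pd.read_csv(path, sep="\t")
    if not {"protein", "class"}.issubset(df.columns):
        raise ValueError("class table must have columns protein, class")
    allowed = {"kinase", "phosphatase", "dna_binding", "other"}
    bad = set(df["class"]) - allowed
    if bad:
        raise ValueError(f"unknown regulatory classes {sorted(bad)}")
    return dict(zip(df["protein"], df["class"]))
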