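"""Synthetic multi-omics benchmark generator with persisted ground truth.

Generates every input the pipeline consumes — genome FASTA, gene models,
RNA-seq coverage, iTRAQ peptide reports (global and IMAC-enriched),
metabolite tables, GO and regulatory-class annotations — from explicit
generative models whose parameters are recorded in a truth table, so
every stage can be tested for parameter recovery without external data.

Generative models
-----------------
* Protein abundance: log-normal base level per protein; the nitrogen-
  limited condition multiplies it by 2**delta (delta = 0 for null
  proteins, symmetric ± effects otherwise).
* Peptide intensity: protein abundance × a fixed per-peptide ionisation
  factor (log-normal) × per-channel multiplicative noise (log-normal,
  sigma in log2 units) — the minimal model under which "sum, log2,
  centre" is a sensible estimator.
* Phosphopeptide intensity: protein abundance × phosphorylation
  occupancy, with occupancy ratio 2**phi across conditions and phi drawn
  independently of delta, so log-space subtraction of the protein change
  is exactly unbiased for phi.
* Coverage: a plateau of fixed depth over [TSS, gene 3' end] plus
  Poisson(lambda) noise at every base; the TSS lies a planted offset
  u ~ U[20, 800] bp upstream of the start codon.
* Promoters receive planted degenerate motifs whose signed expression
  effect decays exponentially with the distance to the TSS.

Running with the same seed reproduces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CoverageTrack,
    GeneModel,
    GenomeAnnotation,
    PeptideRecord,
    write_bedgraph,
    write_design,
    write_fasta,
    write_gff,
    write_metabolite_table,
    write_peptide_table,
)
from .motif import Motif
from .tss_promoter import reverse_complement

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CHANNELS = ("114", "115", "116", "117")
CHANNEL_CONDITION = {"114": "highN", "115": "highN", "116": "lowN", "117": "lowN"}

INTRACELLULAR_NAMES = [
    "citrate", "fumarate", "malate", "succinate", "2-oxoglutarate",
    "alanine", "putrescine", "spermidine", "urea", "mannitol",
    "erythritol", "glycerol", "trehalose", "glucose", "glucose-6-phosphate",
    "glutamate", "glutamine", "aspartate", "proline", "serine",
    "glycine", "lysine", "arginine+ornithine", "leucine", "valine",
]
EXTRACELLULAR_NAMES = ["glucose_ext", "glycerol_ext", "citrate_ext", "mannitol_ext"]

GO_TERMS = [
    "amino-acid biosynthesis", "proteolysis", "translation",
    "ribosome biogenesis", "fatty-acid beta-oxidation",
    "transcription regulation", "lipid storage", "TCA cycle",
    "polyamine metabolism", "nitrogen utilisation",
]


@dataclass(frozen=True)
class MotifPlan:
    """One planted promoter motif and its distance-dependent effect."""

    pattern: str
    n_genes: int = 60
    distance_mean: float = 150.0
    distance_sd: float = 30.0
    beta: float = 2.0       # signed log2 effect at distance 0
    decay: float = 300.0    # e-folding distance, bp


DEFAULT_MOTIFS = (
    MotifPlan("G[AC]TAAGC", 60, 150.0, 30.0, 2.0, 300.0),
    MotifPlan("CACGTG[AC]", 60, 250.0, 60.0, -2.0, 300.0),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults emulate the study design: two conditions
    (C/N = 10 replete vs C/N = 150 limited), three biological replicates,
    4-plex isobaric labelling (two reporter channels per condition per
    replicate), triplicate metabolite measurements with dry weights.
    """

    n_genes: int = 300
    n_replicates: int = 3
    channel_noise_sigma: float = 0.2      # log2 units
    ionization_sigma: float = 1.5         # log2 units
    base_abundance_log2: float = 16.0
    base_abundance_sigma: float = 1.5
    peptides_per_protein_mean: float = 3.0
    null_fraction: float = 0.7
    effect_min: float = 1.0
    effect_max: float = 2.5
    # genome / coverage
    gene_codons_min: int = 100
    gene_codons_max: int = 300
    gap_min: int = 1700
    gap_max: int = 2600
    long_gap_fraction: float = 0.25
    long_gap_min: int = 2600
    long_gap_max: int = 3600
    tss_offset_min: int = 20
    tss_offset_max: int = 800
    coverage_depth: int = 50
    coverage_background: float = 2.0      # Poisson lambda
    # phosphoproteome
    phospho_base_occupancy: float = 0.25
    phospho_null_fraction: float = 0.5
    phospho_effect_min: float = 1.0
    phospho_effect_max: float = 2.0
    phosphopeptides_mean: float = 1.8
    imac_contaminant_ratio: float = 882.0 / 1219.0   # contaminants per phosphopeptide
    class_sizes: tuple = (("kinase", 20), ("phosphatase", 12), ("dna_binding", 40))
    class_phospho_prob: tuple = (
        ("kinase", 0.75), ("phosphatase", 0.25), ("dna_binding", 0.45), ("other", 0.25)
    )
    # metabolome
    n_metabolites: int = 40
    n_extracellular: int = 10
    metabolite_null_fraction: float = 0.6
    metabolite_effect_min: float = 1.0
    metabolite_effect_max: float = 3.0
    metabolite_noise_sigma: float = 0.25  # log2 units
    dry_weight_mean: float = 10.0         # mg
    dry_weight_sigma: float = 0.7
    # motifs
    motifs: tuple = DEFAULT_MOTIFS


@dataclass
class SyntheticDataset:
    config: SimConfig
    seed: int
    annotation: GenomeAnnotation
    genome: dict[str, str]
    coverage: CoverageTrack
    peptides: list[PeptideRecord]
    design: pd.DataFrame
    metabolites: pd.DataFrame
    go: pd.DataFrame
    classes: dict[str, str]
    truth: dict


def sample_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for rep in range(1, config.n_replicates + 1):
        for ch in CHANNELS:
            rows.append(
                {
                    "sample": f"r{rep}_{ch}",
                    "replicate": rep,
                    "channel": ch,
                    "condition": CHANNEL_CONDITION[ch],
                }
            )
    return pd.DataFrame(rows)


def _sample_ids(config: SimConfig) -> tuple[list[str], np.ndarray]:
    design = sample_design(config)
    samples = list(design["sample"])
    is_low = (design["condition"] == "lowN").to_numpy()
    return samples, is_low


def simulate_intensity_rows(
    base_log2: np.ndarray,
    delta: np.ndarray,
    is_low: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reporter intensities for rows with per-row base level and effect.

    Returns a (rows × samples) array of 2**(base + delta·lowN + noise);
    the per-peptide ionisation factor is expected to be folded into
    ``base_log2`` by the caller.
    """
    n_rows = len(base_log2)
    noise = rng.normal(0.0, config.channel_noise_sigma, size=(n_rows, len(is_low)))
    log2_i = base_log2[:, None] + np.outer(delta, is_low.astype(float)) + noise
    return np.exp2(log2_i)


def simulate_protein_matrix(
    deltas: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Vectorised peptide-level simulation rolled up to a raw protein matrix.

    Uses the same intensity model as the file-level generator but skips
    record materialisation, so calibration runs with tens of thousands of
    proteins stay fast.  Row index is p0001, p0002, …
    """
    deltas = np.asarray(deltas, dtype=float)
    n = len(deltas)
    samples, is_low = _sample_ids(config)
    base = rng.normal(config.base_abundance_log2, config.base_abundance_sigma, n)
    pep_counts = 1 + rng.poisson(config.peptides_per_protein_mean - 1.0, n)
    protein_idx = np.repeat(np.arange(n), pep_counts)
    ions = rng.normal(0.0, config.ionization_sigma, len(protein_idx))
    rows = simulate_intensity_rows(
        base[protein_idx] + ions, deltas[protein_idx], is_low, config, rng
    )
    raw = np.zeros((n, len(samples)))
    np.add.at(raw, protein_idx, rows)
    ids = [f"p{i + 1:05d}" for i in range(n)]
    return pd.DataFrame(raw, index=ids, columns=samples)


def simulate_phospho_pair(
    deltas: np.ndarray,
    phis: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One phosphopeptide per protein plus a matching global protein matrix.

    The phosphopeptide of protein i carries occupancy effect ``phis[i]``
    on top of the protein effect ``deltas[i]``; keys are
    p00001|PEPi|S1-style so they feed straight into fractional_change.
    """
    deltas = np.asarray(deltas, dtype=float)
    phis = np.asarray(phis, dtype=float)
    prot_raw = simulate_protein_matrix(deltas, config, rng)
    samples, is_low = _sample_ids(config)
    n = len(deltas)
    base = rng.normal(config.base_abundance_log2, config.base_abundance_sigma, n)
    ions = rng.normal(0.0, config.ionization_sigma, n)
    rows = simulate_intensity_rows(
        base + ions + np.log2(config.phospho_base_occupancy),
        deltas + phis,
        is_low,
        config,
        rng,
    )
    keys = [f"{pid}|PEP{i}|S1" for i, pid in enumerate(prot_raw.index)]
    phos_raw = pd.DataFrame(rows, index=keys, columns=samples)
    return phos_raw, prot_raw


# ---------------------------------------------------------------------------
# Genome and coverage

def _sample_gene_layout(config: SimConfig, rng: np.random.Generator):
    n = config.n_genes
    lengths = 3 * rng.integers(config.gene_codons_min, config.gene_codons_max + 1, n)
    gaps = rng.integers(config.gap_min, config.gap_max + 1, n + 1)
    long_mask = rng.random(n + 1) < config.long_gap_fraction
    long_gaps = rng.integers(config.long_gap_min, config.long_gap_max + 1, n + 1)
    gaps = np.where(long_mask, long_gaps, gaps)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    starts = np.zeros(n, dtype=int)
    pos = 0
    for i in range(n):
        pos += gaps[i]
        starts[i] = pos
        pos += lengths[i]
    chrom_len = pos + gaps[n]
    return lengths, strands, starts, chrom_len


def _plant_motifs(config, rng, genes, tss, truth_motifs, stamped):
    """Pick disjoint gene sets per motif plan, sample distances, record
    genomic stamp coordinates.  Returns delta overrides {gene_idx: delta}."""
    available = list(range(len(genes)))
    overrides = {}
    for plan in config.motifs:
        motif = Motif.parse(plan.pattern)
        m = len(motif)
        if plan.n_genes > len(available):
            raise ValueError("not enough genes to plant all motifs")
        chosen_pos = rng.choice(len(available), size=plan.n_genes, replace=False)
        chosen = sorted(available[i] for i in chosen_pos)
        available = [g for g in available if g not in set(chosen)]
        plan_truth = {"pattern": plan.pattern, "beta": plan.beta,
                      "decay": plan.decay, "genes": {}}
        for gi in chosen:
            g = genes[gi]
            avail_len = (
                tss[gi] - g.upstream_boundary
                if g.strand == "+"
                else g.upstream_boundary - tss[gi] - 1
            )
            d = rng.normal(plan.distance_mean, plan.distance_sd)
            d = int(np.clip(d, 5, avail_len - m - 5))
            word = "".join(
                sorted(sym)[rng.integers(len(sym))] for sym in motif.symbols
            )
            if g.strand == "+":
                pos0 = tss[gi] - d - m
                stamped.append((pos0, word))
            else:
                pos0 = tss[gi] + 1 + d
                stamped.append((pos0, reverse_complement(word)))
            plan_truth["genes"][g.gene_id] = {
                "distance": d,
                "effect": plan.beta * float(np.exp(-d / plan.decay)),
            }
            overrides[gi] = plan_truth["genes"][g.gene_id]["effect"]
        truth_motifs.append(plan_truth)
    return overrides


def _make_genome(chrom_len, stamped, rng) -> str:
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = lookup[rng.integers(0, 4, chrom_len)]
    for pos, word in stamped:
        arr[pos: pos + len(word)] = np.frombuffer(word.encode(), dtype=np.uint8)
    return arr.tobytes().decode()


def _make_coverage(config, rng, genes, tss, chrom_len) -> np.ndarray:
    cov = rng.poisson(config.coverage_background, chrom_len)
    for gi, g in enumerate(genes):
        if g.strand == "+":
            cov[tss[gi]: g.cds_end] += config.coverage_depth
        else:
            cov[g.cds_start: tss[gi] + 1] += config.coverage_depth
    return cov


# ---------------------------------------------------------------------------
# Peptides

def _random_peptide(rng, used: set[str]) -> str:
    while True:
        length = int(rng.integers(8, 19))
        body = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length - 1))
        seq = body + ("K" if rng.random() < 0.5 else "R")
        if seq not in used:
            used.add(seq)
            return seq


def _simulate_global_peptides(config, rng, gene_ids, base_log2, delta, samples, is_low, used):
    peptides = []
    for i, gid in enumerate(gene_ids):
        n_pep = 1 + rng.poisson(config.peptides_per_protein_mean - 1.0)
        ions = rng.normal(0.0, config.ionization_sigma, n_pep)
        rows = simulate_intensity_rows(
            base_log2[i] + ions, np.full(n_pep, delta[i]), is_low, config, rng
        )
        for j in range(n_pep):
            peptides.append(
                PeptideRecord(
                    sequence=_random_peptide(rng, used),
                    protein_ids=[gid],
                    phospho_sites=[],
                    intensities=dict(zip(samples, rows[j])),
                    source="global",
                )
            )
    return peptides


def _simulate_phosphopeptides(
    config, rng, gene_ids, protein_len, base_log2, delta, classes, samples, is_low, used
):
    prob = dict(config.class_phospho_prob)
    phospho_rows = []
    truth_pp = []
    for i, gid in enumerate(gene_ids):
        if rng.random() >= prob[classes[gid]]:
            continue
        n_pp = 1 + rng.poisson(config.phosphopeptides_mean - 1.0)
        for _ in range(n_pp):
            n_sites = 1 + int(rng.random() < 0.3)
            n_sites = min(n_sites, protein_len[i])
            positions = rng.choice(protein_len[i], size=n_sites, replace=False) + 1
            residues = [
                "STY"[k] for k in rng.choice(3, size=n_sites, p=[0.55, 0.33, 0.12])
            ]
            sites = sorted(zip(residues, (int(p) for p in positions)), key=lambda s: s[1])
            if rng.random() < config.phospho_null_fraction:
                phi = 0.0
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                phi = sign * rng.uniform(config.phospho_effect_min, config.phospho_effect_max)
            ion = rng.normal(0.0, config.ionization_sigma)
            base = base_log2[i] + ion + np.log2(config.phospho_base_occupancy)
            row = simulate_intensity_rows(
                np.array([base]), np.array([delta[i] + phi]), is_low, config, rng
            )[0]
            seq = _random_peptide(rng, used)
            phospho_rows.append(
                PeptideRecord(
                    sequence=seq,
                    protein_ids=[gid],
                    phospho_sites=sites,
                    intensities=dict(zip(samples, row)),
                    source="imac",
                )
            )
            truth_pp.append(
                {
                    "protein": gid,
                    "sequence": seq,
                    "sites": [[r, p] for r, p in sites],
                    "phi": float(phi),
                    "delta": float(delta[i]),
                }
            )
    return phospho_rows, truth_pp


def _simulate_contaminants(config, rng, gene_ids, base_log2, delta, samples, is_low,
                           n_phosphopeptides, used):
    n_cont = int(round(config.imac_contaminant_ratio * n_phosphopeptides))
    order = np.argsort(-base_log2, kind="stable")
    top = order[: max(1, len(order) // 5)]
    picks = rng.choice(top, size=n_cont, replace=True)
    peptides = []
    for i in picks:
        ion = rng.normal(0.0, config.ionization_sigma)
        row = simulate_intensity_rows(
            np.array([base_log2[i] + ion]), np.array([delta[i]]), is_low, config, rng
        )[0]
        peptides.append(
            PeptideRecord(
                sequence=_random_peptide(rng, used),
                protein_ids=[gene_ids[i]],
                phospho_sites=[],
                intensities=dict(zip(samples, row)),
                source="imac",
            )
        )
    return peptides


# ---------------------------------------------------------------------------
# Metabolites and annotation tables

def _simulate_metabolites(config, rng) -> tuple[pd.DataFrame, dict]:
    names = list(INTRACELLULAR_NAMES[: config.n_metabolites])
    names += [f"met_{i:03d}" for i in range(len(names), config.n_metabolites)]
    ext = list(EXTRACELLULAR_NAMES[: config.n_extracellular])
    ext += [f"ext_met_{i:03d}" for i in range(len(ext), config.n_extracellular)]

    def effect():
        if rng.random() < config.metabolite_null_fraction:
            return 0.0
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return sign * rng.uniform(config.metabolite_effect_min, config.metabolite_effect_max)

    cells = [("CN10", "9h"), ("CN150", "1h"), ("CN150", "9h")]
    rows = []
    truth = {}
    for name in names + ext:
        intracellular = name in names
        pooled = name == "arginine+ornithine"
        base = rng.normal(5.0, 1.0)
        fc_cond = effect()
        fc_time = effect()
        truth[name] = {
            "compartment": "intracellular" if intracellular else "extracellular",
            "fc_condition_9h": float(fc_cond),
            "fc_time_CN150": float(fc_time),
            "pooled": bool(pooled),
        }
        for condition, timepoint in cells:
            mu = base
            if condition == "CN150":
                mu += fc_cond
                if timepoint == "1h":
                    mu -= fc_time
            for rep in range(1, 4):
                conc = 2.0 ** (mu + rng.normal(0.0, config.metabolite_noise_sigma))
                if pooled:
                    conc += 2.0 ** (base - 1.0 + rng.normal(0.0, config.metabolite_noise_sigma))
                if intracellular:
                    dw = max(rng.normal(config.dry_weight_mean, config.dry_weight_sigma), 3.0)
                    value = conc * dw
                else:
                    dw = np.nan
                    value = conc
                rows.append(
                    {
                        "metabolite": name,
                        "compartment": "intracellular" if intracellular else "extracellular",
                        "condition": condition,
                        "timepoint": timepoint,
                        "replicate": rep,
                        "value": value,
                        "dry_weight": dw,
                        "pooled": int(pooled),
                    }
                )
    return pd.DataFrame(rows), truth


def _assign_classes(config, rng, gene_ids) -> dict[str, str]:
    classes = {gid: "other" for gid in gene_ids}
    order = rng.permutation(len(gene_ids))
    cursor = 0
    for cls, size in config.class_sizes:
        for idx in order[cursor: cursor + size]:
            classes[gene_ids[idx]] = cls
        cursor += size
    return classes


def _simulate_go(config, rng, gene_ids, delta, motif_truth) -> tuple[pd.DataFrame, dict]:
    terms = GO_TERMS + [f"process_{i:02d}" for i in range(10)]
    rows = []
    planted = {}
    motif_genes = set(motif_truth[0]["genes"]) if motif_truth else set()
    up_genes = {gid for gid, d in zip(gene_ids, delta) if d >= 1.0}
    for gid, d in zip(gene_ids, delta):
        assigned = set()
        n_terms = 1 + min(int(rng.poisson(1.0)), 2)
        for idx in rng.choice(len(terms), size=n_terms, replace=False):
            assigned.add(terms[idx])
        if gid in motif_genes and rng.random() < 0.6:
            assigned.add("amino-acid biosynthesis")
        if gid in up_genes and rng.random() < 0.5:
            assigned.add("proteolysis")
        for term in sorted(assigned):
            rows.append({"gene": gid, "term": term})
    if motif_truth:
        planted["amino-acid biosynthesis"] = {
            "coupled_to_motif": motif_truth[0]["pattern"], "prob": 0.6,
        }
    planted["proteolysis"] = {"coupled_to": "up-regulated genes", "prob": 0.5}
    return pd.DataFrame(rows), planted


# ---------------------------------------------------------------------------
# Top-level generation

def generate_dataset(config: SimConfig = SimConfig(), seed: int = 0) -> SyntheticDataset:
    rng = np.random.default_rng(seed)
    n = config.n_genes

    lengths, strands, starts, chrom_len = _sample_gene_layout(config, rng)
    gene_ids = [f"g{i + 1:04d}" for i in range(n)]
    genes = [
        GeneModel(
            gene_id=gene_ids[i],
            chrom="chr1",
            strand=str(strands[i]),
            cds_start=int(starts[i]),
            cds_end=int(starts[i] + lengths[i]),
        )
        for i in range(n)
    ]
    annotation = GenomeAnnotation(chromosomes={"chr1": int(chrom_len)}, genes=genes)
    annotation.compute_upstream_boundaries()

    u = rng.integers(config.tss_offset_min, config.tss_offset_max + 1, n)
    tss = np.where(
        strands == "+",
        starts - u,
        starts + lengths - 1 + u,
    ).astype(int)

    classes = _assign_classes(config, rng, gene_ids)

    truth_motifs: list[dict] = []
    stamped: list[tuple[int, str]] = []
    overrides = _plant_motifs(config, rng, genes, tss, truth_motifs, stamped)

    null = rng.random(n) < config.null_fraction
    signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    magnitude = rng.uniform(config.effect_min, config.effect_max, n)
    delta = np.where(null, 0.0, signs * magnitude)
    for gi, eff in overrides.items():
        delta[gi] = eff

    genome = {"chr1": _make_genome(chrom_len, stamped, rng)}
    coverage = CoverageTrack(
        counts={"chr1": _make_coverage(config, rng, genes, tss, chrom_len)}
    )

    samples, is_low = _sample_ids(config)
    base_log2 = rng.normal(config.base_abundance_log2, config.base_abundance_sigma, n)
    protein_len = (lengths // 3 - 1).astype(int)
    used: set[str] = set()
    peptides = _simulate_global_peptides(
        config, rng, gene_ids, base_log2, delta, samples, is_low, used
    )
    phospho, truth_pp = _simulate_phosphopeptides(
        config, rng, gene_ids, protein_len, base_log2, delta, classes, samples, is_low, used
    )
    contaminants = _simulate_contaminants(
        config, rng, gene_ids, base_log2, delta, samples, is_low, len(phospho), used
    )
    peptides = peptides + phospho + contaminants

    metabolites, truth_met = _simulate_metabolites(config, rng)
    go, planted_go = _simulate_go(config, rng, gene_ids, delta, truth_motifs)

    truth = {
        "seed": int(seed),
        "n_genes": n,
        "channel_noise_sigma": config.channel_noise_sigma,
        "coverage_background": config.coverage_background,
        "coverage_depth": config.coverage_depth,
        "n_replicates": config.n_replicates,
        "genes": {
            gene_ids[i]: {
                "strand": str(strands[i]),
                "cds": [int(starts[i]), int(starts[i] + lengths[i])],
                "tss": int(tss[i]),
                "tss_offset": int(u[i]),
                "delta": float(delta[i]),
                "class": classes[gene_ids[i]],
                "protein_length": int(protein_len[i]),
                "base_log2_abundance": float(base_log2[i]),
            }
            for i in range(n)
        },
        "phosphopeptides": truth_pp,
        "motifs": truth_motifs,
        "metabolites": truth_met,
        "go_planted": planted_go,
    }
    return SyntheticDataset(
        config=config,
        seed=seed,
        annotation=annotation,
        genome=genome,
        coverage=coverage,
        peptides=peptides,
        design=sample_design(config),
        metabolites=metabolites,
        go=go,
        classes=classes,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.genome, outdir / "genome.fa")
    write_gff(dataset.annotation, outdir / "genes.gff3")
    write_bedgraph(dataset.coverage, outdir / "coverage.bedgraph")
    write_peptide_table(dataset.peptides, outdir / "peptides.tsv")
    write_design(dataset.design, outdir / "design.tsv")
    write_metabolite_table(dataset.metabolites, outdir / "metabolites.tsv")
    dataset.go.to_csv(outdir / "go.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"protein": list(dataset.classes), "class": list(dataset.classes.values())}
    ).to_csv(outdir / "classes.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, sort_keys=True, indent=1)
        fh.write("\n")


def generate(config: SimConfig, seed: int, outdir) -> SyntheticDataset:
    dataset = generate_dataset(config, seed)
    write_dataset(dataset, outdir)
    return dataset


# ---------------------------------------------------------------------------
# Published-count fixture

PUBLISHED_GENOME_SIZE = 6448
PUBLISHED_CLASS_COUNTS = (("kinase", 89, 33), ("phosphatase", 45, 4), ("dna_binding", 279, 49))
PUBLISHED_PHOSPHOPROTEINS = 599
PUBLISHED_DETECTED_ALL_REPLICATES = 3567


def fixture_published_counts(outdir=None):
    """Deterministic fixture mirroring the published regulatory-class and
    proteome-coverage counts (89/45/279 class sizes with 33/4/49
    phosphorylated members, 599 phosphoproteins of 6448 genes, 3567
    models detected in every replicate).  Protein ids are synthetic.

    Returns (classes, phosphoproteins, detected); optionally writes
    classes.tsv, phosphoproteins.txt and detected_proteins.txt.
    """
    ids = [f"syn{i + 1:04d}" for i in range(PUBLISHED_GENOME_SIZE)]
    classes: dict[str, str] = {}
    phospho: list[str] = []
    cursor = 0
    for cls, size, n_phos in PUBLISHED_CLASS_COUNTS:
        members = ids[cursor: cursor + size]
        for pid in members:
            classes[pid] = cls
        phospho.extend(members[:n_phos])
        cursor += size
    others = ids[cursor:]
    for pid in others:
        classes[pid] = "other"
    n_other_phos = PUBLISHED_PHOSPHOPROTEINS - len(phospho)
    phospho.extend(others[:n_other_phos])
    detected = ids[:PUBLISHED_DETECTED_ALL_REPLICATES]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"protein": ids, "class": [classes[i] for i in ids]}).to_csv(
            outdir / "classes.tsv", sep="\t", index=False
        )
        Path(outdir / "phosphoproteins.txt").write_text("\n".join(phospho) + "\n")
        Path(outdir / "detected_proteins.txt").write_text("\n".join(detected) + "\n")
    return classes, set(phospho), detected
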