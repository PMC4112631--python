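"""Synthetic genomes, expression tables, progeny counts, splice fixtures.

The generator produces inputs with the statistical structure the analyses
assume, so every stage is testable without external downloads:

* a toy genome of ordered, strand-labelled, non-overlapping genes with
  log-normal lengths and intergenic gaps;
* a differential-expression table of null genes (zero-centred Gaussian
  log2 fold noise, uniform p-values) with injected blocks of 2-3
  immediately adjacent, sign-concordant deregulated genes, and optional
  adjacent duplicate pairs sharing a family id;
* binomially segregating progeny counts;
* spliced-gene fixtures whose intron-retention consequences are known by
  construction.

All randomness flows from a single integer seed through
``numpy.random.default_rng``. What the generator does NOT emulate:
microarray intensities, dye effects, normalization artefacts, or any
correlation structure beyond the injected blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneCatalogue, GeneRecord
from .splice import SpliceGeneModel, TruncationPrediction, predict_truncation

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "simulate_genome",
    "simulate_expression",
    "simulate_segregation",
    "make_splice_fixture",
    "top6b_splice_scenario",
]

# Codons per residue for reverse translation (standard nuclear code).
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = sorted(c for v in _CODONS.values() for c in v)


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters. Defaults give a toy genome that runs a
    full pipeline pass in seconds while keeping realistic scale ratios:
    ~2 kb genes and ~2 kb intergenic gaps (compact plant-like genome),
    strand-independent gene orientation, and injected adjacent blocks of
    two genes at a 2.0 log2-unit effect (4-fold), comfortably past the
    0.8 selection threshold.
    """

    n_chromosomes: int = 5
    genes_per_chromosome: int = 1000
    gene_length_meanlog: float = 7.5  # log bp; median ~1.8 kb
    gene_length_sdlog: float = 0.5
    gap_meanlog: float = 7.4  # log bp; median ~1.6 kb, mean ~2 kb
    gap_sdlog: float = 0.6
    strand_probability: float = 0.5  # P(+ strand)
    null_log2fc_sd: float = 0.25  # zero-centred noise on null genes
    n_injected_blocks: int = 10
    block_size: int = 2
    block_effect: float = 2.0  # |log2fc| of injected genes
    block_effect_jitter: float = 0.15
    block_p_scale: float = 1e-4  # injected p ~ scale * Beta(1, 9)
    n_duplicate_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.genes_per_chromosome) < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.strand_probability <= 1.0):
            raise ValueError("strand_probability must be in [0, 1]")
        if self.block_effect < 0:
            raise ValueError("block_effect must be >= 0")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class TruthLabels:
    """Ground truth of one expression simulation.

    ``labels`` maps every gene to one of ``null`` / ``injected-up`` /
    ``injected-down`` / ``duplicate``; ``blocks`` lists the member tuples
    of injected blocks (consecutive catalogue ranks); ``family_map``
    carries the duplicate-pair family assignment.
    """

    labels: dict[str, str]
    blocks: tuple[tuple[str, ...], ...]
    duplicate_pairs: tuple[tuple[str, str], ...]
    family_map: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["gene_id", "label"]
        )


def simulate_genome(config: SimulationConfig) -> GeneCatalogue:
    """Draw a toy genome of non-overlapping, strand-labelled genes.

    Genes are laid down left to right per chromosome with log-normal
    lengths and gaps, so placement can never collide. Deterministic for a
    fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = 1
        n = config.genes_per_chromosome
        if n == 0:
            continue
        lengths = np.maximum(
            np.rint(
                rng.lognormal(config.gene_length_meanlog, config.gene_length_sdlog, n)
            ).astype(int),
            50,
        )
        gaps = np.maximum(
            np.rint(rng.lognormal(config.gap_meanlog, config.gap_sdlog, n)).astype(int),
            1,
        )
        strands = np.where(
            rng.random(n) < config.strand_probability, "+", "-"
        )
        for i in range(n):
            start = pos + int(gaps[i])
            end = start + int(lengths[i]) - 1
            records.append(
                GeneRecord(
                    gene_id=f"g{c + 1:02d}_{i + 1:05d}",
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=str(strands[i]),
                )
            )
            pos = end
    return GeneCatalogue(records)


def _pick_block_starts(
    rng: np.random.Generator,
    chrom_sizes: list[int],
    n_blocks: int,
    block_size: int,
) -> list[tuple[int, int]]:
    """Choose non-touching (chromosome, start_rank) slots for blocks.

    A buffer of one rank between blocks keeps every injected block a
    maximal run, so truth labels match detected sets one-to-one.
    """
    candidates = [
        (ci, r)
        for ci, size in enumerate(chrom_sizes)
        for r in range(size - block_size + 1)
    ]
    rng.shuffle(candidates)
    chosen: list[tuple[int, int]] = []
    occupied: set[tuple[int, int]] = set()
    for ci, r in candidates:
        if len(chosen) == n_blocks:
            break
        span = {(ci, x) for x in range(r - 1, r + block_size + 1)}
        if span & occupied:
            continue
        chosen.append((ci, r))
        occupied |= span
    if len(chosen) < n_blocks:
        raise ValueError(
            f"cannot place {n_blocks} blocks of size {block_size}: "
            f"only {len(chosen)} non-adjacent slots available"
        )
    return sorted(chosen)


def simulate_expression(
    catalogue: GeneCatalogue, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthLabels]:
    """Simulate a DE table over the catalogue with injected structure.

    Null genes draw ``log2fc ~ N(0, null_log2fc_sd)`` and ``p ~ U(0,1)``.
    Each injected block gets one sign (alternating up/down) and per-gene
    ``log2fc = sign * (block_effect + N(0, jitter))`` with
    ``p = block_p_scale * Beta(1, 9)``. Duplicate pairs are adjacent gene
    pairs sharing a family id with correlated strong fold changes.
    """
    rng = np.random.default_rng(config.seed + 1)
    chroms = catalogue.chromosomes
    genes_by_chrom = [list(catalogue.genes_on(c)) for c in chroms]
    chrom_sizes = [len(g) for g in genes_by_chrom]
    n_genes = len(catalogue)
    need = config.n_injected_blocks * config.block_size + 2 * config.n_duplicate_pairs
    if need > n_genes:
        raise ValueError(
            f"capacity exceeded: need {need} genes for injected structure, "
            f"catalogue has {n_genes}"
        )

    slots = _pick_block_starts(
        rng,
        chrom_sizes,
        config.n_injected_blocks + config.n_duplicate_pairs,
        config.block_size,
    )
    block_slots = slots[: config.n_injected_blocks]
    dup_slots = slots[config.n_injected_blocks :]

    labels = {g.gene_id: "null" for g in catalogue}
    log2fc = {}
    p_value = {}

    blocks = []
    for b, (ci, r) in enumerate(block_slots):
        sign = 1 if b % 2 == 0 else -1
        members = tuple(
            genes_by_chrom[ci][r + k].gene_id for k in range(config.block_size)
        )
        blocks.append(members)
        for gid in members:
            labels[gid] = "injected-up" if sign > 0 else "injected-down"
            log2fc[gid] = sign * (
                config.block_effect
                + rng.normal(0.0, config.block_effect_jitter)
            )
            p_value[gid] = config.block_p_scale * rng.beta(1.0, 9.0)

    duplicate_pairs = []
    family_map: dict[str, str] = {}
    for d, (ci, r) in enumerate(dup_slots):
        a = genes_by_chrom[ci][r].gene_id
        b_ = genes_by_chrom[ci][r + 1].gene_id
        fam = f"fam{d + 1:03d}"
        sign = 1 if rng.random() < 0.5 else -1
        base = sign * (config.block_effect + rng.normal(0.0, config.block_effect_jitter))
        for gid in (a, b_):
            labels[gid] = "duplicate"
            log2fc[gid] = base + rng.normal(0.0, 0.05)
            p_value[gid] = config.block_p_scale * rng.beta(1.0, 9.0)
            family_map[gid] = fam
        duplicate_pairs.append((a, b_))

    rows = []
    for g in catalogue:
        gid = g.gene_id
        if gid in log2fc:
            fc, p = log2fc[gid], p_value[gid]
        else:
            fc = rng.normal(0.0, config.null_log2fc_sd)
            p = rng.uniform()
        rows.append((gid, float(fc), float(min(p, 1.0))))
    table = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_value"])
    truth = TruthLabels(
        labels=labels,
        blocks=tuple(blocks),
        duplicate_pairs=tuple(duplicate_pairs),
        family_map=family_map,
    )
    return table, truth


def simulate_segregation(
    n_progeny: int, mutant_probability: float, seed: int = 0
) -> tuple[int, int]:
    """Binomial progeny draw: ``(n_mutant, n_wildtype)``."""
    if n_progeny <= 0:
        raise ValueError("n_progeny must be positive")
    if not (0.0 <= mutant_probability <= 1.0):
        raise ValueError("mutant_probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_mut = int(rng.binomial(n_progeny, mutant_probability))
    return n_mut, n_progeny - n_mut


# -- splice fixtures ---------------------------------------------------------


def _random_sense_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [(_SENSE_CODONS[i]) for i in rng.integers(0, len(_SENSE_CODONS), n)]


def _reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    return "".join(
        _CODONS[res][int(rng.integers(0, len(_CODONS[res])))] for res in peptide
    )


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def make_splice_fixture(
    seed: int = 0,
    n_residues_before: int = 20,
    n_residues_after: int = 10,
    novel_peptide_length: int = 8,
    intron_length: int = 60,
) -> tuple[SpliceGeneModel, TruncationPrediction]:
    """Build a two-exon gene whose intron retention has a known outcome.

    The intron begins with the canonical GT donor, encodes
    ``novel_peptide_length`` in-frame residues (the first forced to Val
    by the donor GT), then a stop codon, then random padding. The exon
    junction sits at a codon boundary, so the expected truncation is
    known entirely by construction and returned alongside the model.
    """
    rng = np.random.default_rng(seed)
    utr5 = _random_bases(rng, 12)
    utr3 = _random_bases(rng, 15)

    cds_before = "ATG" + "".join(_random_sense_codons(rng, n_residues_before - 1))
    cds_after = "".join(_random_sense_codons(rng, n_residues_after))
    stop = _STOPS[int(rng.integers(0, 3))]

    novel = "V" + "".join(
        sorted(_CODONS)[int(rng.integers(0, 20))]
        for _ in range(novel_peptide_length - 1)
    )
    novel_nt = "GT" + _reverse_translate(rng, novel)[2:]
    # GT prefix constrains the first codon to GTx = Val; keep the drawn
    # third base so the codon stays valid.
    intron_stop = _STOPS[int(rng.integers(0, 3))]
    pad = intron_length - len(novel_nt) - 3
    if pad < 0:
        raise ValueError("intron_length too short for the requested peptide")
    intron = novel_nt + intron_stop + _random_bases(rng, pad)

    model = SpliceGeneModel(
        gene_id=f"synth_splice_{seed}",
        exons=(utr5 + cds_before, cds_after + stop + utr3),
        introns=(intron,),
        cds_offset=len(utr5),
        protein_length=n_residues_before + n_residues_after,
    )
    expected = TruncationPrediction(
        transcript_length=len(model.mature_mrna) + len(intron),
        novel_peptide=novel,
        stop_position_in_intron=3 * novel_peptide_length + 1,
        residues_retained=n_residues_before,
        residues_lost=n_residues_after,
    )
    assert predict_truncation(model, 1) == expected
    return model, expected


def top6b_splice_scenario(
    seed: int = 0,
) -> tuple[SpliceGeneModel, tuple[int, str], TruncationPrediction]:
    """Synthetic stand-in with the geometry of the TOP6B splice mutation.

    The true genomic sequence is not bundled; this model reproduces the
    published geometry exactly: a 2212-nt mature mRNA encoding a 670-aa
    protein, a 300-nt intron 7 whose junction follows codon 198 (a Met),
    and a G->A substitution at intron nucleotide 1 that abolishes the GT
    donor. Translating the mutant intron-retained 2512-nt transcript adds
    the intron-encoded peptide IIIYSYQV after Met198 and stops at a UGA
    whose first base is intron nucleotide 25, losing the 472 C-terminal
    residues.

    Returns ``(wild_type_model, variant, expected_mutant_prediction)``
    where ``variant = (1, "A")`` applies to intron 7.
    """
    rng = np.random.default_rng(seed)
    protein_length = 670
    residues_before = 198  # last retained residue; engineered to be Met
    utr5_len, utr3_len = 100, 99

    pep_before = "M" + "".join(
        sorted(_CODONS)[int(rng.integers(0, 20))] for _ in range(residues_before - 2)
    ) + "M"  # residue 198 is Met, per the published junction
    cds_before = _reverse_translate(rng, pep_before)
    cds_after = "".join(_random_sense_codons(rng, protein_length - residues_before))

    # Mutant intron 7 encodes IIIYSYQV then TGA starting at nt 25; the
    # wild type differs only at nt 1 (G, restoring the GT donor).
    novel = "IIIYSYQV"
    mutant_head = _reverse_translate(rng, novel)
    mutant_head = "AT" + mutant_head[2:]  # first codon ATx = Ile; nt 1 is the mutant A
    intron7_mut = mutant_head + "TGA" + _random_bases(rng, 300 - len(mutant_head) - 3)
    intron7_wt = "G" + intron7_mut[1:]

    # Eight exons / seven introns; intron 7 is the mutated one. Upstream
    # exon boundaries are arbitrary cuts; only junction 7 must fall on a
    # codon boundary (CDS nt before it: 3 * 198 = 594).
    utr5 = _random_bases(rng, utr5_len)
    body = utr5 + cds_before
    cuts = np.linspace(0, len(body), 8, dtype=int)[1:-1]
    exons = []
    prev = 0
    for cut in cuts:
        exons.append(body[prev:cut])
        prev = cut
    exons.append(body[prev:])  # exon 7 ends exactly at the codon-198 junction
    exons.append(cds_after + "TGA" + _random_bases(rng, utr3_len))  # exon 8

    introns = ["GT" + _random_bases(rng, 58) for _ in range(6)]
    introns.append(intron7_wt)

    model = SpliceGeneModel(
        gene_id="synthetic_top6b_like",
        exons=tuple(exons),
        introns=tuple(introns),
        cds_offset=utr5_len,
        protein_length=protein_length,
    )
    assert len(model.mature_mrna) == 2212
    expected = TruncationPrediction(
        transcript_length=2512,
        novel_peptide=novel,
        stop_position_in_intron=25,
        residues_retained=residues_before,
        residues_lost=protein_length - residues_before,
    )
    return model, (1, "A"), expected
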