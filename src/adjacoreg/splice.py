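"""Splice-donor mutation consequence prediction.

A point mutation at the first nucleotide of an intron destroys the
invariant GT donor dinucleotide, so the spliceosome retains the intron in
the mature transcript. Translation then runs from the annotated start
codon into the retained intron until the first in-frame stop, producing a
truncated protein carrying a short stretch of novel, intron-encoded
residues.

The gene model keeps exon and intron sequences explicitly; everything
here is single-gene arithmetic on those sequences (no genome-wide variant
annotation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from Bio.Seq import Seq

__all__ = [
    "SpliceGeneModel",
    "TruncationPrediction",
    "DonorStatus",
    "validate_donor_site",
    "retained_intron_transcript",
    "predict_truncation",
    "alternative_donor_transcript",
]

_ALPHABET = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Donor-site diagnosis values.
DONOR_INTACT = "consensus intact"
DONOR_ABOLISHED = "consensus abolished"
DonorStatus = str


def _translate(seq: str) -> str:
    """Standard nuclear genetic code; trailing partial codon ignored."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate(table="Standard"))


@dataclass(frozen=True)
class SpliceGeneModel:
    """Exon/intron structure plus sequence for one spliced gene.

    ``cds_offset`` is the 0-based position of the A of the start ATG
    within the mature (spliced) mRNA. ``protein_length`` is the annotated
    full-length protein in residues (stop codon not counted).
    """

    gene_id: str
    exons: tuple[str, ...]
    introns: tuple[str, ...]
    cds_offset: int
    protein_length: int

    def __post_init__(self) -> None:
        if len(self.introns) != len(self.exons) - 1:
            raise ValueError(
                f"{self.gene_id}: need exactly len(exons)-1 introns "
                f"(got {len(self.exons)} exons, {len(self.introns)} introns)"
            )
        for label, seqs in (("exon", self.exons), ("intron", self.introns)):
            for i, s in enumerate(seqs, start=1):
                bad = set(s) - _ALPHABET
                if bad:
                    raise ValueError(
                        f"{self.gene_id}: {label} {i} has non-ACGT symbols {sorted(bad)}"
                    )
        if self.cds_offset < 0:
            raise ValueError("cds_offset must be >= 0")
        mrna = self.mature_mrna
        if mrna[self.cds_offset : self.cds_offset + 3] != "ATG":
            raise ValueError(
                f"{self.gene_id}: CDS does not begin with ATG at offset {self.cds_offset}"
            )
        protein = _translate(mrna[self.cds_offset :])
        stop_at = protein.find("*")
        if stop_at != self.protein_length:
            raise ValueError(
                f"{self.gene_id}: mature CDS encodes "
                f"{stop_at if stop_at >= 0 else '>' + str(len(protein))} residues, "
                f"annotated protein_length is {self.protein_length}"
            )

    @property
    def mature_mrna(self) -> str:
        return "".join(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def _check_intron(self, intron_index: int) -> None:
        if not (1 <= intron_index <= self.n_introns):
            raise IndexError(
                f"{self.gene_id}: intron index {intron_index} outside 1..{self.n_introns}"
            )

    def with_intron_variant(
        self, intron_index: int, position: int, alt: str
    ) -> "SpliceGeneModel":
        """Return a copy with a substitution at ``position`` (1-based) of
        the given intron."""
        self._check_intron(intron_index)
        intron = self.introns[intron_index - 1]
        if not (1 <= position <= len(intron)):
            raise IndexError(
                f"variant position {position} outside intron {intron_index} "
                f"(length {len(intron)})"
            )
        if alt not in _ALPHABET:
            raise ValueError(f"variant base must be one of ACGT, got {alt!r}")
        mutated = intron[: position - 1] + alt + intron[position:]
        introns = list(self.introns)
        introns[intron_index - 1] = mutated
        return replace(self, introns=tuple(introns))


@dataclass(frozen=True)
class TruncationPrediction:
    """Consequence of translating an intron-retained transcript."""

    transcript_length: int  # nt, intron retained
    novel_peptide: str  # intron-encoded residues before the stop
    stop_position_in_intron: int  # 1-based nt of the stop codon's first base
    residues_retained: int  # exon-encoded residues kept
    residues_lost: int  # annotated_length - residues_retained

    def __post_init__(self) -> None:
        if self.residues_retained < 0 or self.residues_lost < 0:
            raise ValueError("residue counts must be >= 0")


def validate_donor_site(
    model: SpliceGeneModel,
    intron_index: int,
    variant: Optional[tuple[int, str]] = None,
) -> DonorStatus:
    """Diagnose the splice-donor consensus of an intron (1-based index).

    The consensus is reduced to the invariant GT dinucleotide at intron
    positions 1-2. ``variant`` is an optional ``(position, alt_base)``
    substitution applied before the check.
    """
    model._check_intron(intron_index)
    if variant is not None:
        model = model.with_intron_variant(intron_index, variant[0], variant[1])
    intron = model.introns[intron_index - 1]
    return DONOR_INTACT if intron.startswith("GT") else DONOR_ABOLISHED


def retained_intron_transcript(
    model: SpliceGeneModel, intron_index: int
) -> tuple[str, int]:
    """Transcript with one intron retained in place: ``(sequence, length)``."""
    model._check_intron(intron_index)
    parts = []
    for i, exon in enumerate(model.exons, start=1):
        parts.append(exon)
        if i == intron_index:
            parts.append(model.introns[intron_index - 1])
    seq = "".join(parts)
    return seq, len(seq)


def predict_truncation(
    model: SpliceGeneModel, intron_index: int
) -> TruncationPrediction:
    """Translate the intron-retained transcript to its premature stop.

    Translation starts at the annotated ATG and proceeds codon by codon
    until the first stop. Residues whose codons end at or before the
    intron junction are exon-encoded ("retained"); residues at or past
    the junction (including a codon spanning it) are "novel". The stop
    position is the 1-based nucleotide of the stop codon's first base
    within the retained intron.
    """
    transcript, length = retained_intron_transcript(model, intron_index)
    intron_start = sum(len(e) for e in model.exons[:intron_index])  # 0-based
    intron_len = len(model.introns[intron_index - 1])

    cds = transcript[model.cds_offset :]
    protein = _translate(cds)
    stop_idx = protein.find("*")  # residue index of the stop
    if stop_idx == -1:
        raise ValueError(
            f"{model.gene_id}: no in-frame stop before transcript end "
            "(model implies read-through)"
        )
    stop_codon_start = model.cds_offset + 3 * stop_idx  # 0-based in transcript
    if stop_codon_start < intron_start:
        raise ValueError(
            f"{model.gene_id}: stop codon precedes the retained intron; "
            "the mature CDS already terminates upstream"
        )

    # Residues fully encoded upstream of the junction.
    residues_retained = min(
        (intron_start - model.cds_offset) // 3, stop_idx
    )
    novel_peptide = protein[residues_retained:stop_idx]
    stop_in_intron = stop_codon_start - intron_start + 1
    if stop_in_intron > intron_len:
        # Stop falls downstream of the retained intron (frame-preserving
        # intron with no internal stop); position reported past its end.
        pass
    return TruncationPrediction(
        transcript_length=length,
        novel_peptide=novel_peptide,
        stop_position_in_intron=stop_in_intron,
        residues_retained=residues_retained,
        residues_lost=model.protein_length - residues_retained,
    )


def alternative_donor_transcript(
    model: SpliceGeneModel, intron_index: int, offset: int = 21
) -> tuple[str, str]:
    """Splice at a cryptic donor ``offset`` nt into the intron.

    Models the hypothesis that a downstream GT can substitute for a
    mutated canonical donor, adding the intron's first ``offset``
    nucleotides to the mature transcript. Returns ``(transcript,
    extra_residues)`` with the peptide encoded by the retained stub; the
    offset must be a multiple of 3 (frame-preserving) and the stub must
    not contain an in-frame stop.
    """
    model._check_intron(intron_index)
    if offset % 3 != 0:
        raise ValueError("cryptic-donor offset must preserve the reading frame")
    intron = model.introns[intron_index - 1]
    if offset >= len(intron):
        raise ValueError("offset beyond intron end")
    stub = intron[:offset]
    parts = []
    for i, exon in enumerate(model.exons, start=1):
        parts.append(exon)
        if i == intron_index:
            parts.append(stub)
    transcript = "".join(parts)
    extra = _translate(stub) if stub else ""
    if "*" in extra:
        raise ValueError("retained donor stub contains an in-frame stop")
    return transcript, extra
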