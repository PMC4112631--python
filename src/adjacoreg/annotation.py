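"""Genome gene annotations as an ordered, strand-aware catalogue.

The catalogue is the substrate for all positional (adjacency) statistics:
genes on each chromosome are ranked by coordinate, and "immediately
adjacent" means consecutive ranks with no intervening annotated gene.

Coordinates are stored 1-based inclusive (GFF3 convention). BED input
(0-based half-open) is converted on ingest: ``start = bed_start + 1``,
``end = bed_end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "GeneRecord",
    "GeneCatalogue",
    "read_annotation",
    "write_annotation",
    "interval_width",
]

_STRANDS = frozenset({"+", "-"})

#: Column order of the canonical TSV representation.
TSV_COLUMNS = ("gene_id", "chromosome", "start", "end", "strand", "family_id")


@dataclass(frozen=True)
class GeneRecord:
    """A single gene: identifier, location, strand, optional family.

    ``family_id`` groups duplicated/paralogous genes so that adjacent
    co-regulated pairs explained by duplicated regulatory elements can be
    excluded from enrichment counts.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: coordinates are 1-based, got start={self.start}")
        if self.strand not in _STRANDS:
            raise ValueError(
                f"gene {self.gene_id}: unknown strand symbol {self.strand!r} (expected '+' or '-')"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneCatalogue:
    """Per-chromosome ordered gene records with O(1) neighbour lookup.

    Within each chromosome, records are sorted by ``(start, end, gene_id)``;
    the rank index is a bijection ``gene_id <-> (chromosome, rank)``.
    Overlapping genes are permitted.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        by_chrom: dict[str, list[GeneRecord]] = {}
        seen: set[str] = set()
        for rec in records:
            if rec.gene_id in seen:
                raise ValueError(f"duplicate gene_id: {rec.gene_id}")
            seen.add(rec.gene_id)
            by_chrom.setdefault(rec.chromosome, []).append(rec)
        self._by_chrom: dict[str, list[GeneRecord]] = {}
        self._index: dict[str, tuple[str, int]] = {}
        for chrom in sorted(by_chrom):
            ordered = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end, r.gene_id))
            self._by_chrom[chrom] = ordered
            for rank, rec in enumerate(ordered):
                self._index[rec.gene_id] = (chrom, rank)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __iter__(self) -> Iterator[GeneRecord]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneCatalogue):
            return NotImplemented
        return list(self) == list(other)

    # -- accessors ----------------------------------------------------------

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._by_chrom)

    def genes_on(self, chromosome: str) -> tuple[GeneRecord, ...]:
        return tuple(self._by_chrom.get(chromosome, ()))

    def get(self, gene_id: str) -> GeneRecord:
        chrom, rank = self._locate(gene_id)
        return self._by_chrom[chrom][rank]

    def rank(self, gene_id: str) -> tuple[str, int]:
        """Return ``(chromosome, rank)`` of a gene (rank is 0-based)."""
        return self._locate(gene_id)

    def _locate(self, gene_id: str) -> tuple[str, int]:
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"gene_id not in catalogue: {gene_id}") from None

    def immediate_neighbours(
        self, gene_id: str
    ) -> tuple[Optional[str], Optional[str]]:
        """Previous/next gene on the same chromosome; ``None`` at boundaries."""
        chrom, rank = self._locate(gene_id)
        genes = self._by_chrom[chrom]
        prev_id = genes[rank - 1].gene_id if rank > 0 else None
        next_id = genes[rank + 1].gene_id if rank + 1 < len(genes) else None
        return prev_id, next_id

    def family_map(self) -> dict[str, str]:
        """gene_id -> family_id for every gene that has one."""
        return {r.gene_id: r.family_id for r in self if r.family_id is not None}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.gene_id, r.chromosome, r.start, r.end, r.strand, r.family_id)
            for r in self
        ]
        return pd.DataFrame(rows, columns=list(TSV_COLUMNS))


# -- readers ----------------------------------------------------------------


def _read_tsv(path: Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    if df.empty and df.columns.size == 0:
        return []
    required = {"gene_id", "chromosome", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: TSV header missing columns {sorted(missing)}")
    records = []
    has_family = "family_id" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            fam = getattr(row, "family_id", None) if has_family else None
            if pd.isna(fam):
                fam = None
            records.append(
                GeneRecord(
                    gene_id=str(row.gene_id),
                    chromosome=str(row.chromosome),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                    family_id=fam,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
    return records


def _read_gff3(path: Path) -> list[GeneRecord]:
    # Only feature type "gene" is ingested; transcript/exon structure is the
    # business of the splice model, not the adjacency substrate.
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: malformed GFF3 row at line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    key, _, val = item.partition("=")
                    attr_map[key.strip()] = val.strip()
            gene_id = attr_map.get("ID")
            if not gene_id:
                raise ValueError(
                    f"{path}: malformed GFF3 row at line {lineno}: missing ID attribute"
                )
            try:
                records.append(
                    GeneRecord(
                        gene_id=gene_id,
                        chromosome=chrom,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        family_id=attr_map.get("family_id"),
                    )
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed GFF3 row at line {lineno}: {exc}"
                ) from exc
    return records


def _read_bed(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: malformed BED row at line {lineno}: "
                    f"need >=6 columns (chrom, start, end, name, score, strand)"
                )
            chrom, s, e, name, _score, strand = fields[:6]
            try:
                # BED is 0-based half-open; internal is 1-based inclusive.
                records.append(
                    GeneRecord(
                        gene_id=name,
                        chromosome=chrom,
                        start=int(s) + 1,
                        end=int(e),
                        strand=strand,
                    )
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed BED row at line {lineno}: {exc}"
                ) from exc
    return records


_READERS = {"tsv": _read_tsv, "gff3": _read_gff3, "bed": _read_bed}


def read_annotation(path: str | Path, format_spec: str = "tsv") -> GeneCatalogue:
    """Read a gene annotation file into a :class:`GeneCatalogue`.

    Parameters
    ----------
    path
        Annotation file. Must exist.
    format_spec
        One of ``{"gff3", "bed", "tsv"}``. For GFF3 only rows of feature
        type ``gene`` are ingested (attribute ``ID`` is the gene id); BED
        needs >=6 columns (column 4 id, column 6 strand); TSV needs a header
        ``gene_id  chromosome  start  end  strand [family_id]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    try:
        reader = _READERS[format_spec]
    except KeyError:
        raise ValueError(
            f"unknown format_spec {format_spec!r}; expected one of {sorted(_READERS)}"
        ) from None
    if path.stat().st_size == 0:
        return GeneCatalogue([])
    return GeneCatalogue(reader(path))


def write_annotation(catalogue: GeneCatalogue, path: str | Path) -> None:
    """Dump the catalogue as canonical TSV (round-trips exactly)."""
    catalogue.to_frame().to_csv(path, sep="\t", index=False)


def interval_width(coord_a: int, coord_b: int) -> int:
    """Width ``|coord_b - coord_a|`` between two 1-based coordinates.

    Used for mapping-interval arithmetic between flanking marker positions.
    """
    for c in (coord_a, coord_b):
        if c <= 0:
            raise ValueError(f"coordinates must be positive, got {c}")
    return abs(int(coord_b) - int(coord_a))
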