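"""Shared genomic domain objects.

Coordinates are 0-based half-open everywhere inside the library; GTF I/O
converts from the 1-based inclusive file convention at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")
BIOTYPES = ("coding", "lncRNA")


class ValidationError(ValueError):
    """A domain object violates one of its structural invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval on one chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp in common on the same chromosome (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap(self, other: "GenomicInterval") -> int | None:
        """End-to-start distance in bp; 0 when overlapping or abutting.

        Returns None for intervals on different chromosomes, where a linear
        distance is undefined.
        """
        if self.chrom != other.chrom:
            return None
        return max(0, self.start - other.end, other.start - self.end)


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured genomic locus (coding gene or lncRNA).

    Exons must be sorted, non-overlapping and contained in the locus; the
    gaps between consecutive exons are the introns.
    """

    transcript_id: str
    gene_name: str
    biotype: str
    locus: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValidationError("empty transcript_id")
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.transcript_id}: biotype must be one of {BIOTYPES}, "
                f"got {self.biotype!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.locus.chrom or ex.strand != self.locus.strand:
                raise ValidationError(
                    f"{self.transcript_id}: exon {ex.chrom}:{ex.start}-{ex.end} "
                    f"not on locus chromosome/strand"
                )
            if ex.start < self.locus.start or ex.end > self.locus.end:
                raise ValidationError(
                    f"{self.transcript_id}: exon [{ex.start}, {ex.end}) outside "
                    f"locus [{self.locus.start}, {self.locus.end})"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = ex.end

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.locus.chrom, a.end, b.start, self.locus.strand)
                )
        return tuple(out)

    @property
    def tss(self) -> int:
        """Transcription start coordinate: locus.start on '+', locus.end on '-'."""
        return self.locus.start if self.locus.strand == "+" else self.locus.end
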