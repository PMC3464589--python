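"""Genomic intervals in BED convention (0-based, half-open).

Every coordinate in this package is 0-based with an exclusive end.  Strand
"." is legal and means "strandless"; predicted RNA structures are always
strandless because comparative structure prediction does not resolve the
transcribed strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


PART_KINDS = ("five_utr", "cds", "intron", "three_utr")


@dataclass
class GeneModel:
    """A gene as a list of (interval, part kind) on one strand.

    Parts must be non-overlapping within the gene and all on the gene's
    strand.  UTR/CDS parts are exonic; introns are not.
    """

    gene_id: str
    parts: list[tuple[GenomicInterval, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv, kind in self.parts:
            if kind not in PART_KINDS:
                raise ValueError(f"unknown gene part kind {kind!r}")
        ivs = sorted((iv for iv, _ in self.parts), key=lambda i: (i.chrom, i.start))
        for a, b in zip(ivs, ivs[1:]):
            if a.chrom == b.chrom and a.end > b.start:
                raise ValueError(f"overlapping parts in gene {self.gene_id}")

    @property
    def strand(self) -> str:
        return self.parts[0][0].strand if self.parts else "."

    def parts_of_kind(self, kind: str) -> list[GenomicInterval]:
        return [iv for iv, k in self.parts if k == kind]

    @property
    def span(self) -> GenomicInterval:
        ivs = [iv for iv, _ in self.parts]
        return GenomicInterval(
            ivs[0].chrom,
            min(iv.start for iv in ivs),
            max(iv.end for iv in ivs),
            self.strand,
        )


EXONIC_KINDS = ("five_utr", "cds", "three_utr")
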