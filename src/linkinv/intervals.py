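"""Genomic interval primitives.

All internal coordinates are 0-based, half-open; conversion to/from 1-based
formats (VCF, the inversion catalog's printed positions) happens at I/O
boundaries only.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap of two intervals.

    Returns ``min(|a ∩ b| / |a|, |a ∩ b| / |b|)``, i.e. the overlap fraction
    of the *less* well covered interval; 0 for intervals on different
    chromosomes. This is the symmetric merge criterion used for clustering
    structural-variant calls.
    """
    inter = a.intersection_length(b)
    if inter == 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def make_windows(chrom_lengths: dict[str, int], size: int) -> list[GenomicInterval]:
    """Tile each chromosome with consecutive windows of ``size`` bp.

    The final window of each chromosome is truncated at the chromosome end.
    """
    out: list[GenomicInterval] = []
    for chrom in chrom_lengths:
        length = chrom_lengths[chrom]
        for start in range(0, length, size):
            out.append(GenomicInterval(chrom, start, min(start + size, length)))
    return out
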