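"""Genomic coordinate containers.

All coordinates are 0-based half-open (BED convention).  A :class:`PeakSet`
is always tied to a :class:`Genome` (a chromosome-size table) so that every
interval can be validated against its chromosome length — silently dropping
peaks on unknown chromosomes would corrupt downstream randomization nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


class GenomeError(ValueError):
    """Raised for inconsistent chromosome-size tables or unknown chromosomes."""


@dataclass(frozen=True)
class Genome:
    """Chromosome-name -> length (bp) table.

    Lengths must be positive and names unique; looking up an unknown
    chromosome raises :class:`GenomeError`.
    """

    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise GenomeError("genome has no chromosomes")
        for name, length in self.chrom_sizes.items():
            if not isinstance(length, int) or length <= 0:
                raise GenomeError(
                    f"chromosome {name!r} has non-positive length {length!r}"
                )
        object.__setattr__(self, "chrom_sizes", dict(self.chrom_sizes))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __iter__(self):
        return iter(self.chrom_sizes)

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            raise GenomeError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval with optional peak height and summit.

    ``height`` is the per-peak signal magnitude in arbitrary units (the
    narrowPeak signalValue, or the BED6 score).  ``summit`` is an absolute
    bp position inside ``[start, end)``.
    """

    chrom: str
    start: int
    end: int
    height: Optional[float] = None
    summit: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.height is not None and self.height < 0:
            raise ValueError(f"negative peak height {self.height}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 bp (half-open: touching
        endpoints do not overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PeakSet:
    """A set of peaks on a genome, stored sorted by (chrom, start, end)."""

    intervals: tuple
    genome: Genome

    def __init__(self, intervals: Iterable[GenomicInterval], genome: Genome):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        for iv in ivs:
            if iv.chrom not in genome:
                raise GenomeError(f"peak on unknown chromosome {iv.chrom!r}")
            if iv.end > genome.length(iv.chrom):
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} extends past "
                    f"chromosome end {genome.length(iv.chrom)}"
                )
        object.__setattr__(self, "intervals", tuple(ivs))
        object.__setattr__(self, "genome", genome)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def on_chrom(self, chrom: str) -> tuple:
        return tuple(iv for iv in self.intervals if iv.chrom == chrom)

    def heights(self):
        return [iv.height for iv in self.intervals]
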