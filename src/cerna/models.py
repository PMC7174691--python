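"""Core genomic containers shared by every pipeline stage.

Coordinates are 0-based half-open throughout the package; conversion to the
1-based inclusive GTF convention happens only in :mod:`cerna.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Positional overlap, ignoring strand."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript, optionally with sequence.

    ``exons`` must share one chromosome and strand, be sorted by start and be
    non-overlapping. ``length`` is the spliced length (sum of exon lengths)
    and must match ``len(sequence)`` when a sequence is attached.
    ``read_support`` carries the assembler's read-count evidence used by the
    identification cascade.
    """

    id: str
    exons: Tuple[GenomicInterval, ...]
    sequence: Optional[str] = None
    read_support: int = 0

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        if not self.exons:
            raise ValueError(f"transcript {self.id!r} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"transcript {self.id!r}: exons span multiple "
                "chromosomes or strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.id!r}: exons unsorted or overlapping"
                )
        if self.read_support < 0:
            raise ValueError(f"transcript {self.id!r}: negative read support")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"transcript {self.id!r}: sequence length "
                f"{len(self.sequence)} != spliced length {self.length}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Half-open (donor, acceptor) intervals between adjacent exons."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )
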