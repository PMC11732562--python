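"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)``, the BED convention.
Strand is one of ``'+'``, ``'-'`` or ``'.'`` (unstranded).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic span ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share >= 1 bp on the same chrom."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def with_strand(self, strand: str) -> "GenomicInterval":
        return replace(self, strand=strand)


@dataclass(frozen=True)
class GeneModel:
    """A single-isoform gene: one interval, one TSS, one TTS.

    On the ``+`` strand the TSS is ``interval.start`` and the TTS is
    ``interval.end``; on the ``-`` strand the TSS is ``interval.end - 1``
    (the last covered base) and the TTS is ``interval.start``.
    """

    id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("gene id must be non-empty")
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent ``(start, end)`` pairs into maximal runs."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
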