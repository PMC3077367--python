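"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)`` throughout the
package; 1-based formats (wiggle, TRANSFAC position indices) are converted
at the parsing boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
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

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass
class PeakRegion:
    """A ChIP-seq peak interval with its tag-count height.

    ``height`` is the peak's tag count, used as a proxy for binding
    strength; ``dataset_id`` labels the TF / cell-line experiment the
    peak came from.
    """

    interval: GenomicInterval
    height: float = 0.0
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError(f"negative peak height {self.height}")


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals into a minimal disjoint set."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out.pop()
            out.append(
                GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
            )
        else:
            out.append(iv)
    return out


def subtract_intervals(
    region: GenomicInterval, blocked: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Return the sub-intervals of ``region`` not covered by ``blocked``."""
    gaps: list[GenomicInterval] = []
    cursor = region.start
    for iv in merge_intervals(
        [b for b in blocked if b.overlaps(region)]
    ):
        lo = max(iv.start, region.start)
        if lo > cursor:
            gaps.append(GenomicInterval(region.chrom, cursor, lo))
        cursor = max(cursor, min(iv.end, region.end))
    if cursor < region.end:
        gaps.append(GenomicInterval(region.chrom, cursor, region.end))
    return gaps
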