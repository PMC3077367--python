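"""Construction of the site and promoter benchmark datasets.

Site benchmark: every ChIP-seq peak is embedded in a randomly placed
fixed-length test region (20 kb by default, ~100x the average peak);
overlapping regions are merged into one region whose length is the sum
of the merged lengths, which keeps the positive/negative base-pair ratio
constant.  The peak-free remainder of each region, minus an exclusion
mask of lesser peaks, is cut into 200 bp negative chunks.

Promoter benchmark: per gene, a promoter region (2000 bp upstream to
200 bp downstream of the TSS, strand-aware) and a first-intron region
(capped at 3000 bp downstream of the intron start); peaks are mapped
into the regions, partially overlapping peaks extend the region, and
the peak-free flanks become the negatives, not further subdivided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .intervals import (
    GenomicInterval,
    PeakRegion,
    merge_intervals,
    subtract_intervals,
)


@dataclass
class SiteBenchmarkConfig:
    region_length: int = 20_000
    chunk_length: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.region_length > self.chunk_length > 0:
            raise ValueError("need region_length > chunk_length > 0")


@dataclass
class PromoterBenchmarkConfig:
    upstream: int = 2000
    downstream: int = 200
    intron_cap: int = 3000

    def __post_init__(self) -> None:
        if min(self.upstream, self.downstream, self.intron_cap) <= 0:
            raise ValueError("promoter window sizes must be positive")


@dataclass
class TestRegion:
    """One benchmark test region: its interval, the peaks (positives) it
    contains, and its negative subintervals."""

    __test__ = False  # not a pytest collection target

    interval: GenomicInterval
    peaks: list[PeakRegion] = field(default_factory=list)
    negatives: list[GenomicInterval] = field(default_factory=list)
    kind: str = "site"
    label: str = ""

    @property
    def region_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"


@dataclass
class BenchmarkDataset:
    dataset_id: str
    regions: list[TestRegion]
    config: object | None = None

    @property
    def peaks(self) -> list[PeakRegion]:
        return [p for r in self.regions for p in r.peaks]

    @property
    def n_positives(self) -> int:
        return len(self.peaks)

    @property
    def n_negatives(self) -> int:
        return sum(len(r.negatives) for r in self.regions)


@dataclass
class Gene:
    """Minimal gene record for the promoter benchmark: TSS, strand, and
    the first intron interval (None for intronless genes)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    first_intron: GenomicInterval | None = None


def place_site_regions(peaks: list[PeakRegion], chrom_sizes: dict[str, int],
                       cfg: SiteBenchmarkConfig | None = None,
                       rng: np.random.Generator | None = None
                       ) -> list[TestRegion]:
    """Place one fixed-length test region uniformly at random around
    each peak.  Regions are clipped into the chromosome by shifting
    inward, preserving the exact region length."""
    cfg = cfg or SiteBenchmarkConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    too_long = [p for p in peaks if p.interval.length > cfg.region_length]
    if too_long:
        raise ValueError(
            "peaks longer than the test region length: "
            + ", ".join(str(p.interval) for p in too_long[:5])
        )
    atypical = sum(1 for p in peaks
                   if not 100 <= p.interval.length <= 400)
    if atypical:
        warnings.warn(
            f"{atypical} peak(s) outside the typical 100-400 bp range"
        )
    regions: list[TestRegion] = []
    for peak in peaks:
        iv = peak.interval
        chrom_size = chrom_sizes[iv.chrom]
        if chrom_size < cfg.region_length:
            raise ValueError(
                f"chromosome {iv.chrom} shorter than the region length"
            )
        upstream = int(rng.integers(0, cfg.region_length - iv.length + 1))
        start = iv.start - upstream
        start = min(max(start, 0), chrom_size - cfg.region_length)
        # clipping may not shift the region off the peak
        start = min(start, iv.start)
        start = max(start, iv.end - cfg.region_length)
        regions.append(
            TestRegion(
                GenomicInterval(iv.chrom, start, start + cfg.region_length),
                peaks=[peak],
                kind="site",
                label=peak.dataset_id,
            )
        )
    return regions


def merge_overlapping(regions: list[TestRegion]) -> list[TestRegion]:
    """Iteratively merge overlapping test regions.

    Two overlapping regions become one region starting at the leftmost
    start, containing all their peaks, with length equal to the sum of
    the two lengths; total benchmark length is conserved exactly.
    """
    out: list[TestRegion] = []
    for region in sorted(regions,
                         key=lambda r: (r.interval.chrom, r.interval.start,
                                        r.interval.end)):
        if out and out[-1].interval.overlaps(region.interval):
            last = out.pop()
            start = last.interval.start
            end = start + last.interval.length + region.interval.length
            merged = TestRegion(
                GenomicInterval(last.interval.chrom, start, end),
                peaks=last.peaks + region.peaks,
                kind=last.kind,
                label=last.label or region.label,
            )
            for p in merged.peaks:
                if not merged.interval.contains(p.interval):
                    raise AssertionError(
                        f"merged region {merged.interval} lost peak "
                        f"{p.interval}"
                    )
            out.append(merged)
        else:
            out.append(TestRegion(region.interval, list(region.peaks),
                                  list(region.negatives), region.kind,
                                  region.label))
    return out


def chunk_negatives(region: TestRegion,
                    mask: list[GenomicInterval] | None = None,
                    chunk_length: int = 200) -> TestRegion:
    """Fill a region's negatives: the non-peak, non-masked gaps cut into
    consecutive chunks of ``chunk_length`` bp from each gap's left edge.

    A terminal remainder of at least half a chunk stands alone; a
    shorter remainder merges into the previous chunk; a gap shorter than
    one chunk stays a single (short) chunk.
    """
    blocked = [p.interval for p in region.peaks]
    if mask:
        blocked += [m for m in mask if m.overlaps(region.interval)]
    negatives: list[GenomicInterval] = []
    c = chunk_length
    for gap in subtract_intervals(region.interval, blocked):
        g = gap.length
        if g <= c:
            negatives.append(gap)
            continue
        n_full, rem = divmod(g, c)
        cuts = [c] * n_full
        if rem >= c / 2:
            cuts.append(rem)
        elif rem:
            cuts[-1] += rem
        pos = gap.start
        for width in cuts:
            negatives.append(GenomicInterval(gap.chrom, pos, pos + width))
            pos += width
    region.negatives = negatives
    return region


def build_site_benchmark(peaks: list[PeakRegion],
                         chrom_sizes: dict[str, int],
                         mask: list[GenomicInterval] | None = None,
                         cfg: SiteBenchmarkConfig | None = None,
                         rng: np.random.Generator | None = None,
                         dataset_id: str = "") -> BenchmarkDataset:
    """Full site benchmark: place, merge, then chunk negatives."""
    cfg = cfg or SiteBenchmarkConfig()
    regions = merge_overlapping(place_site_regions(peaks, chrom_sizes, cfg, rng))
    regions = _clip_into_chromosomes(regions, chrom_sizes)
    for region in regions:
        chunk_negatives(region, mask, cfg.chunk_length)
    return BenchmarkDataset(dataset_id or _infer_id(peaks), regions, cfg)


def _clip_into_chromosomes(regions: list[TestRegion],
                           chrom_sizes: dict[str, int]) -> list[TestRegion]:
    """Shift regions (typically grown by merging) back inside their
    chromosome, preserving length; a region longer than the chromosome
    is truncated with a warning.  Shifting inward cannot evict peaks:
    the shifted span still covers every contained peak."""
    out: list[TestRegion] = []
    for region in regions:
        iv = region.interval
        size = chrom_sizes[iv.chrom]
        if iv.length > size:
            warnings.warn(
                f"region {iv} longer than chromosome; truncating"
            )
            region.interval = GenomicInterval(iv.chrom, 0, size)
        elif iv.end > size:
            region.interval = GenomicInterval(iv.chrom, size - iv.length, size)
        elif iv.start < 0:  # defensive; placement already clips
            region.interval = GenomicInterval(iv.chrom, 0, iv.length)
        out.append(region)
    # a shift can introduce a new overlap with the previous region; merge
    # once more (idempotent when nothing moved) and re-clip lengths
    if any(a.interval.overlaps(b.interval) for a, b in zip(out, out[1:])):
        out = merge_overlapping(out)
        out = _clip_into_chromosomes(out, chrom_sizes)
    return out


def build_promoter_benchmark(genes: list[Gene], peaks: list[PeakRegion],
                             cfg: PromoterBenchmarkConfig | None = None,
                             mask: list[GenomicInterval] | None = None,
                             dataset_id: str = "") -> BenchmarkDataset:
    """Promoter benchmark: per-gene promoter and capped first-intron
    regions, overlap-deduplicated, with peaks mapped in and peak-free
    flanks as undivided negatives."""
    cfg = cfg or PromoterBenchmarkConfig()
    candidates: list[TestRegion] = []
    for gene in genes:
        if gene.strand == "+":
            p_start = gene.tss - cfg.upstream
            p_end = gene.tss + cfg.downstream
        elif gene.strand == "-":
            p_start = gene.tss - cfg.downstream
            p_end = gene.tss + cfg.upstream
        else:
            raise ValueError(f"gene {gene.gene_id}: strand must be + or -")
        if p_start >= 0:
            candidates.append(
                TestRegion(GenomicInterval(gene.chrom, p_start, p_end),
                           kind="promoter", label=gene.gene_id)
            )
        intron = gene.first_intron
        if intron is not None:
            if gene.strand == "+":
                i_start = intron.start
                i_end = min(intron.end, intron.start + cfg.intron_cap)
            else:
                i_end = intron.end
                i_start = max(intron.start, intron.end - cfg.intron_cap)
            candidates.append(
                TestRegion(GenomicInterval(gene.chrom, i_start, i_end),
                           kind="intron", label=gene.gene_id)
            )

    # genes with overlapping promoter/intron regions contribute only one
    # region: keep the first in (chrom, start) order
    kept: list[TestRegion] = []
    for region in sorted(candidates,
                         key=lambda r: (r.interval.chrom, r.interval.start,
                                        r.interval.end)):
        if kept and kept[-1].interval.overlaps(region.interval):
            continue
        kept.append(region)

    # map peaks; partially overlapping peaks extend the region
    for region in kept:
        iv = region.interval
        inside = [p for p in peaks if p.interval.overlaps(iv)]
        if inside:
            start = min(iv.start, min(p.interval.start for p in inside))
            end = max(iv.end, max(p.interval.end for p in inside))
            region.interval = GenomicInterval(iv.chrom, start, end)
            region.peaks = sorted(inside, key=lambda p: p.interval.start)
        blocked = [p.interval for p in region.peaks]
        if mask:
            blocked += [m for m in mask if m.overlaps(region.interval)]
        region.negatives = subtract_intervals(region.interval, blocked)
    return BenchmarkDataset(dataset_id or _infer_id(peaks), kept, cfg)


def _infer_id(peaks: list[PeakRegion]) -> str:
    ids = {p.dataset_id for p in peaks if p.dataset_id}
    return ids.pop() if len(ids) == 1 else "benchmark"


def validate_dataset(dataset: BenchmarkDataset,
                     mask: list[GenomicInterval] | None = None) -> None:
    """Assert the dataset's structural invariants: peaks inside their
    regions, negatives disjoint from peaks and mask, regions disjoint."""
    for region in dataset.regions:
        for p in region.peaks:
            if not region.interval.contains(p.interval):
                raise AssertionError(f"peak {p.interval} outside region")
        for neg in region.negatives:
            for p in region.peaks:
                if neg.overlaps(p.interval):
                    raise AssertionError(f"negative {neg} overlaps a peak")
            for m in mask or []:
                if neg.overlaps(m):
                    raise AssertionError(f"negative {neg} overlaps the mask")
    ivs = sorted((r.interval for r in dataset.regions),
                 key=lambda i: (i.chrom, i.start))
    for a, b in zip(ivs, ivs[1:]):
        if a.overlaps(b):
            raise AssertionError(f"regions {a} and {b} overlap")
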