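"""Readers and writers for the standard formats the toolkit touches.

BED (peaks and regions), MAF alignment blocks, FASTA genomes, JASPAR and
TRANSFAC count matrices, plain-text k-mer lists, newick trees, fixedStep
wiggle conservation tracks, and the benchmark region dialect
(test region + semicolon-separated peak list).

Everything is 0-based half-open internally; 1-based inputs (wiggle,
TRANSFAC position rows) are converted here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, PeakRegion
from .motif_models import BASES, CountMatrix, KmerSet
from .phylo import PhyloTree


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path, dataset_id: str = "") -> list[PeakRegion]:
    """Parse a BED file of peaks; column 5 (if present) is the peak
    tag-count height, missing heights default to 0.  Input order is
    preserved."""
    peaks: list[PeakRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}, line {lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}, line {lineno}: start {start} >= end {end}"
                )
            height = 0.0
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    height = float(fields[4])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}, line {lineno}: non-numeric score column"
                    ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-." else "."
            peaks.append(
                PeakRegion(
                    GenomicInterval(fields[0], start, end, strand),
                    height=height,
                    dataset_id=dataset_id,
                )
            )
    return peaks


def write_bed(peaks: list[PeakRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i + 1}\t"
                f"{p.height:g}\t{iv.strand}\n"
            )


def write_intervals_bed(intervals: list[GenomicInterval], path: str | Path
                        ) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, size = line.split()[:2]
                sizes[name] = int(size)
    return sizes


# ---------------------------------------------------------------------------
# MAF

@dataclass
class MafRecord:
    """One 's' line of a MAF block.  ``start``/``size`` follow MAF
    conventions (strand-relative start); ``text`` is the aligned sequence
    with gap characters, as written in the file."""

    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) > 1 else parts[0]

    @property
    def gapless(self) -> str:
        return self.text.replace("-", "")


@dataclass
class AlignmentBlock:
    """One MAF alignment paragraph: equal-length aligned rows keyed by
    species, plus the designated reference species."""

    records: dict[str, MafRecord]
    reference: str

    def __post_init__(self) -> None:
        lengths = {len(r.text) for r in self.records.values()}
        if len(lengths) > 1:
            raise ValueError("unequal aligned sequence lengths in block")
        if self.reference not in self.records:
            raise ValueError(f"reference species {self.reference!r} not in block")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.records.values())).text)

    @property
    def species(self) -> list[str]:
        return list(self.records)

    @property
    def ref_record(self) -> MafRecord:
        return self.records[self.reference]

    @property
    def ref_interval(self) -> GenomicInterval:
        r = self.ref_record
        return GenomicInterval(r.chrom, r.start, r.start + r.size)

    def ref_columns(self) -> np.ndarray:
        """Alignment column index of each reference base, in order."""
        text = np.frombuffer(self.ref_record.text.encode(), dtype="S1")
        return np.nonzero(text != b"-")[0]


def read_maf(path: str | Path, reference: str | None = None
             ) -> list[AlignmentBlock]:
    """Parse MAF alignment blocks.  The reference species defaults to the
    first 's' record of each block (the UCSC convention)."""
    blocks: list[AlignmentBlock] = []
    current: list[MafRecord] = []

    def flush() -> None:
        if current:
            ref = reference or current[0].species
            blocks.append(
                AlignmentBlock({r.species: r for r in current}, reference=ref)
            )
            current.clear()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("a"):
                flush()
            elif line.startswith("s"):
                fields = line.split()
                if len(fields) != 7:
                    raise ValueError(f"{path}, line {lineno}: malformed s-line")
                _, src, start, size, strand, src_size, text = fields
                current.append(
                    MafRecord(src, int(start), int(size), strand,
                              int(src_size), text)
                )
            # i/e/q and comment lines ignored
    flush()
    return blocks


def write_maf(blocks: list[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write("\na score=0.0\n")
            for rec in block.records.values():
                fh.write(
                    f"s {rec.src} {rec.start} {rec.size} {rec.strand} "
                    f"{rec.src_size} {rec.text}\n"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Motif matrices and k-mer lists

_JASPAR_ROW = re.compile(r"^\s*([ACGT])\s*[|\[]?\s*([-\d.\seE+]+?)\s*\]?\s*$")


def read_motif_matrix(path: str | Path, dialect: str) -> CountMatrix:
    """Read a motif count matrix.

    ``jaspar``: four labelled rows ``A [ 1 2 ... ]`` (brackets optional),
    optionally preceded by a ``>`` header carrying the motif id.
    ``transfac``: position-per-row records between ``P0`` and ``XX``,
    with A C G T columns; the motif id is taken from an ``ID`` or ``AC``
    line when present.
    """
    text = Path(path).read_text()
    if dialect == "jaspar":
        return _parse_jaspar(text, default_id=Path(path).stem)
    if dialect == "transfac":
        return _parse_transfac(text, default_id=Path(path).stem)
    raise ValueError(f"unknown matrix dialect {dialect!r}")


def _parse_jaspar(text: str, default_id: str = "") -> CountMatrix:
    motif_id = default_id
    rows: dict[str, list[float]] = {}
    for line in text.splitlines():
        if line.startswith(">"):
            motif_id = line[1:].split()[0] if line[1:].split() else default_id
            continue
        m = _JASPAR_ROW.match(line)
        if m:
            base, numbers = m.groups()
            try:
                rows[base] = [float(x) for x in numbers.split()]
            except ValueError as exc:
                raise ValueError(f"non-numeric cell in row {base}") from exc
    missing = [b for b in BASES if b not in rows]
    if missing:
        raise ValueError(f"missing base row(s) {missing} in JASPAR matrix")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError("unequal row lengths in JASPAR matrix")
    return CountMatrix(np.array([rows[b] for b in BASES]), motif_id=motif_id)


def _parse_transfac(text: str, default_id: str = "") -> CountMatrix:
    motif_id = default_id
    in_matrix = False
    columns: list[list[float]] = []
    order: list[int] | None = None
    for line in text.splitlines():
        tag = line[:2].strip()
        if tag in ("ID", "AC") and len(line.split()) > 1:
            motif_id = line.split()[1]
        elif tag == "P0" or line.startswith("PO"):
            header = line.split()[1:]
            if len(header) < 4 or any(b not in header for b in BASES):
                raise ValueError("TRANSFAC P0 header must name A C G T columns")
            order = [header.index(b) for b in BASES]
            in_matrix = True
        elif tag == "XX":
            in_matrix = False
        elif in_matrix and line.strip():
            fields = line.split()
            try:
                values = [float(x) for x in fields[1:5]]
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"non-numeric cell in TRANSFAC row {fields[0]!r}"
                ) from exc
            if len(values) < 4:
                raise ValueError(f"short TRANSFAC row {fields[0]!r}")
            columns.append([values[i] for i in order])  # type: ignore[index]
    if not columns:
        raise ValueError("no P0-delimited matrix block found")
    return CountMatrix(np.array(columns).T, motif_id=motif_id)


def read_kmers(path: str | Path, motif_id: str = "") -> KmerSet:
    """Read a plain-text k-mer list, one per line; an optional second
    column gives the multiplicity."""
    kmers: list[str] = []
    counts: list[int] = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            kmers.append(fields[0].upper())
            counts.append(int(fields[1]) if len(fields) > 1 else 1)
    return KmerSet(kmers, counts, motif_id=motif_id or Path(path).stem)


def write_kmers(kmers: KmerSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mer, count in zip(kmers.kmers, kmers.counts):
            fh.write(f"{mer}\t{count}\n" if count != 1 else f"{mer}\n")


# ---------------------------------------------------------------------------
# Newick

def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text().strip())


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# fixedStep wiggle

def read_fixedstep_wig(path: str | Path) -> dict[str, dict[int, float]]:
    """Parse a fixedStep wiggle track into per-chromosome position->value
    maps.  Wiggle is 1-based; positions are converted to 0-based."""
    scores: dict[str, dict[int, float]] = {}
    chrom: str | None = None
    pos = 0
    step = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                params = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
                try:
                    chrom = params["chrom"]
                    pos = int(params["start"]) - 1  # to 0-based
                    step = int(params.get("step", 1))
                except KeyError as exc:
                    raise ValueError(
                        f"{path}, line {lineno}: fixedStep missing {exc}"
                    ) from exc
                scores.setdefault(chrom, {})
            else:
                if chrom is None:
                    raise ValueError(
                        f"{path}, line {lineno}: value before fixedStep header"
                    )
                scores[chrom][pos] = float(line)
                pos += step
    return scores


def write_fixedstep_wig(scores: dict[str, dict[int, float]], path: str | Path
                        ) -> None:
    with open(path, "w") as fh:
        for chrom, values in scores.items():
            run_start = None
            prev = None
            buf: list[float] = []

            def flush() -> None:
                if buf:
                    fh.write(
                        f"fixedStep chrom={chrom} start={run_start + 1} step=1\n"
                    )
                    fh.writelines(f"{v:g}\n" for v in buf)

            for p in sorted(values):
                if prev is None or p != prev + 1:
                    flush()
                    buf = []
                    run_start = p
                buf.append(values[p])
                prev = p
            flush()


# ---------------------------------------------------------------------------
# Benchmark region dialect

def write_benchmark_regions(regions, path: str | Path) -> None:
    """Write benchmark test regions in the semicolon dialect: test region
    coordinates and dataset label, followed by the peak regions therein,
    ``;``-separated."""
    with open(path, "w") as fh:
        for region in regions:
            iv = region.interval
            parts = [f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"{region.label}\t{region.kind}"]
            for p in region.peaks:
                pi = p.interval
                parts.append(f"{pi.chrom}:{pi.start}-{pi.end}:{p.height:g}")
            fh.write(";".join(parts) + "\n")


def read_benchmark_regions(path: str | Path):
    """Read the semicolon benchmark dialect back into TestRegions (with
    peaks; negatives live in the companion BED)."""
    from .benchmark_builder import TestRegion  # local import: avoid cycle

    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            head, *peak_parts = line.split(";")
            fields = head.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}, line {lineno}: malformed region line")
            chrom, start, end, label, kind = fields[:5]
            peaks = []
            for part in peak_parts:
                pchrom, span, height = part.rsplit(":", 2)
                ps, pe = span.split("-")
                peaks.append(
                    PeakRegion(GenomicInterval(pchrom, int(ps), int(pe)),
                               height=float(height), dataset_id=label)
                )
            regions.append(
                TestRegion(GenomicInterval(chrom, int(start), int(end)),
                           peaks=peaks, negatives=[], kind=kind, label=label)
            )
    return regions
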