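"""Phylogeny-aware synthetic fixtures: evolved multi-species sequences
with planted motif sites under purifying selection, strength-linked
ChIP-seq-like peaks, decoy peaks, and a conservation track.

The simulator emulates the statistical structure the benchmark assumes:
a reference genome with motif instances planted at known positions,
orthologous sequences diverged along a phylogeny with planted sites
substituting more slowly than background (purifying selection), peak
intervals centered near planted sites whose tag-count heights correlate
with site strength (and optionally with per-site conservation), decoy
"lesser" peaks supplying an exclusion mask, and a per-base conservation
track computed as cross-species column identity.

Evolution is simulated outward from the reference leaf (the tree is
rerooted there, which is equivalent under the reversible substitution
model), so every planted site's k-mer occurs verbatim at its recorded
reference position and the ground truth stays exact.  Substitution is
single-parameter (Jukes-Cantor style): on a
branch of length t, each background column mutates with probability
1 - exp(-rate * t) to a uniformly chosen different base.  Per branch,
each planted site is frozen with probability equal to its conservation
level; otherwise its columns mutate at the background rate.  Deletions
(when enabled) hit only background columns of non-reference species.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .benchmark_builder import (
    BenchmarkDataset,
    Gene,
    PromoterBenchmarkConfig,
    SiteBenchmarkConfig,
    build_promoter_benchmark,
    build_site_benchmark,
)
from .intervals import GenomicInterval, PeakRegion
from .io_formats import (
    AlignmentBlock,
    MafRecord,
    write_bed,
    write_fasta,
    write_fixedstep_wig,
    write_intervals_bed,
    write_maf,
    write_newick,
)
from .motif_models import BASES, CountMatrix, KmerSet, build_pwm
from .phylo import PhyloTree

#: a small mammal-like tree: reference (hg), two rodents, one outgroup
DEFAULT_TREE = "((hg:0.12,(mm:0.25,rn:0.22):0.18):0.08,canFam:0.45);"


@dataclass
class SimConfig:
    """Synthetic-fixture parameters.

    Defaults describe a single ~20 kb reference chromosome with 30
    planted sites under strong purifying selection (sites frozen on 90%
    of branches), neutral-scale background divergence, and peak heights
    rising with the planted site's PWM score.
    """

    tree_newick: str = DEFAULT_TREE
    ref_species: str = "hg"
    chrom: str = "chrS"
    length: int = 20_000
    background: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    motif: CountMatrix | None = None
    n_sites: int = 30
    site_conservation: float = 0.9
    conservation_jitter: bool = False  # per-site levels ~ U(0,1) * level
    # 1.0 per unit branch length puts the reference-to-rodent divergence
    # near 0.4 substitutions/site on the default tree, the neutral
    # mammalian range; background must diverge for conservation
    # filtering to carry signal
    substitution_rate: float = 1.0
    indel_rate: float = 0.0
    peak_height_base: float = 20.0
    peak_height_slope: float = 5.0
    peak_height_noise_sd: float = 5.0
    height_conservation_slope: float = 0.0
    peak_fraction: float = 1.0
    peak_length_range: tuple[int, int] = (100, 400)
    n_decoy_peaks: int = 10
    maf_block_columns: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("need at least one planted site")
        if not 0 <= self.site_conservation <= 1:
            raise ValueError("site_conservation must be in [0, 1]")
        if min(self.substitution_rate, self.indel_rate) < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.peak_fraction <= 1:
            raise ValueError("peak_fraction must be in [0, 1]")
        if abs(sum(self.background) - 1) > 1e-9:
            raise ValueError("background frequencies must sum to 1")


#: built-in motif counts.  Columns are deliberately irregular (no two
#: cells equal within a column) so PWM scores are near-continuous, as
#: they are for real database matrices; perfectly regular columns
#: produce a coarse score lattice and massive region-maximum ties.
_HIGH_IC_COUNTS = np.array([  # 10 bp, ~1.6 bits/column average
    #  T   G   A   C   G   T   C   A   T   G      (consensus)
    [  2,  1, 94,  1,  2,  1,  3, 92,  1,  2],    # A
    [  1,  2,  2, 95,  1,  2, 93,  3,  2,  1],    # C
    [  3, 95,  3,  2, 96,  3,  2,  1,  3, 94],    # G
    [ 94,  2,  1,  2,  1, 94,  2,  4, 94,  3],    # T
], dtype=float)

_LOW_IC_COUNTS = np.array([  # 8 bp, ~0.45 bits/column average
    #  G   A   T   T   A   C   A   G      (consensus)
    [  5, 24,  7,  6, 26,  8, 23,  4],    # A
    [  7,  5,  4,  8,  3, 22,  6,  6],    # C
    [ 23,  6,  5,  3,  4,  3,  7, 25],    # G
    [  5,  5, 24, 23,  7,  7,  4,  5],    # T
], dtype=float)


def default_motif(avg_ic: str = "high") -> CountMatrix:
    """Built-in test motifs: a 10 bp information-rich motif (average
    column information well above 1 bit) or an 8 bp information-poor one
    (average below 0.8 bits)."""
    if avg_ic == "high":
        return CountMatrix(_HIGH_IC_COUNTS.copy(),
                           motif_id="synthetic-high-ic")
    if avg_ic == "low":
        return CountMatrix(_LOW_IC_COUNTS.copy(), motif_id="synthetic-low-ic")
    raise ValueError(f"unknown built-in motif {avg_ic!r}")


@dataclass
class PlantedSite:
    """Ground truth for one planted motif instance."""

    position: int            # reference 0-based start
    strand: str
    kmer: str                # as planted on the reference forward strand
    conservation: float      # per-site purifying-selection level
    pwm_score: float
    conserved: bool = False  # intact in every leaf after evolution
    peak_index: int | None = None


@dataclass
class SimBundle:
    """A complete synthetic fixture with its ground truth."""

    config: SimConfig
    tree: PhyloTree
    sequences: dict[str, str]            # leaf species -> gap-free sequence
    alignment: list[AlignmentBlock]
    peaks: list[PeakRegion]
    decoys: list[PeakRegion]
    sites: list[PlantedSite]
    phylop: dict[str, dict[int, float]]

    @property
    def reference(self) -> str:
        return self.sequences[self.config.ref_species]

    def mask_intervals(self) -> list[GenomicInterval]:
        return [d.interval for d in self.decoys]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            {f"{sp}.{self.config.chrom}": seq
             for sp, seq in self.sequences.items()},
            outdir / "genomes.fa",
        )
        write_fasta({self.config.chrom: self.reference},
                    outdir / "reference.fa")
        write_maf(self.alignment, outdir / "alignment.maf")
        write_newick(self.tree, outdir / "tree.nwk")
        write_bed(self.peaks, outdir / "peaks.bed")
        write_intervals_bed(self.mask_intervals(), outdir / "mask.bed")
        write_fixedstep_wig(self.phylop, outdir / "phylop.wig")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("position\tstrand\tkmer\tconservation\tpwm_score\t"
                     "conserved\tpeak_index\n")
            for s in self.sites:
                fh.write(
                    f"{s.position}\t{s.strand}\t{s.kmer}\t"
                    f"{s.conservation:.6g}\t{s.pwm_score:.6g}\t"
                    f"{int(s.conserved)}\t"
                    f"{'' if s.peak_index is None else s.peak_index}\n"
                )


def _sample_site_kmer(motif: CountMatrix, rng: np.random.Generator) -> str:
    q = motif.counts / motif.counts.sum(axis=0)
    return "".join(
        BASES[rng.choice(4, p=q[:, j])] for j in range(motif.length)
    )


def sample_kmer_set(motif: CountMatrix, n: int,
                    rng: np.random.Generator) -> KmerSet:
    """Draw ``n`` binding k-mers from a count matrix's column
    distributions, collapsing duplicates into multiplicities — a stand-in
    for a database motif's k-mer list."""
    from collections import Counter

    draws = Counter(_sample_site_kmer(motif, rng) for _ in range(n))
    kmers = sorted(draws)
    return KmerSet(kmers, [draws[m] for m in kmers],
                   motif_id=f"{motif.motif_id}-kmers")


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate(cfg: SimConfig) -> SimBundle:
    """Generate a complete synthetic fixture from a config; the same
    seed yields a byte-identical bundle."""
    rng = np.random.default_rng(cfg.seed)
    motif = cfg.motif or default_motif()
    k = motif.length
    tree = PhyloTree.from_newick(cfg.tree_newick)
    if cfg.ref_species not in tree.leaves:
        raise ValueError(
            f"reference species {cfg.ref_species!r} not a tree leaf"
        )
    bg = np.asarray(cfg.background)
    pwm = build_pwm(motif)

    # --- reference with planted sites -------------------------------------
    ref = rng.choice(4, size=cfg.length, p=bg)
    margin = max(cfg.peak_length_range[1], 50)
    positions = _place_sites(rng, cfg.length, k, cfg.n_sites, margin)
    sites: list[PlantedSite] = []
    site_cols = np.zeros(cfg.length, dtype=bool)
    site_index = np.full(cfg.length, -1)
    for idx, pos in enumerate(positions):
        kmer = _sample_site_kmer(motif, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = kmer if strand == "+" else _revcomp(kmer)
        ref[pos:pos + k] = [BASES.index(b) for b in planted]
        site_cols[pos:pos + k] = True
        site_index[pos:pos + k] = idx
        if cfg.conservation_jitter:
            level = float(rng.uniform(0.0, 1.0)) * cfg.site_conservation
        else:
            level = cfg.site_conservation
        sites.append(PlantedSite(pos, strand, planted, level,
                                 pwm.score_kmer(kmer)))

    # --- evolve along the tree --------------------------------------------
    leaf_rows = _evolve(cfg, tree, ref, sites, site_index, rng)

    for site in sites:
        site.conserved = all(
            np.array_equal(rows[site.position:site.position + k],
                           ref[site.position:site.position + k])
            for rows in leaf_rows.values()
        )

    sequences = {
        sp: "".join(BASES[c] for c in row[row >= 0])
        for sp, row in leaf_rows.items()
    }
    alignment = _to_maf_blocks(cfg, leaf_rows)
    phylop = _identity_track(cfg, ref, leaf_rows)

    # --- peaks and decoys ---------------------------------------------------
    peaks, decoys = _make_peaks(cfg, rng, sites, site_cols)
    return SimBundle(cfg, tree, sequences, alignment, peaks, decoys,
                     sites, phylop)


def _place_sites(rng: np.random.Generator, length: int, k: int,
                 n_sites: int, margin: int) -> list[int]:
    """Non-overlapping site starts, at least one peak-length away from
    the chromosome ends."""
    lo, hi = margin, length - margin - k
    if hi <= lo:
        raise ValueError("reference too short for the requested margin")
    taken: list[int] = []
    for _ in range(10_000):
        if len(taken) == n_sites:
            break
        pos = int(rng.integers(lo, hi))
        if all(abs(pos - t) >= k + 2 for t in taken):
            taken.append(pos)
    if len(taken) < n_sites:
        raise ValueError(
            f"could not place {n_sites} non-overlapping sites in "
            f"{length} bp; increase the reference length"
        )
    return sorted(taken)


def _evolve(cfg: SimConfig, tree: PhyloTree, ref: np.ndarray,
            sites: list[PlantedSite], site_index: np.ndarray,
            rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve the reference sequence outward to the other species.

    The tree is rerooted at the reference leaf, which under the
    reversible substitution model is equivalent to evolving from the
    original root but keeps the reference byte-identical to the planted
    sequence (so the ground truth stays exact).  Rows are column arrays
    over the reference coordinate system; -1 marks a deletion.
    """
    dtree = dendropy.Tree.get(data=cfg.tree_newick, schema="newick",
                              preserve_underscores=True)
    ref_node = next(
        lf for lf in dtree.leaf_node_iter()
        if lf.taxon.label == cfg.ref_species
    )
    if ref_node is not dtree.seed_node:
        dtree.reroot_at_node(ref_node, update_bipartitions=False,
                             suppress_unifurcations=False)
    n = ref.size
    leaf_rows: dict[str, np.ndarray] = {cfg.ref_species: ref.copy()}
    state: dict[int, np.ndarray] = {id(dtree.seed_node): ref.copy()}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = state[id(node.parent_node)]
        t = float(node.edge.length or 0.0)
        seq = parent_seq.copy()
        p_sub = 1.0 - np.exp(-cfg.substitution_rate * t)
        # per-site freezing: frozen sites skip substitution on this branch
        frozen = np.zeros(n, dtype=bool)
        for idx, site in enumerate(sites):
            if rng.random() < site.conservation:
                frozen |= site_index == idx
        alive = seq >= 0
        mutate = alive & ~frozen & (rng.random(n) < p_sub)
        shift = rng.integers(1, 4, size=int(mutate.sum()))
        seq[mutate] = (seq[mutate] + shift) % 4
        if cfg.indel_rate > 0:
            # deletions only, background columns only
            lam = cfg.indel_rate * t * n
            n_del = rng.poisson(lam)
            candidates = np.nonzero(alive & (site_index < 0))[0]
            if n_del > 0 and candidates.size:
                drop = rng.choice(candidates,
                                  size=min(n_del, candidates.size),
                                  replace=False)
                seq[drop] = -1
        state[id(node)] = seq
        label = node.taxon.label if node.taxon is not None else None
        if label is not None and label != cfg.ref_species:
            leaf_rows[label] = seq
    return leaf_rows


def _to_maf_blocks(cfg: SimConfig, leaf_rows: dict[str, np.ndarray]
                   ) -> list[AlignmentBlock]:
    """Cut the columnwise alignment into MAF blocks of at most
    ``maf_block_columns`` reference columns."""
    n = leaf_rows[cfg.ref_species].size
    totals = {sp: int((row >= 0).sum()) for sp, row in leaf_rows.items()}
    offsets = {sp: 0 for sp in leaf_rows}
    blocks: list[AlignmentBlock] = []
    species_order = [cfg.ref_species] + [
        sp for sp in leaf_rows if sp != cfg.ref_species
    ]
    for start in range(0, n, cfg.maf_block_columns):
        end = min(start + cfg.maf_block_columns, n)
        records: dict[str, MafRecord] = {}
        for sp in species_order:
            row = leaf_rows[sp][start:end]
            text = "".join("-" if c < 0 else BASES[c] for c in row)
            size = int((row >= 0).sum())
            records[sp] = MafRecord(
                src=f"{sp}.{cfg.chrom}", start=offsets[sp], size=size,
                strand="+", src_size=totals[sp], text=text,
            )
            offsets[sp] += size
        blocks.append(AlignmentBlock(records, reference=cfg.ref_species))
    return blocks


def _identity_track(cfg: SimConfig, ref: np.ndarray,
                    leaf_rows: dict[str, np.ndarray]
                    ) -> dict[str, dict[int, float]]:
    """Conservation stand-in: per reference column, the fraction of
    aligned non-reference species matching the reference base, rescaled
    to [-1, 1].  Exercises profile and averaging code; it is not a real
    phyloP."""
    others = [row for sp, row in leaf_rows.items() if sp != cfg.ref_species]
    match = np.zeros(ref.size)
    aligned = np.zeros(ref.size)
    for row in others:
        alive = row >= 0
        aligned += alive
        match += alive & (row == ref)
    with np.errstate(invalid="ignore"):
        frac = np.where(aligned > 0, match / np.maximum(aligned, 1), 0.0)
    values = 2.0 * frac - 1.0
    return {cfg.chrom: {i: float(v) for i, v in enumerate(values)}}


def _make_peaks(cfg: SimConfig, rng: np.random.Generator,
                sites: list[PlantedSite], site_cols: np.ndarray
                ) -> tuple[list[PeakRegion], list[PeakRegion]]:
    lo_len, hi_len = cfg.peak_length_range
    peaks: list[PeakRegion] = []
    occupied: list[GenomicInterval] = []
    for idx, site in enumerate(sites):
        if rng.random() >= cfg.peak_fraction:
            continue
        length = int(rng.integers(lo_len, hi_len + 1))
        offset = int(rng.integers(0, length - len(site.kmer) + 1))
        start = max(site.position - offset, 0)
        end = min(start + length, cfg.length)
        height = (cfg.peak_height_base
                  + cfg.peak_height_slope * site.pwm_score
                  + cfg.height_conservation_slope * site.conservation
                  + rng.normal(0.0, cfg.peak_height_noise_sd))
        iv = GenomicInterval(cfg.chrom, start, end)
        peaks.append(PeakRegion(iv, height=max(height, 0.0),
                                dataset_id="sim"))
        site.peak_index = len(peaks) - 1
        occupied.append(iv)
    decoys: list[PeakRegion] = []
    for _ in range(cfg.n_decoy_peaks):
        for _attempt in range(1000):
            length = int(rng.integers(lo_len, hi_len + 1))
            start = int(rng.integers(0, cfg.length - length))
            iv = GenomicInterval(cfg.chrom, start, start + length)
            if (not any(iv.overlaps(o) for o in occupied)
                    and not site_cols[start:start + length].any()):
                decoys.append(PeakRegion(iv, height=0.0, dataset_id="decoy"))
                occupied.append(iv)
                break
    return peaks, decoys


def make_benchmark_fixture(cfg: SimConfig, kind: str = "site",
                           region_length: int = 2000, chunk: int = 200
                           ) -> tuple[SimBundle, BenchmarkDataset]:
    """Simulate, then build a scaled-down benchmark over the emitted
    peaks (default 2 kb regions, 200 bp negative chunks) so the full
    pipeline runs in seconds."""
    bundle = simulate(cfg)
    chrom_sizes = {cfg.chrom: cfg.length}
    mask = bundle.mask_intervals()
    if kind == "site":
        site_cfg = SiteBenchmarkConfig(region_length=region_length,
                                       chunk_length=chunk, seed=cfg.seed + 1)
        dataset = build_site_benchmark(bundle.peaks, chrom_sizes, mask,
                                       site_cfg, dataset_id="sim")
    elif kind == "promoter":
        rng = np.random.default_rng(cfg.seed + 1)
        genes = _fixture_genes(cfg, bundle, rng)
        dataset = build_promoter_benchmark(
            genes, bundle.peaks, PromoterBenchmarkConfig(), mask,
            dataset_id="sim",
        )
    else:
        raise ValueError(f"unknown benchmark kind {kind!r}")
    return bundle, dataset


def _fixture_genes(cfg: SimConfig, bundle: SimBundle,
                   rng: np.random.Generator) -> list[Gene]:
    """Invent plus-strand genes whose promoters cover the simulated
    peaks, plus peak-free genes so the promoter benchmark has clean
    negative regions."""
    genes: list[Gene] = []
    for i, peak in enumerate(bundle.peaks):
        mid = (peak.interval.start + peak.interval.end) // 2
        tss = min(mid + int(rng.integers(50, 150)), cfg.length - 1)
        intron_start = tss + 400
        intron = None
        if intron_start + 500 < cfg.length:
            intron = GenomicInterval(
                cfg.chrom, intron_start,
                min(intron_start + 2000, cfg.length),
            )
        genes.append(Gene(f"gene{i}", cfg.chrom, tss, "+", intron))
    return genes
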