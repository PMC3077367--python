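"""End-to-end glue: run any of the five scoring methods over a
benchmark dataset and evaluate it.

The five methods are ``pwm`` and ``motifscan`` (single-genome), and the
conservation-based ``ws`` (Weighted Sum over a PWM), ``bbls-pwm`` and
``bbls-ms`` (Bayesian branch length score with PWM or MotifScan leaf
scores).
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark_builder import BenchmarkDataset
from .conservation import (
    BblsConfig,
    WsConfig,
    bbls_track,
    calibrate_cutoff,
    percentile_cutoff,
    ws_track,
)
from .evaluation import LabeledScore, RocResult, label_scores, roc_auc
from .intervals import GenomicInterval
from .io_formats import AlignmentBlock
from .motif_models import (
    BaseFrequencies,
    CountMatrix,
    KmerSet,
    SubstitutionMatrix,
    background_from_sequence,
    build_pwm,
    build_substitution_matrix,
)
from .phylo import PhyloTree
from .scanners import MotifScanConfig, ScoreTrack, scan_motifscan, scan_pwm

METHODS = ("pwm", "motifscan", "ws", "bbls-pwm", "bbls-ms")
CONSERVATION_METHODS = ("ws", "bbls-pwm", "bbls-ms")


@dataclass
class MotifResources:
    """Everything needed to score one motif with every method."""

    counts: CountMatrix | None = None
    kmers: KmerSet | None = None
    substitution: SubstitutionMatrix | None = None
    background: BaseFrequencies | None = None
    alpha: float = 1.0
    motifscan_cfg: MotifScanConfig = field(default_factory=MotifScanConfig)

    def __post_init__(self) -> None:
        if self.counts is None and self.kmers is None:
            raise ValueError("need a count matrix or a k-mer set")
        if self.background is None:
            self.background = BaseFrequencies.uniform()
        self.pwm = (build_pwm(self.counts, self.background, self.alpha)
                    if self.counts is not None else None)
        if self.kmers is not None and self.substitution is None:
            self.substitution = build_substitution_matrix([self.kmers])

    def base_scorer(self, which: str) -> Callable[[str], ScoreTrack]:
        if which == "pwm":
            if self.pwm is None:
                raise ValueError("no count matrix for PWM scoring")
            return lambda seq: scan_pwm(seq, self.pwm)
        if which == "motifscan":
            if self.kmers is None:
                raise ValueError("no k-mer set for MotifScan scoring")
            return lambda seq: scan_motifscan(
                seq, self.kmers, self.substitution, self.motifscan_cfg
            )
        raise ValueError(f"unknown base scorer {which!r}")


@dataclass
class GenomeResources:
    """Reference genome plus the comparative inputs the conservation
    methods need."""

    genome: dict[str, str]
    blocks: Sequence[AlignmentBlock] = ()
    tree: PhyloTree | None = None
    ws_cfg: WsConfig = field(default_factory=WsConfig)
    bbls_cfg: BblsConfig = field(default_factory=BblsConfig)

    def blocks_for(self, chrom: str) -> list[AlignmentBlock]:
        return [b for b in self.blocks if b.ref_interval.chrom == chrom]

    def estimate_background(self) -> BaseFrequencies:
        return background_from_sequence("".join(self.genome.values()))


def reference_score_distribution(mres: MotifResources, gres: GenomeResources,
                                 which: str) -> np.ndarray:
    """Genome-wide per-position (strand-combined) scores of the base
    scorer on the reference genome."""
    scorer = mres.base_scorer(which)
    parts = [scorer(seq).best() for seq in gres.genome.values()]
    return np.concatenate(parts) if parts else np.empty(0)


def reference_window_max_distribution(mres: MotifResources,
                                      gres: GenomeResources, which: str,
                                      half_width: int = 15) -> np.ndarray:
    """Genome-wide distribution of the BBLS leaf statistic on the
    reference: for every reference position, the maximum motif score
    (both strands) over the +/- half_width bp window.

    The BBLS percentile cutoff is taken on this distribution, so that
    "the 95th percentile" means 5% of background windows put a leaf
    above the cutoff — the same statistic the species leaves are scored
    with.  A cutoff drawn from the raw per-position distribution would
    be cleared by almost every window maximum and the binary presence
    model would saturate.
    """
    scorer = mres.base_scorer(which)
    parts = []
    for seq in gres.genome.values():
        track = scorer(seq)
        best = track.best()
        if best.size == 0:
            continue
        n = len(seq)
        L = track.motif_length
        pos = np.arange(n)
        starts = np.clip(pos - half_width, 0, None)
        ends = np.clip(pos + half_width - L + 2, 1, best.size)
        parts.append(_sliding_window_max(best, starts, ends))
    return np.concatenate(parts) if parts else np.empty(0)


def _sliding_window_max(values: np.ndarray, starts: np.ndarray,
                        ends: np.ndarray) -> np.ndarray:
    from .conservation import _varying_window_maxima

    return _varying_window_maxima(values, starts, ends)


def region_track(method: str, chrom: str, interval: GenomicInterval,
                 seq: str, mres: MotifResources, gres: GenomeResources,
                 threshold: float | None = None,
                 ref_distribution: np.ndarray | None = None) -> ScoreTrack:
    """Score one region with one method."""
    if method == "pwm":
        return mres.base_scorer("pwm")(seq)
    if method == "motifscan":
        return mres.base_scorer("motifscan")(seq)
    blocks = gres.blocks_for(chrom)
    if method == "ws":
        return ws_track(seq, interval, blocks, mres.base_scorer("pwm"),
                        gres.ws_cfg)
    if method in ("bbls-pwm", "bbls-ms"):
        base = "pwm" if method == "bbls-pwm" else "motifscan"
        if threshold is None:
            raise ValueError("BBLS needs a precomputed percentile cutoff")
        cfg = BblsConfig(
            cutoff_percentile=gres.bbls_cfg.cutoff_percentile,
            leaf_model=gres.bbls_cfg.leaf_model,
            leaf_scorer=base,
            half_width=gres.bbls_cfg.half_width,
        )
        if gres.tree is None:
            raise ValueError("BBLS needs a phylogenetic tree")
        return bbls_track(seq, interval, blocks, gres.tree,
                          mres.base_scorer(base), threshold, cfg,
                          ref_distribution=ref_distribution)
    raise ValueError(f"unknown method {method!r}")


def score_dataset(method: str, dataset: BenchmarkDataset,
                  mres: MotifResources, gres: GenomeResources,
                  threshold: float | None = None,
                  ref_distribution: np.ndarray | None = None
                  ) -> dict[str, ScoreTrack]:
    """Per-region score tracks for one method over a benchmark."""
    if method in ("bbls-pwm", "bbls-ms") and threshold is None:
        base = "pwm" if method == "bbls-pwm" else "motifscan"
        if ref_distribution is None:
            ref_distribution = reference_window_max_distribution(
                mres, gres, base, gres.bbls_cfg.half_width
            )
        threshold = percentile_cutoff(ref_distribution,
                                      gres.bbls_cfg.cutoff_percentile)
    tracks: dict[str, ScoreTrack] = {}
    for region in dataset.regions:
        iv = region.interval
        seq = gres.genome[iv.chrom][iv.start:iv.end]
        track = region_track(method, iv.chrom, iv, seq, mres, gres,
                             threshold, ref_distribution)
        track.seq_id = region.region_id
        tracks[region.region_id] = track
    return tracks


def evaluate_dataset(method: str, dataset: BenchmarkDataset,
                     mres: MotifResources, gres: GenomeResources,
                     threshold: float | None = None,
                     ref_distribution: np.ndarray | None = None
                     ) -> tuple[RocResult, list[LabeledScore]]:
    tracks = score_dataset(method, dataset, mres, gres, threshold,
                           ref_distribution)
    labels = label_scores(dataset, tracks)
    return roc_auc(labels), labels


def evaluate_all_methods(dataset: BenchmarkDataset, mres: MotifResources,
                         gres: GenomeResources,
                         methods: Sequence[str] = METHODS) -> pd.DataFrame:
    """ROC / ROC-50 table (one row per method) for one benchmark."""
    rows = []
    for method in methods:
        result, _ = evaluate_dataset(method, dataset, mres, gres)
        rows.append({
            "method": method,
            "auc": result.auc,
            "roc50": result.roc50,
            "n_positives": result.n_positives,
            "n_negatives": result.n_negatives,
        })
    return pd.DataFrame(rows).set_index("method")


def calibrate_bbls_percentile(datasets: Sequence[BenchmarkDataset],
                              mres: MotifResources, gres: GenomeResources,
                              grid: Sequence[float] = (50, 75, 90, 95, 99),
                              base: str = "pwm"):
    """Grid-search the BBLS cutoff percentile on calibration datasets,
    maximizing mean ROC (ties to higher ROC-50, then higher
    percentile)."""
    ref_dist = reference_window_max_distribution(mres, gres, base,
                                                 gres.bbls_cfg.half_width)
    method = "bbls-pwm" if base == "pwm" else "bbls-ms"

    def evaluate(dataset: BenchmarkDataset, q: float) -> tuple[float, float]:
        threshold = percentile_cutoff(ref_dist, q)
        result, _ = evaluate_dataset(method, dataset, mres, gres,
                                     threshold, ref_dist)
        return result.auc, result.roc50

    return calibrate_cutoff(datasets, evaluate, grid)
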