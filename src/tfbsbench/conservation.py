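"""Conservation-based scoring: Weighted Sum and the Bayesian branch
length score (BBLS), over multi-species alignment blocks.

Weighted Sum (WS) adds, to the reference-genome motif score at each
position, a weighted maximum of the motif score in each aligned species'
window (15 bp up- and downstream of the reference position, gaps
removed).  BBLS converts per-species window maxima into motif-presence
probabilities at the tree leaves via a percentile cutoff, then computes
the expected branch length of the phylogenetic subtree spanned by the
species carrying the motif, under independent leaf presence:

    BBLS = sum_b l(b) * (1 - prod_{i in A(b)} (1 - p_i))
                      * (1 - prod_{i in B(b)} (1 - p_i))

where each edge ``b`` splits the (unrooted) tree's leaves into sides
``A(b)`` and ``B(b)``.  This equals E[BLS] over all 2^n leaf presence
configurations.  The reference leaf always has p = 1, since scoring is
anchored at a concrete reference position.

Species windows are anchored by alignment columns, not by independent
coordinate arithmetic, so indels shift windows correctly.  Positions
without alignment coverage score 0 (never NaN), keeping region maxima
well-defined.
"""

from __future__ import annotations

from collections import deque
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AlignmentBlock
from .intervals import GenomicInterval
from .phylo import PhyloTree
from .scanners import ScoreTrack


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class WsConfig:
    """Weighted Sum parameters.

    ``default_weight`` applies to every non-reference species unless
    overridden in ``weights``; the default 0.25 per species means the
    added conservation term is half the mean of two species' window
    maxima, so the reference score dominates.  ``half_width`` is the
    window reach in bp on each side of the reference position.
    """

    default_weight: float = 0.25
    weights: dict[str, float] = field(default_factory=dict)
    half_width: int = 15

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("window half-width must be >= 0")
        if self.default_weight < 0 or any(w < 0 for w in self.weights.values()):
            raise ValueError("species weights must be >= 0")

    def weight_for(self, species: str) -> float:
        return self.weights.get(species, self.default_weight)


@dataclass
class BblsConfig:
    """BBLS parameters: cutoff percentile ``q`` of the reference-species
    score distribution, the leaf probability model, and which scanner
    supplies leaf scores."""

    cutoff_percentile: float = 95.0
    # "soft" (percentile-rank presence probabilities) is the default:
    # branch lengths are weighted by a continuous probability, the
    # Bayesian reading; "binary" is the hard cutoff-gating variant
    leaf_model: str = "soft"
    leaf_scorer: str = "pwm"
    half_width: int = 15

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_percentile < 100:
            raise ValueError("cutoff percentile must be in (0, 100)")
        if self.leaf_model not in ("binary", "soft"):
            raise ValueError("leaf model must be 'binary' or 'soft'")
        if self.leaf_scorer not in ("pwm", "motifscan"):
            raise ValueError("leaf scorer must be 'pwm' or 'motifscan'")


# ---------------------------------------------------------------------------
# Alignment window projection

def project_species_window(block: AlignmentBlock, ref_pos: int, h: int
                           ) -> dict[str, str]:
    """Gap-free per-species window around a reference genomic position.

    The alignment columns spanning reference positions ``ref_pos - h ..
    ref_pos + h`` (clipped to the block) are extracted for each species
    and gaps removed.  Species whose rows are entirely gaps in the
    window yield empty strings.
    """
    ref_iv = block.ref_interval
    if not ref_iv.start <= ref_pos < ref_iv.end:
        raise ValueError(
            f"reference position {ref_pos} outside block {ref_iv}"
        )
    ref_cols = block.ref_columns()
    r = ref_pos - ref_iv.start
    c_lo = int(ref_cols[max(r - h, 0)])
    c_hi = int(ref_cols[min(r + h, len(ref_cols) - 1)])
    return {
        sp: rec.text[c_lo:c_hi + 1].replace("-", "")
        for sp, rec in block.records.items()
    }


def _varying_window_maxima(values: np.ndarray, starts: np.ndarray,
                           ends: np.ndarray) -> np.ndarray:
    """Sliding maxima of ``values`` over windows ``[starts[r], ends[r])``
    with both bounds non-decreasing; empty windows give -inf."""
    out = np.full(starts.size, -np.inf)
    dq: deque[int] = deque()
    j = 0
    for r in range(starts.size):
        e = min(int(ends[r]), values.size)
        while j < e:
            while dq and values[dq[-1]] <= values[j]:
                dq.pop()
            dq.append(j)
            j += 1
        while dq and dq[0] < starts[r]:
            dq.popleft()
        if dq and dq[0] < e:
            out[r] = values[dq[0]]
    return out


def species_window_maxima(block: AlignmentBlock, species: str,
                          species_scores: np.ndarray, h: int, L: int
                          ) -> np.ndarray:
    """Per-reference-position maximum of a species' motif scores over
    the +/- h bp window.

    ``species_scores`` are the species' per-position (strand-combined)
    scores on its gap-free block text.  Returns one value per reference
    base of the block; positions whose window holds no complete motif
    give -inf.
    """
    rec = block.records[species]
    ref_cols = block.ref_columns()
    n = ref_cols.size
    gaps = np.frombuffer(rec.text.encode(), dtype="S1") != b"-"
    prefix = np.concatenate([[0], np.cumsum(gaps)])  # non-gaps before col
    r = np.arange(n)
    c_lo = ref_cols[np.maximum(r - h, 0)]
    c_hi = ref_cols[np.minimum(r + h, n - 1)]
    starts = prefix[c_lo]
    ends = prefix[c_hi + 1] - L + 1  # last valid motif start, exclusive
    return _varying_window_maxima(species_scores, starts, ends)


# ---------------------------------------------------------------------------
# Weighted Sum

def ws_score(ref_track: ScoreTrack,
             species_maxima: Mapping[str, np.ndarray],
             cfg: WsConfig | None = None) -> ScoreTrack:
    """Combine a reference track with per-species window maxima:
    ``WS(i) = S_ref(i) + sum_s w_s * max_s(i)``.  Entries of -inf (no
    window) contribute 0.  The conservation term is strandless and is
    added to both strand tracks."""
    cfg = cfg or WsConfig()
    bonus = np.zeros(len(ref_track))
    for sp, maxima in species_maxima.items():
        contrib = np.where(np.isfinite(maxima), maxima, 0.0)
        bonus += cfg.weight_for(sp) * contrib
    return ScoreTrack(ref_track.seq_id, ref_track.motif_length,
                      ref_track.fwd + bonus, ref_track.rev + bonus,
                      method=f"ws-{ref_track.method}")


def ws_track(seq: str, interval: GenomicInterval,
             blocks: Sequence[AlignmentBlock],
             scorer: Callable[..., ScoreTrack],
             cfg: WsConfig | None = None, seq_id: str = "") -> ScoreTrack:
    """Weighted Sum track over a reference region.

    ``scorer(sequence)`` must return a ScoreTrack (e.g. a bound PWM or
    MotifScan scanner).  Positions with no alignment coverage keep the
    plain reference score.
    """
    cfg = cfg or WsConfig()
    ref_track = scorer(seq)
    maxima = _collect_species_maxima(
        seq, interval, blocks, scorer, cfg.half_width, ref_track.motif_length,
        len(ref_track), exclude_reference=True,
    )
    track = ws_score(ref_track, maxima, cfg)
    track.seq_id = seq_id or ref_track.seq_id
    return track


def _collect_species_maxima(seq: str, interval: GenomicInterval,
                            blocks: Sequence[AlignmentBlock],
                            scorer: Callable[..., ScoreTrack],
                            h: int, L: int, n_positions: int,
                            exclude_reference: bool = True,
                            restrict_species: set[str] | None = None
                            ) -> dict[str, np.ndarray]:
    """Per-species arrays of window maxima over ``n_positions`` motif
    start positions of the region; -inf where a species has no usable
    window."""
    out: dict[str, np.ndarray] = {}
    for block in blocks:
        biv = block.ref_interval
        if biv.chrom != interval.chrom or not biv.overlaps(interval):
            continue
        lo = max(biv.start, interval.start)
        hi = min(biv.end, interval.start + n_positions)
        if lo >= hi:
            continue
        for sp, rec in block.records.items():
            if exclude_reference and sp == block.reference:
                continue
            if restrict_species is not None and sp not in restrict_species:
                continue
            gapless = rec.gapless
            if len(gapless) < L:
                continue
            sp_scores = scorer(gapless).best()
            block_max = species_window_maxima(block, sp, sp_scores, h, L)
            arr = out.setdefault(sp, np.full(n_positions, -np.inf))
            sl_out = slice(lo - interval.start, hi - interval.start)
            sl_blk = slice(lo - biv.start, hi - biv.start)
            np.maximum(arr[sl_out], block_max[sl_blk], out=arr[sl_out])
    return out


# ---------------------------------------------------------------------------
# BBLS

def percentile_cutoff(scores: np.ndarray, q: float) -> float:
    """q-th percentile (linear interpolation) of a score distribution,
    normally the reference genome-wide per-position scores of the
    motif."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score distribution")
    if not 0 < q < 100:
        raise ValueError("percentile must be in (0, 100)")
    return float(np.percentile(scores, q))


def leaf_probabilities(species_best_scores: Mapping[str, float | None],
                       threshold: float, ref_species: str,
                       model: str = "binary",
                       ref_distribution: np.ndarray | None = None
                       ) -> dict[str, float]:
    """Motif-presence probability per tree leaf.

    ``binary``: 1 when the species' best window score reaches the
    threshold (ties count as present), else 0.  ``soft``: the score's
    empirical percentile rank within the reference score distribution.
    Unaligned leaves (score None) get 0; the reference leaf is always 1.
    """
    if ref_species not in species_best_scores:
        raise ValueError(f"reference species {ref_species!r} missing")
    if model == "soft":
        if ref_distribution is None:
            raise ValueError("soft model needs the reference distribution")
        sorted_ref = np.sort(np.asarray(ref_distribution, dtype=float))
    p: dict[str, float] = {}
    for sp, score in species_best_scores.items():
        if sp == ref_species:
            p[sp] = 1.0
        elif score is None or not np.isfinite(score):
            p[sp] = 0.0
        elif model == "binary":
            p[sp] = 1.0 if score >= threshold else 0.0
        else:
            rank = np.searchsorted(sorted_ref, score, side="right")
            p[sp] = float(np.clip(rank / sorted_ref.size, 0.0, 1.0))
    return p


def bbls(tree: PhyloTree, p: Mapping[str, float]) -> float:
    """Bayesian branch length score for one set of leaf probabilities."""
    missing = [lf for lf in tree.leaves if lf not in p]
    if missing:
        raise ValueError(f"missing leaf probabilities for {missing}")
    vec = np.array([p[lf] for lf in tree.leaves], dtype=float)
    if np.any(vec < 0) or np.any(vec > 1):
        raise ValueError("leaf probabilities must lie in [0, 1]")
    return float(bbls_many(tree, vec[None, :])[0])


def bbls_many(tree: PhyloTree, P: np.ndarray) -> np.ndarray:
    """Vectorized BBLS for a (n_cases, n_leaves) probability matrix,
    leaf columns in ``tree.leaves`` order."""
    one_minus = 1.0 - np.asarray(P, dtype=float)
    out = np.zeros(one_minus.shape[0])
    for mask, length in zip(tree.edge_masks, tree.edge_lengths):
        if length == 0.0:
            continue
        q_child = one_minus[:, mask].prod(axis=1)
        q_other = one_minus[:, ~mask].prod(axis=1)
        out += length * (1.0 - q_child) * (1.0 - q_other)
    return out


def bbls_track(seq: str, interval: GenomicInterval,
               blocks: Sequence[AlignmentBlock], tree: PhyloTree,
               scorer: Callable[..., ScoreTrack], threshold: float,
               cfg: BblsConfig | None = None,
               ref_distribution: np.ndarray | None = None,
               seq_id: str = "") -> ScoreTrack:
    """BBLS score per reference position of a region.

    For each position, every aligned species' window (+/- 15 bp, gaps
    removed) is scored with ``scorer``; window maxima become leaf
    probabilities against ``threshold`` and feed the BBLS.  The score is
    strandless and reported identically on both strands.  Positions
    without alignment coverage score 0.
    """
    cfg = cfg or BblsConfig()
    ref_species = _reference_species(blocks, interval)
    ref_track = scorer(seq)
    n = len(ref_track)
    L = ref_track.motif_length
    if n == 0:
        return ScoreTrack(seq_id, L, np.empty(0), np.empty(0), method="bbls")

    tree_leaves = set(tree.leaves)
    if ref_species is not None and blocks:
        aligned_species = set().union(*(set(b.records) for b in blocks))
        missing = sorted(tree_leaves - aligned_species)
        if missing:
            raise ValueError(
                f"tree leaves absent from the alignment: {missing}"
            )

    maxima = _collect_species_maxima(
        seq, interval, blocks, scorer, cfg.half_width, L, n,
        exclude_reference=True, restrict_species=tree_leaves,
    )

    P = np.zeros((n, tree.n_leaves))
    if cfg.leaf_model == "soft":
        if ref_distribution is None:
            raise ValueError("soft leaf model needs the reference distribution")
        sorted_ref = np.sort(np.asarray(ref_distribution, dtype=float))
    for i, leaf in enumerate(tree.leaves):
        if leaf == ref_species:
            P[:, i] = 1.0
            continue
        arr = maxima.get(leaf)
        if arr is None:
            continue
        finite = np.isfinite(arr)
        if cfg.leaf_model == "binary":
            P[finite, i] = (arr[finite] >= threshold).astype(float)
        else:
            ranks = np.searchsorted(sorted_ref, arr[finite], side="right")
            P[finite, i] = np.clip(ranks / sorted_ref.size, 0.0, 1.0)

    scores = bbls_many(tree, P)
    return ScoreTrack(seq_id, L, scores, scores.copy(), method="bbls")


def _reference_species(blocks: Sequence[AlignmentBlock],
                       interval: GenomicInterval) -> str | None:
    for block in blocks:
        if block.ref_interval.chrom == interval.chrom:
            return block.reference
    return blocks[0].reference if blocks else None


# ---------------------------------------------------------------------------
# Cutoff calibration

DEFAULT_PERCENTILE_GRID = (50.0, 75.0, 90.0, 95.0, 99.0)


@dataclass
class CalibrationResult:
    best_percentile: float
    table: pd.DataFrame


def calibrate_cutoff(benchmarks: Sequence,
                     evaluate: Callable[[object, float], tuple[float, float]],
                     grid: Sequence[float] = DEFAULT_PERCENTILE_GRID
                     ) -> CalibrationResult:
    """Pick the cutoff percentile maximizing mean ROC AUC over the
    calibration datasets.

    ``evaluate(benchmark, percentile)`` must return (ROC AUC, ROC-50)
    for one dataset at one percentile.  Ties on mean ROC break toward
    higher mean ROC-50, then toward the higher percentile.
    """
    if not list(grid):
        raise ValueError("empty percentile grid")
    if not list(benchmarks):
        raise ValueError("no calibration benchmarks")
    rows = []
    for q in grid:
        results = [evaluate(b, q) for b in benchmarks]
        rows.append({
            "percentile": float(q),
            "mean_roc": float(np.mean([r[0] for r in results])),
            "mean_roc50": float(np.mean([r[1] for r in results])),
        })
    table = pd.DataFrame(rows)
    best = max(rows, key=lambda r: (r["mean_roc"], r["mean_roc50"],
                                    r["percentile"]))
    return CalibrationResult(best["percentile"], table)
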