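"""Region labelling, ROC / ROC-50 scoring, peak-height stratification,
and the benchmark's summary statistics.

Each test region contributes its maximum score: one positive label per
peak, one negative label per negative subregion.  The ROC is computed
with a conservative tie policy — at equal scores all negatives are
counted before any positive — so a method that saturates its maximum
score on many regions is penalized rather than flattered.  The ROC-50
curve stops counting positives after the 50 highest-scoring negatives,
measuring early-retrieval specificity.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark_builder import BenchmarkDataset, TestRegion
from .scanners import ScoreTrack


@dataclass
class LabeledScore:
    score: float
    positive: bool
    region_id: str = ""
    height: float | None = None


@dataclass
class RocResult:
    auc: float
    roc50: float
    n_positives: int
    n_negatives: int
    curve: np.ndarray | None = None  # (k, 2) FPR, TPR points


@dataclass
class StratifyConfig:
    low_percentile: float = 10.0
    high_percentile: float = 90.0

    def __post_init__(self) -> None:
        if not 0 < self.low_percentile < self.high_percentile < 100:
            raise ValueError("need 0 < low < high < 100")


# ---------------------------------------------------------------------------
# Labelling

def _region_max(track: ScoreTrack, region_start: int,
                sub: "TestRegion | object") -> float:
    """Maximum score (both strands) of motif windows starting inside a
    subinterval, track coordinates anchored at ``region_start``."""
    lo = max(sub.start - region_start, 0)
    hi = min(sub.end - region_start, len(track))
    if lo >= hi:
        return -math.inf
    window = np.maximum(track.fwd[lo:hi], track.rev[lo:hi])
    return float(window.max())


def label_scores(dataset: BenchmarkDataset,
                 tracks: Mapping[str, ScoreTrack]) -> list[LabeledScore]:
    """One positive label per peak (max score over positions and strands
    inside the peak), one negative label per negative subregion."""
    labels: list[LabeledScore] = []
    for region in dataset.regions:
        track = tracks.get(region.region_id)
        if track is None:
            raise ValueError(f"no score track covers region {region.region_id}")
        expected = region.interval.length - track.motif_length + 1
        if len(track) != expected:
            raise ValueError(
                f"track for {region.region_id} has {len(track)} positions, "
                f"expected {expected}"
            )
        start = region.interval.start
        for peak in region.peaks:
            labels.append(LabeledScore(
                _region_max(track, start, peak.interval), True,
                region.region_id, height=peak.height,
            ))
        for neg in region.negatives:
            score = _region_max(track, start, neg)
            if not math.isfinite(score):
                warnings.warn(
                    f"negative {neg} shorter than the motif; skipped"
                )
                continue
            labels.append(LabeledScore(score, False, region.region_id))
    return labels


# ---------------------------------------------------------------------------
# ROC

def _split_scores(labels: Sequence[LabeledScore]
                  ) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([l.score for l in labels if l.positive], dtype=float)
    neg = np.array([l.score for l in labels if not l.positive], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    return pos, neg


def roc_auc(labels: Sequence[LabeledScore],
            tie_policy: str = "negatives_first",
            truncate_negatives: int = 50,
            with_curve: bool = False) -> RocResult:
    """Area under the ROC curve.

    ``negatives_first`` (the benchmark's conservative policy): within a
    tied score all negatives precede all positives, so the AUC equals
    the fraction of (positive, negative) pairs where the positive is
    strictly greater.  ``midrank``: cross-class ties count half (the
    usual Mann-Whitney convention).
    """
    pos, neg = _split_scores(labels)
    neg_sorted = np.sort(neg)
    greater = np.searchsorted(neg_sorted, pos, side="left")
    if tie_policy == "negatives_first":
        wins = greater.sum()
    elif tie_policy == "midrank":
        ge = np.searchsorted(neg_sorted, pos, side="right")
        wins = greater.sum() + 0.5 * (ge - greater).sum()
    else:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    auc = float(wins) / (pos.size * neg.size)
    r50 = _roc50(pos, neg_sorted, truncate_negatives)
    curve = _roc_curve_points(pos, neg) if with_curve else None
    return RocResult(auc, r50, pos.size, neg.size, curve)


def _roc50(pos: np.ndarray, neg_sorted: np.ndarray, n_trunc: int) -> float:
    """Truncated ROC area: curve cut after the ``n_trunc`` highest
    negatives (negatives-first ties), normalized by n_trunc * P so a
    method ranking all positives above the top negatives scores 1."""
    N = neg_sorted.size
    k = min(n_trunc, N)
    # score of the k-th highest negative; with negatives-first ties a
    # positive is counted before the j-th negative iff it is strictly
    # greater than that negative's score
    top_neg = neg_sorted[N - k:]  # ascending, the k highest
    # area in grid units = sum over the k counted negatives of the
    # number of positives strictly above each
    area = 0.0
    for neg_score in top_neg:
        area += np.count_nonzero(pos > neg_score)
    return float(area) / (k * pos.size)


def roc50(labels: Sequence[LabeledScore], n_trunc: int = 50) -> float:
    pos, neg = _split_scores(labels)
    return _roc50(pos, np.sort(neg), n_trunc)


def _roc_curve_points(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    order = sorted(
        [(s, 1) for s in pos] + [(s, 0) for s in neg],
        key=lambda t: (-t[0], t[1]),  # descending score, negatives first
    )
    tp = fp = 0
    points = [(0.0, 0.0)]
    for _, is_pos in order:
        if is_pos:
            tp += 1
        else:
            fp += 1
        points.append((fp / neg.size, tp / pos.size))
    return np.array(points)


# ---------------------------------------------------------------------------
# Peak-height stratification

def stratify_by_height(dataset: BenchmarkDataset,
                       cfg: StratifyConfig | None = None
                       ) -> tuple[BenchmarkDataset, BenchmarkDataset]:
    """Split positives into peaks strictly below the 10th / strictly
    above the 90th height percentile (linear interpolation); negatives
    are retained unchanged in both strata."""
    cfg = cfg or StratifyConfig()
    heights = np.array([p.height for p in dataset.peaks], dtype=float)
    if heights.size == 0:
        raise ValueError("dataset has no peaks")
    lo_thr = np.percentile(heights, cfg.low_percentile)
    hi_thr = np.percentile(heights, cfg.high_percentile)

    def select(keep) -> BenchmarkDataset:
        regions = []
        for region in dataset.regions:
            kept = [p for p in region.peaks if keep(p.height)]
            regions.append(TestRegion(region.interval, kept,
                                      list(region.negatives), region.kind,
                                      region.label))
        sub = BenchmarkDataset(dataset.dataset_id, regions, dataset.config)
        if sub.n_positives == 0:
            raise ValueError(
                "empty height stratum (peak heights too uniform)"
            )
        return sub

    return select(lambda h: h < lo_thr), select(lambda h: h > hi_thr)


# ---------------------------------------------------------------------------
# Method comparison statistics

def median_mad(values: Sequence[float]) -> tuple[float, float]:
    """Median and (unscaled) median absolute deviation."""
    arr = np.asarray(values, dtype=float)
    med = float(np.median(arr))
    return med, float(np.median(np.abs(arr - med)))


def wilcoxon_one_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """One-sided exact Wilcoxon signed-rank p-value for paired samples,
    testing whether ``x`` tends to exceed ``y``.  Zero differences are
    dropped (Wilcoxon's original convention); all-zero differences give
    p = 1 by convention."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    res = stats.wilcoxon(d, alternative="greater", zero_method="wilcox",
                         method="exact" if d.size <= 25 else "auto")
    return float(res.pvalue)


def compare_methods(auc_table: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize a methods x datasets AUC table.

    Returns (per-method median/MAD summary, pairwise one-sided Wilcoxon
    signed-rank p-values; entry (a, b) tests a > b).
    """
    if auc_table.isna().any().any():
        raise ValueError("AUC table has missing cells")
    if auc_table.shape[0] < 2 or auc_table.shape[1] < 2:
        raise ValueError("need >= 2 methods and >= 2 datasets")
    summary = pd.DataFrame(
        [(m, *median_mad(auc_table.loc[m])) for m in auc_table.index],
        columns=["method", "median", "mad"],
    ).set_index("method")
    methods = list(auc_table.index)
    pvals = pd.DataFrame(np.ones((len(methods), len(methods))),
                         index=methods, columns=methods)
    for a in methods:
        for b in methods:
            if a != b:
                pvals.loc[a, b] = wilcoxon_one_sided(
                    auc_table.loc[a], auc_table.loc[b]
                )
    return summary, pvals


def spearman(x: Sequence[float], y: Sequence[float]
             ) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value comes from the exact permutation distribution
    for n <= 10 and from the t approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman undefined for a constant vector")
    rho, p_t = stats.spearmanr(x, y)
    n = x.size
    if n > 10:
        return float(rho), float(p_t)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    target = abs(rho) - 1e-12
    hits = total = 0
    perm_iter = permutations(range(n))
    chunk: list[tuple[int, ...]] = []
    for perm in perm_iter:
        chunk.append(perm)
        if len(chunk) == 100_000:
            hits += _count_extreme(rx_c, ry_c, chunk, denom, target)
            total += len(chunk)
            chunk = []
    if chunk:
        hits += _count_extreme(rx_c, ry_c, chunk, denom, target)
        total += len(chunk)
    return float(rho), hits / total


def _count_extreme(rx_c: np.ndarray, ry_c: np.ndarray,
                   perms: list[tuple[int, ...]], denom: float,
                   target: float) -> int:
    mat = ry_c[np.array(perms)]
    rhos = (mat @ rx_c) / denom
    return int(np.count_nonzero(np.abs(rhos) >= target))


# ---------------------------------------------------------------------------
# Positional profiles

def positional_profile(peaks, chrom_scores: Mapping[str, np.ndarray],
                       phylop: Mapping[str, Mapping[int, float]],
                       flank: int = 250
                       ) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Profiles over a ``2 * flank`` bp window centered on each peak
    midpoint.

    Returns (histogram of the argmax-score offset, ties to the leftmost;
    per-offset mean conservation; per-peak mean conservation over the
    window, for the low/high peak comparison).  ``chrom_scores`` maps a
    chromosome to its per-position (strand-combined) motif scores.
    Peaks whose window exceeds the scored sequence are skipped with a
    warning.
    """
    width = 2 * flank
    histogram = np.zeros(width)
    cons_sum = np.zeros(width)
    cons_count = np.zeros(width)
    per_peak_means: list[float] = []
    for peak in peaks:
        iv = peak.interval
        mid = (iv.start + iv.end) // 2
        lo = mid - flank
        scores = chrom_scores.get(iv.chrom)
        if scores is None or lo < 0 or lo + width > scores.size:
            warnings.warn(f"window around {iv} out of bounds; peak skipped")
            continue
        window = scores[lo:lo + width]
        histogram[int(np.argmax(window))] += 1
        track = phylop.get(iv.chrom, {})
        vals = np.array([track.get(p, np.nan) for p in range(lo, lo + width)])
        present = ~np.isnan(vals)
        cons_sum[present] += vals[present]
        cons_count[present] += 1
        if present.any():
            per_peak_means.append(float(vals[present].mean()))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_cons = np.where(cons_count > 0, cons_sum / cons_count, np.nan)
    return histogram, mean_cons, per_peak_means
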