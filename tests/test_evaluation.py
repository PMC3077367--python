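"""ROC / ROC-50 with the negatives-first tie policy, stratification,
Wilcoxon and Spearman statistics, positional profiles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tfbsbench.benchmark_builder import BenchmarkDataset, TestRegion
from tfbsbench.evaluation import (
    LabeledScore,
    StratifyConfig,
    compare_methods,
    label_scores,
    median_mad,
    positional_profile,
    roc50,
    roc_auc,
    spearman,
    stratify_by_height,
    wilcoxon_one_sided,
)
from tfbsbench.intervals import GenomicInterval, PeakRegion
from tfbsbench.scanners import ScoreTrack


def labels_from(pos, neg):
    return ([LabeledScore(s, True) for s in pos]
            + [LabeledScore(s, False) for s in neg])


# ---------------------------------------------------------------------------
# Independent oracles

def auc_pair_oracle(pos, neg):
    """Strict pair counting: ties never credit the positive."""
    wins = sum(1 for p in pos for n in neg if p > n)
    return wins / (len(pos) * len(neg))


def roc50_order_oracle(pos, neg, n_trunc=50):
    """Walk the sorted label list (negatives first within ties), stop
    after n_trunc negatives, accumulate the step-curve area."""
    order = sorted([(s, 1) for s in pos] + [(s, 0) for s in neg],
                   key=lambda t: (-t[0], t[1]))
    k = min(n_trunc, len(neg))
    area = tp = negs = 0
    for _, is_pos in order:
        if is_pos:
            tp += 1
        else:
            negs += 1
            area += tp
            if negs == k:
                break
    return area / (k * len(pos))


def random_instance(rng, max_labels=60):
    n = int(rng.integers(4, max_labels + 1))
    n_pos = int(rng.integers(1, n))
    scores = rng.integers(0, 12, size=n).astype(float)  # ties guaranteed
    return scores[:n_pos], scores[n_pos:]


# ---------------------------------------------------------------------------
# ROC

def test_perfect_separation_auc_one():
    res = roc_auc(labels_from([5, 6], [1, 2, 3]))
    assert res.auc == 1.0
    assert res.roc50 == 1.0


def test_all_tied_scores_auc_zero():
    res = roc_auc(labels_from([2, 2], [2, 2, 2]))
    assert res.auc == 0.0


def test_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([LabeledScore(1.0, True)])


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        pos, neg = random_instance(rng, 40)
        res = roc_auc(labels_from(pos, neg))
        assert res.auc == pytest.approx(auc_pair_oracle(pos, neg), abs=0)


def test_roc50_matches_truncated_oracle():
    rng = np.random.default_rng(43)
    for _ in range(100):
        pos, neg = random_instance(rng, 120)
        got = roc50(labels_from(pos, neg))
        assert got == pytest.approx(roc50_order_oracle(pos, neg), abs=1e-12)


def test_roc50_equals_auc_when_few_negatives():
    rng = np.random.default_rng(44)
    for _ in range(30):
        pos, neg = random_instance(rng, 40)
        if len(neg) > 50:
            continue
        res = roc_auc(labels_from(pos, neg))
        assert res.roc50 == pytest.approx(res.auc, abs=1e-12)


def test_no_positive_in_top_fifty_negatives_scores_zero():
    pos = [0.0] * 3
    neg = list(range(1, 101))  # 100 negatives all above every positive
    assert roc50(labels_from(pos, neg)) == 0.0


def test_negatives_first_never_exceeds_midrank():
    rng = np.random.default_rng(45)
    for _ in range(100):
        pos, neg = random_instance(rng)
        lbs = labels_from(pos, neg)
        nf = roc_auc(lbs, tie_policy="negatives_first").auc
        mid = roc_auc(lbs, tie_policy="midrank").auc
        assert nf <= mid + 1e-12
        cross_ties = bool(set(pos) & set(neg))
        assert (abs(nf - mid) < 1e-12) == (not cross_ties)


def test_curve_points_step_shape():
    res = roc_auc(labels_from([3, 1], [2]), with_curve=True)
    assert res.curve[0].tolist() == [0.0, 0.0]
    assert res.curve[-1].tolist() == [1.0, 1.0]


# ---------------------------------------------------------------------------
# Labelling

def make_flat_dataset():
    region = TestRegion(
        GenomicInterval("chr1", 0, 2000),
        peaks=[PeakRegion(GenomicInterval("chr1", 900, 1100), height=50)],
        negatives=[GenomicInterval("chr1", i, i + 200)
                   for i in (0, 200, 400, 600, 1200)],
    )
    return BenchmarkDataset("toy", [region])


def test_label_counts_one_positive_per_peak():
    dataset = make_flat_dataset()
    track = ScoreTrack("chr1:0-2000", 10, np.zeros(1991), np.zeros(1991))
    labels = label_scores(dataset, {"chr1:0-2000": track})
    assert sum(l.positive for l in labels) == 1
    assert sum(not l.positive for l in labels) == 5
    assert len({l.score for l in labels}) == 1  # constant track, one score


def test_label_scores_peak_carries_the_planted_maximum():
    dataset = make_flat_dataset()
    fwd = np.zeros(1991)
    fwd[950] = 9.0  # inside the peak
    track = ScoreTrack("chr1:0-2000", 10, fwd, np.zeros(1991))
    labels = label_scores(dataset, {"chr1:0-2000": track})
    positive = [l for l in labels if l.positive][0]
    assert positive.score == 9.0
    assert positive.height == 50


def test_label_scores_uncovered_region_named():
    dataset = make_flat_dataset()
    with pytest.raises(ValueError, match="chr1:0-2000"):
        label_scores(dataset, {})


# ---------------------------------------------------------------------------
# Stratification

def test_stratify_counts_and_thresholds():
    regions = []
    for i in range(100):
        start = i * 1000
        regions.append(TestRegion(
            GenomicInterval("chr1", start, start + 500),
            peaks=[PeakRegion(GenomicInterval("chr1", start + 100,
                                              start + 300),
                              height=float(i + 1))],
            negatives=[GenomicInterval("chr1", start + 350, start + 450)],
        ))
    dataset = BenchmarkDataset("toy", regions)
    low, high = stratify_by_height(dataset)
    low_heights = [p.height for p in low.peaks]
    high_heights = [p.height for p in high.peaks]
    assert max(low_heights) < min(high_heights)
    assert 5 <= len(low_heights) <= 15
    assert 5 <= len(high_heights) <= 15
    # negatives are retained unchanged
    assert low.n_negatives == high.n_negatives == dataset.n_negatives


def test_stratify_uniform_heights_rejected():
    region = TestRegion(
        GenomicInterval("chr1", 0, 500),
        peaks=[PeakRegion(GenomicInterval("chr1", 0, 100), height=5.0),
               PeakRegion(GenomicInterval("chr1", 200, 300), height=5.0)],
    )
    with pytest.raises(ValueError, match="stratum"):
        stratify_by_height(BenchmarkDataset("toy", [region]))


# ---------------------------------------------------------------------------
# Method comparison

def test_wilcoxon_all_positive_differences_n9():
    x = np.arange(1, 10) + 0.5
    y = np.arange(1, 10).astype(float)
    assert wilcoxon_one_sided(x, y) == pytest.approx(1 / 2**9)


def test_wilcoxon_identical_series_is_one():
    x = np.arange(5.0)
    assert wilcoxon_one_sided(x, x) == 1.0


def test_median_mad_constant_vector():
    assert median_mad([0.7] * 6) == (0.7, 0.0)


def test_compare_methods_table():
    table = pd.DataFrame(
        {f"d{i}": [0.7 + 0.01 * i, 0.6 + 0.01 * i] for i in range(9)},
        index=["a", "b"],
    )
    summary, pvals = compare_methods(table)
    assert summary.loc["a", "median"] == pytest.approx(
        np.median(table.loc["a"])
    )
    assert pvals.loc["a", "b"] == pytest.approx(1 / 2**9)
    assert pvals.loc["b", "a"] == pytest.approx(1.0)


def test_compare_methods_missing_cell_rejected():
    table = pd.DataFrame({"d1": [0.5, np.nan], "d2": [0.4, 0.6]},
                         index=["a", "b"])
    with pytest.raises(ValueError):
        compare_methods(table)


# ---------------------------------------------------------------------------
# Spearman

def test_spearman_monotone_limits():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    rho, _ = spearman(x, [2.0, 4.0, 6.0, 8.0, 10.0])
    assert rho == pytest.approx(1.0)
    rho, _ = spearman(x, [10.0, 8.0, 6.0, 4.0, 2.0])
    assert rho == pytest.approx(-1.0)


def test_spearman_constant_vector_rejected():
    with pytest.raises(ValueError):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def spearman_p_bruteforce(x, y):
    """Two-sided exact permutation p-value by direct enumeration."""
    from scipy import stats

    rho_obs, _ = stats.spearmanr(x, y)
    count = total = 0
    for perm in itertools.permutations(y):
        rho, _ = stats.spearmanr(x, perm)
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def test_spearman_exact_p_matches_enumeration():
    rng = np.random.default_rng(71)
    x = rng.normal(size=7)
    y = rng.normal(size=7)
    rho, p = spearman(x, y)
    assert p == pytest.approx(spearman_p_bruteforce(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# Positional profiles

def test_profile_spike_at_center_and_flat_conservation():
    scores = np.zeros(2000)
    peaks = []
    for mid in (500, 1000, 1500):
        scores[mid] = 5.0
        peaks.append(PeakRegion(GenomicInterval("chr1", mid - 100, mid + 100)))
    phylop = {"chr1": {i: 0.4 for i in range(2000)}}
    hist, cons, per_peak = positional_profile(peaks, {"chr1": scores}, phylop)
    assert hist[250] == 3  # the window center offset
    assert hist.sum() == 3
    assert np.allclose(cons, 0.4)
    assert per_peak == pytest.approx([0.4, 0.4, 0.4])


def test_profile_skips_out_of_bounds_peak():
    scores = np.zeros(600)
    peaks = [PeakRegion(GenomicInterval("chr1", 0, 100))]
    with pytest.warns(UserWarning, match="skipped"):
        hist, _, _ = positional_profile(peaks, {"chr1": scores}, {"chr1": {}})
    assert hist.sum() == 0
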