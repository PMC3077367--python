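"""Weighted Sum, BBLS (with exhaustive-enumeration oracle), window
projection, percentile cutoffs and calibration."""

import itertools

import dendropy
import numpy as np
import pytest

from tfbsbench.conservation import (
    BblsConfig,
    WsConfig,
    bbls,
    bbls_track,
    calibrate_cutoff,
    leaf_probabilities,
    percentile_cutoff,
    project_species_window,
    ws_score,
    ws_track,
)
from tfbsbench.intervals import GenomicInterval
from tfbsbench.io_formats import AlignmentBlock, MafRecord
from tfbsbench.motif_models import CountMatrix, build_pwm
from tfbsbench.phylo import PhyloTree
from tfbsbench.scanners import scan_pwm

from conftest import random_newick


def make_block(texts: dict[str, str], ref: str = "hg",
               ref_start: int = 0) -> AlignmentBlock:
    records = {}
    for sp, text in texts.items():
        size = len(text.replace("-", ""))
        start = ref_start if sp == ref else 0
        records[sp] = MafRecord(f"{sp}.chr1", start, size, "+", 10_000, text)
    return AlignmentBlock(records, reference=ref)


# ---------------------------------------------------------------------------
# Window projection

def test_projection_gapless_h0():
    block = make_block({"hg": "ACGT", "mm": "TTTT", "rn": "GGGG"})
    windows = project_species_window(block, 2, h=0)
    assert windows == {"hg": "G", "mm": "T", "rn": "G"}


def test_projection_all_gap_row_is_empty():
    block = make_block({"hg": "ACGT", "mm": "--AA"})
    assert project_species_window(block, 0, h=1)["mm"] == ""


def test_projection_with_reference_gap_column():
    # reference AC-GT vs other ACTGT; window around the G with h=1 spans
    # the columns of C..T; the other species' gap-free text is CTGT
    block = make_block({"hg": "AC-GT", "mm": "ACTGT"})
    windows = project_species_window(block, 2, h=1)
    assert windows["hg"] == "CGT"
    assert windows["mm"] == "CTGT"


def test_projection_outside_block_is_error():
    block = make_block({"hg": "ACGT"}, ref_start=100)
    with pytest.raises(ValueError):
        project_species_window(block, 99, h=1)


# ---------------------------------------------------------------------------
# Weighted Sum

@pytest.fixture
def toy_pwm():
    rng = np.random.default_rng(2)
    return build_pwm(CountMatrix(rng.uniform(0.5, 12, (4, 5))))


def test_ws_zero_weights_is_reference_track(toy_pwm):
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    block = make_block({"hg": seq, "mm": seq, "rn": seq})
    iv = GenomicInterval("chr1", 0, len(seq))
    scorer = lambda s: scan_pwm(s, toy_pwm)
    track = ws_track(seq, iv, [block], scorer, WsConfig(default_weight=0.0))
    ref = scorer(seq)
    assert np.array_equal(track.fwd, ref.fwd)
    assert np.array_equal(track.rev, ref.rev)


def test_ws_identical_species_boost_at_window_max(toy_pwm):
    rng = np.random.default_rng(6)
    seq = "".join(rng.choice(list("ACGT"), size=120))
    block = make_block({"hg": seq, "mm": seq, "rn": seq})
    iv = GenomicInterval("chr1", 0, len(seq))
    scorer = lambda s: scan_pwm(s, toy_pwm)
    ref = scorer(seq)
    track = ws_track(seq, iv, [block], scorer, WsConfig(default_weight=0.25))
    best = ref.best()
    i = int(np.argmax(best))
    # at the global maximum the two identical species each contribute
    # 0.25 * the same maximum
    assert track.best()[i] == pytest.approx(best[i] * 1.5)


def test_ws_no_alignment_equals_reference(toy_pwm):
    seq = "ACGTACGTACGTACGTACGT"
    iv = GenomicInterval("chr1", 0, len(seq))
    scorer = lambda s: scan_pwm(s, toy_pwm)
    track = ws_track(seq, iv, [], scorer)
    assert np.array_equal(track.fwd, scorer(seq).fwd)


def test_ws_score_empty_window_contributes_zero(toy_pwm):
    seq = "ACGTACGTAC"
    ref = scan_pwm(seq, toy_pwm)
    maxima = {"mm": np.full(len(ref), -np.inf)}
    track = ws_score(ref, maxima, WsConfig(default_weight=0.25))
    assert np.array_equal(track.fwd, ref.fwd)


# ---------------------------------------------------------------------------
# Percentile cutoff and leaf probabilities

def test_percentile_linear_interpolation():
    assert percentile_cutoff(np.arange(1, 101), 95) == pytest.approx(95.05)


def test_percentile_constant_distribution():
    assert percentile_cutoff(np.full(10, 3.3), 90) == pytest.approx(3.3)


def test_percentile_median():
    assert percentile_cutoff(np.array([1, 2, 3]), 50) == pytest.approx(2.0)


def test_percentile_validation():
    with pytest.raises(ValueError):
        percentile_cutoff(np.array([]), 95)
    with pytest.raises(ValueError):
        percentile_cutoff(np.array([1.0]), 0)


def test_leaf_probabilities_binary_conventions():
    scores = {"hg": 0.0, "mm": 5.0, "rn": 2.0, "canFam": None}
    p = leaf_probabilities(scores, threshold=2.0, ref_species="hg")
    assert p == {"hg": 1.0, "mm": 1.0, "rn": 1.0, "canFam": 0.0}
    # ties at the threshold count as present; reference always present
    assert leaf_probabilities({"hg": -9.0, "mm": 1.9}, 2.0, "hg")["mm"] == 0.0


def test_leaf_probabilities_soft_rank():
    ref_dist = np.arange(100.0)
    p = leaf_probabilities({"hg": 0.0, "mm": 49.0}, 90.0, "hg",
                           model="soft", ref_distribution=ref_dist)
    assert p["mm"] == pytest.approx(0.5)
    assert p["hg"] == 1.0


# ---------------------------------------------------------------------------
# BBLS

def test_bbls_reference_only_is_zero(four_leaf_tree):
    p = {lf: 0.0 for lf in four_leaf_tree.leaves}
    p["hg"] = 1.0
    assert bbls(four_leaf_tree, p) == pytest.approx(0.0)


def test_bbls_two_leaf_tree_examples():
    tree = PhyloTree.from_newick("(a:0.1,b:0.2);")
    assert bbls(tree, {"a": 1.0, "b": 1.0}) == pytest.approx(0.3)
    assert bbls(tree, {"a": 1.0, "b": 0.5}) == pytest.approx(0.15)


def test_bbls_missing_leaf_is_error(four_leaf_tree):
    with pytest.raises(ValueError, match="missing leaf"):
        bbls(four_leaf_tree, {"hg": 1.0})


def enumeration_expected_bls(newick: str, p: dict[str, float]) -> float:
    """Independent oracle: E[BLS] by exhaustive enumeration of all 2^n
    leaf presence configurations, edges taken from dendropy directly."""
    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
    leaves = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    edges = []
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        edges.append((float(node.edge.length or 0.0), below))
    total = 0.0
    for presence in itertools.product([0, 1], repeat=len(leaves)):
        present = {lf for lf, z in zip(leaves, presence) if z}
        prob = 1.0
        for lf, z in zip(leaves, presence):
            prob *= p[lf] if z else 1.0 - p[lf]
        if prob == 0.0:
            continue
        bls = sum(
            length for length, below in edges
            if present & below and present - below
        )
        total += prob * bls
    return total


def test_bbls_equals_enumeration_oracle_on_random_trees():
    rng = np.random.default_rng(101)
    for _ in range(25):
        n = int(rng.integers(2, 9))
        newick = random_newick(rng, n)
        tree = PhyloTree.from_newick(newick)
        p = {lf: float(rng.random()) for lf in tree.leaves}
        assert bbls(tree, p) == pytest.approx(
            enumeration_expected_bls(newick, p), abs=1e-9
        )


def test_bbls_monotone_in_probabilities_and_lengths():
    rng = np.random.default_rng(55)
    newick = random_newick(rng, 6)
    tree = PhyloTree.from_newick(newick)
    p = {lf: float(rng.uniform(0, 0.8)) for lf in tree.leaves}
    base = bbls(tree, p)
    for lf in tree.leaves:
        bumped = dict(p)
        bumped[lf] = min(p[lf] + 0.15, 1.0)
        assert bbls(tree, bumped) >= base - 1e-12
    longer = PhyloTree(tree.leaves, tree.edge_masks,
                       tree.edge_lengths * 1.5, tree.newick)
    assert bbls(longer, p) >= base - 1e-12


def test_bbls_binary_probabilities_equal_plain_bls():
    rng = np.random.default_rng(77)
    newick = random_newick(rng, 7)
    tree = PhyloTree.from_newick(newick)
    p = {lf: float(rng.integers(0, 2)) for lf in tree.leaves}
    assert bbls(tree, p) == pytest.approx(
        enumeration_expected_bls(newick, p), abs=1e-12
    )


# ---------------------------------------------------------------------------
# BBLS tracks on alignments

def test_bbls_track_reference_only_tree_is_zero(toy_pwm):
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    block = make_block({"hg": seq})
    tree = PhyloTree.from_newick("(hg:0.1);")
    iv = GenomicInterval("chr1", 0, len(seq))
    track = bbls_track(seq, iv, [block], tree,
                       lambda s: scan_pwm(s, toy_pwm), threshold=0.0,
                       cfg=BblsConfig(leaf_model="binary"))
    assert np.allclose(track.fwd, 0.0)


def test_bbls_track_missing_species_named(toy_pwm, four_leaf_tree):
    seq = "ACGTACGTACGTACGTACGT"
    block = make_block({"hg": seq, "mm": seq})
    iv = GenomicInterval("chr1", 0, len(seq))
    with pytest.raises(ValueError, match="canFam"):
        bbls_track(seq, iv, [block], four_leaf_tree,
                   lambda s: scan_pwm(s, toy_pwm), threshold=0.0,
                   cfg=BblsConfig(leaf_model="binary"))


def test_bbls_track_conserved_site_reaches_total_branch_length(
        toy_pwm, four_leaf_tree):
    rng = np.random.default_rng(12)
    seq = "".join(rng.choice(list("ACGT"), size=80))
    block = make_block({sp: seq for sp in four_leaf_tree.leaves})
    iv = GenomicInterval("chr1", 0, len(seq))
    scorer = lambda s: scan_pwm(s, toy_pwm)
    best = scorer(seq).best()
    threshold = float(best.max())  # only the single best window passes
    track = bbls_track(seq, iv, [block], four_leaf_tree, scorer, threshold,
                       cfg=BblsConfig(leaf_model="binary"))
    assert track.fwd.max() == pytest.approx(four_leaf_tree.total_length)


# ---------------------------------------------------------------------------
# Calibration

def test_calibrate_single_candidate():
    result = calibrate_cutoff([object()], lambda b, q: (0.5, 0.1), grid=[90])
    assert result.best_percentile == 90


def test_calibrate_tie_breaking_rules():
    # equal ROC everywhere; ROC-50 prefers 75; then percentile breaks ties
    def evaluate(_b, q):
        return 0.8, (0.3 if q == 75 else 0.1)

    result = calibrate_cutoff([1, 2], evaluate, grid=[50, 75, 95])
    assert result.best_percentile == 75

    result = calibrate_cutoff([1], lambda b, q: (0.8, 0.1), grid=[50, 95])
    assert result.best_percentile == 95


def test_calibrate_empty_inputs_rejected():
    with pytest.raises(ValueError):
        calibrate_cutoff([], lambda b, q: (0, 0))
    with pytest.raises(ValueError):
        calibrate_cutoff([1], lambda b, q: (0, 0), grid=[])
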