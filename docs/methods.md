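# Methods

This note documents the models, numerical choices, and defaults behind
`tfbsbench`, and what its synthetic benchmarks do and do not show.

## Scoring models

### PWM

Count matrices (JASPAR or TRANSFAC dialect) are converted to log-odds
weights in bits: `W[b,j] = log2(((c_bj + a*p_b) / (C_j + a)) / p_b)`,
with column sums `C_j`, background `p`, and pseudocount `a = 1`
distributed across cells in proportion to the background (so smoothed
columns still sum to one and no cell is ever -inf).  The background is
estimated by counting bases over the reference genome, with absent
bases floored at 1e-4 and renormalized.  Scanning sums column weights
over each window on both strands; a reverse-strand score is the score
of the reverse-complemented window, reported at the forward coordinate
of the window start so region maxima live in one coordinate system.
Ambiguous bases contribute the background expectation
`sum_b p_b W[b,j]` — deterministic and conservative.

Information content is reported against a uniform background
(`IC_j = 2 + sum_b q_bj log2 q_bj`, the classic definition under which
published motif tables satisfy `average = total / length`); the
relative-entropy form against the genomic background is available via a
parameter.  The two built-in synthetic motifs have deliberately
irregular column counts: perfectly regular columns give a PWM whose
scores live on a coarse lattice, region maxima then tie massively, and
the conservative tie policy (below) collapses PWM performance — an
artifact that real database matrices, whose counts vary cell to cell,
do not show.

### MotifScan

The nearest-neighbour scorer compares each window against every motif
k-mer explicitly.  A k-mer `m` with `Hamming(m, x) <= d_max`
contributes the product of substitution weights `s(m_j, x_j)` over its
mismatch positions (matches contribute `s(a,a) = 1`); contributions are
aggregated over the k-mer set — multiplicity-weighted sum by default —
and `log2(1 + .)` transformed.  Defaults (`d_max = 3`, sum, log on) are
fixed reference behaviour and all configurable.  The substitution
matrix is estimated from column co-occurrences across many motifs'
k-mer stacks: ordered base pairs within each column are counted,
Laplace-smoothed, and normalized as
`s(a,b) = C(a,b) / sqrt(C(a,a) C(b,b))` clipped at 1 — symmetric, unit
diagonal, and equivalent in spirit to dividing each row by its (almost
always maximal) diagonal entry.  Ambiguous window bases mismatch every
base at the row-minimum weight; ambiguity codes inside motif k-mers are
rejected outright.

### Weighted Sum

`WS(i) = S_ref(i) + sum_s w_s * M_s(i)` where `M_s(i)` is species `s`'s
maximum motif score (both strands) over the alignment columns spanning
reference positions `i-15 .. i+15`, gaps removed.  The default weight
is 0.25 per non-reference species — with two aligned rodent genomes the
added term is half the mean of their window maxima, so the reference
score dominates.  Species windows are anchored by alignment columns,
not coordinate arithmetic, so indels shift them correctly; a species
absent from a block (or with a window too short for the motif)
contributes nothing, and positions with no alignment coverage keep the
plain reference score.

### BBLS

Each alignment species' window maximum (same +/-15 bp projection)
becomes a motif-presence probability at its tree leaf, and the score is
the expected branch length of the subtree spanned by the present
leaves, under independent presence:

    BBLS = sum_b l(b) * (1 - prod_{A(b)} (1 - p_i)) * (1 - prod_{B(b)} (1 - p_i))

Edges are taken on the unrooted tree (a degree-two root contributes its
two child edges, which carry the same bipartition — equivalent to one
unrooted edge with the summed length).  The identity to E[BLS] over all
2^n presence configurations is exact and is verified against exhaustive
enumeration in the tests.  The reference leaf is always present
(p = 1): scoring is anchored at a concrete reference position.
Unaligned leaves get p = 0, so uncovered positions score 0, never NaN.

Two leaf-probability models are provided.  **soft** (default):
`p_i` is the empirical percentile rank of the leaf's window maximum
within the reference genome's distribution of the same statistic — a
continuous probability, the Bayesian reading of weighting branches by
presence probability.  **binary**: `p_i = 1` iff the score reaches the
cutoff (ties count as present) — the hard gating reading.  The binary
model discards score magnitude; on benchmarks where strong sites matter
it cannot rank a strong conserved site above a weakly conserved
background hit, which is why soft is the default.

**Cutoff distribution.** The cutoff percentile (default q = 95,
recalibrable on benchmark datasets over the grid {50, 75, 90, 95, 99},
ties toward higher ROC-50 then higher percentile) is taken on the
genome-wide distribution of the *leaf statistic itself* — per-position
window-maximum scores — not on raw per-position scores.  A window of
+/-15 bp holds ~44 motif starts, so nearly every window maximum clears
a raw per-position 95th percentile; the binary presence model would
saturate and the score would degenerate to a constant.  Taking the
percentile on the window-maximum distribution makes "95th percentile"
mean "5% of background windows put a leaf above the cutoff", the same
statistic the species leaves are scored with.

## Benchmark construction

Site benchmark: each peak gets a test region of exactly `L_T` (default
20000 bp; the scaled-down synthetic fixtures use 2000 bp) placed
uniformly at random around it, shifted inward at chromosome edges so
length is preserved.  Overlapping regions merge into one region
starting at the leftmost start with length equal to the *sum* of the
merged lengths — total benchmark length, and hence the
positive/negative bp ratio, is conserved exactly (merging is
deterministic; only placement uses the seeded generator).  A merged
region pushed past the chromosome end is shifted back inward (and, in
the extreme, truncated with a warning).  The peak-free remainder, minus
the exclusion mask, is cut into 200 bp chunks from each gap's left
edge; a terminal remainder of at least half a chunk stands alone,
shorter remainders merge into the previous chunk, and gaps shorter than
one chunk stay whole.  Promoter benchmark: per gene a strand-aware
-2000/+200 TSS window and a first-intron region capped at 3000 bp
downstream of the intron's 5' end; among overlapping gene regions the
first in (chrom, start) order is kept; peaks partially overlapping a
region extend it to full containment; negatives are the peak-free
flanks, not subdivided.

## Evaluation

Region scores are maxima over motif start positions inside the interval
(both strands).  The ROC uses the conservative negatives-first tie
policy: AUC equals the fraction of (positive, negative) pairs with the
positive *strictly* greater, so a scorer that saturates its maximum on
many regions is penalized, not flattered (all-tied input scores 0).
ROC-50 truncates the curve after the 50 highest-scoring negatives and
normalizes the step area by `50 * P` (all negatives, with matching
normalization, when fewer than 50 exist — in which case it equals the
AUC).  Stratification keeps peaks strictly above the 90th / strictly
below the 10th height percentile (linear interpolation), retaining all
negatives.  Method comparisons use the one-sided exact Wilcoxon
signed-rank test with zero differences dropped (p = 1 by convention
when all differences vanish) and report median plus unscaled MAD.
Spearman correlations use average ranks; p-values are exact by full
permutation enumeration for n <= 10 and t-approximate above.
Positional profiles histogram the argmax offset (ties to the leftmost)
over 500 bp windows centered on peak midpoints and average the
conservation track per offset; out-of-bounds windows are skipped with a
warning.

## Simulator

The reference sequence is drawn from the background composition
(default 0.3/0.2/0.2/0.3) and motif instances are sampled from the
count-matrix columns, planted without overlap on random strands.
Evolution runs outward from the reference leaf — the tree is rerooted
there, which is equivalent under the reversible substitution model and
keeps the reference byte-identical to the planted truth.  Substitution
is single-parameter Jukes-Cantor: on a branch of length `t` each
background column mutates with probability `1 - exp(-rate * t)` to a
uniformly chosen other base.  The default rate of 1.0 per unit branch
length puts reference-to-rodent divergence on the default four-species
tree (`((hg:0.12,(mm:0.25,rn:0.22):0.18):0.08,canFam:0.45)`) near 0.4
substitutions/site — the neutral mammalian range; with a much lower
rate the simulated background is nearly as conserved as the planted
sites and conservation filtering carries no signal.  Purifying
selection: per branch, each planted site is frozen with probability
equal to its conservation level (site-wide by default; per-site
uniform levels when conservation is coupled to peak height), otherwise
its columns mutate at the background rate.  Indels are off by default;
when enabled they are single-base deletions in non-reference species'
background columns only, so the truth table stays exact.  Peak heights
are `base + slope * site PWM score + coupling * site conservation +
Gaussian noise`, truncated at 0; decoy peaks on background positions
form the exclusion mask.  The conservation track is the per-column
fraction of aligned non-reference species matching the reference base,
rescaled to [-1, 1] — sufficient for exercising profile and averaging
code, not a real evolutionary-rate score.

### What the synthetic benchmarks show — and don't

The simulator reproduces the statistical *structure* the benchmark
assumes: conserved planted sites, divergent background, heights
correlated with strength and conservation.  It does not emulate real
alignment artifacts, indel-rich regions, repeat content, GC
heterogeneity, indirect (cofactor-mediated) binding, or cell-type
specificity, so passing tests demonstrate correctness of the machinery
and the direction of the comparative effects under controlled
conditions, not absolute performance on real genomes.  The two
qualitative findings are checked as seeded stochastic tests averaged
over replicates: (a) the conservation-method gain over PWM is larger
for an information-poor motif (< 0.8 bits/column) than an
information-rich one, and (b) with conservation driving peak height,
the BBLS-PWM gap is larger on the >90th-percentile height stratum than
on the <10th.  For (b) the strength-to-height slope is set to zero in
the test condition so PWM is stratum-neutral and the comparison
isolates the conservation effect; effect sizes (~0.05-0.1 AUC) are
comparable to single-replicate noise at ~15 peaks per stratum, hence
the averaging.  The BBLS monotonicity check (mean site BBLS strictly
increasing in the conservation level) runs at a background rate of 2.0
so that unselected sites are actually destroyed and the top level is
not at the total-branch-length ceiling.

## Problem sizes

Unit tests run on sequences of 10^2-10^3 bp; the end-to-end acceptance
checks simulate 25-600 kb genomes with 30-150 planted sites and 2 kb
site-benchmark regions, chosen so the whole suite completes in well
under a minute of simulation time per check while every stratum retains
at least ~15 positives.  The BBLS-vs-enumeration check covers 200
random trees of up to 12 leaves at 1e-9 tolerance; ROC equals
brute-force pair counting exactly on 500 random tied instances.

## Known limitations

- Windows are projected within one alignment block; a motif window
  straddling a block boundary sees only its own block's columns.
- MAF reverse-strand records are stored as written (strand recorded);
  the simulator and fixtures emit plus-strand records only.
- The MotifScan substitution-matrix estimator and its defaults are a
  documented reference interpretation; the method's original
  parameterization is not restated in the sources available to this
  package.
- `merge_overlapping` can, on peak-dense fixtures, produce regions
  longer than the chromosome; they are shifted inward and in the
  extreme truncated (with a warning), trading exact length conservation
  for valid coordinates.
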