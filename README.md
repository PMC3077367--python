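# tfbsbench

A benchmark toolkit for transcription factor binding site (TFBS)
prediction methods, built around ChIP-seq peak calls.  The idea: treat
each peak as a positive binding region and the surrounding peak-free
sequence as negatives, score every region with a motif-based predictor,
and ask whether the peaks outrank the background.  The package is for
computational biologists who want to rank motif-scanning and
conservation-aware TFBS predictors on a common, reproducible footing —
including entirely on synthetic data, since it ships a phylogeny-aware
simulator that generates every input it consumes.

## What it implements

**Five scoring methods**, each emitting one score per genomic position
and strand:

- **PWM** — log-odds position weight matrix scanning,
  `W[b,j] = log2( q_bj / p_b )` with pseudocount-smoothed column
  probabilities `q` and genomic background `p`.
- **MotifScan** — nearest-neighbour k-mer scoring: a motif k-mer `m`
  contributes `prod_j s(m_j, x_j)` to window `x` when
  `Hamming(m, x) <= d_max`, with a 4x4 substitution matrix `s`
  estimated from column co-occurrences across many motifs; contributions
  are summed and `log2(1 + .)` transformed.
- **Weighted Sum (WS)** — a baseline conservation scheme:
  `WS(i) = S_ref(i) + sum_s w_s * max` of the motif score in each
  aligned species' +/-15 bp window (gaps removed), default
  `w_s = 0.25`.
- **BBLS (PWM or MotifScan leaf scores)** — the Bayesian branch length
  score.  Per position, each species' window maximum becomes a
  motif-presence probability `p_i` at its tree leaf (percentile-rank by
  default, or hard cutoff gating), and

  `BBLS = sum_b l(b) * (1 - prod_{i in A(b)} (1 - p_i)) * (1 - prod_{i in B(b)} (1 - p_i))`

  where edge `b` splits the unrooted tree's leaves into sides `A(b)` and
  `B(b)`.  This is exactly the expected branch length of the subtree
  spanned by the species carrying the motif, under independent leaf
  presence.  The cutoff percentile (default 95) can be re-calibrated on
  benchmark datasets over a grid.

**Benchmark construction** — the *site* benchmark embeds every peak in a
randomly placed fixed-length region (20 kb by default), merges
overlapping regions length-additively (conserving the positive/negative
bp ratio), and chunks the peak-free remainder into 200 bp negatives,
minus an exclusion mask of lesser peaks; the *promoter* benchmark builds
TSS-anchored (-2000/+200) and first-intron (<=3000 bp) regions per gene.

**Evaluation** — per-region maximum scores, ROC AUC and ROC-50 with a
conservative tie policy (at equal scores all negatives count before any
positive), peak-height stratification (<10th / >90th percentile),
one-sided exact Wilcoxon signed-rank method comparisons, median/MAD
summaries, Spearman correlations (exact permutation p for small n), and
500 bp positional profiles of score argmax and conservation around peak
centers.

**Simulator** — plants motif instances in a background genome, evolves
orthologous sequences along a phylogeny with purifying selection on the
sites, emits peaks whose heights track site strength and/or
conservation, decoy peaks, and writes standard formats (FASTA, MAF,
newick, BED, fixedStep wiggle) plus an exact ground-truth table.

## Worked example

Simulate a benchmark with an information-poor 8 bp motif (~0.41
bits/column) under strong purifying selection, then rank all five
methods:

```python
import numpy as np
from tfbsbench import SimConfig, make_benchmark_fixture
from tfbsbench.synth_sim import default_motif, sample_kmer_set
from tfbsbench.pipeline import (MotifResources, GenomeResources,
                                evaluate_all_methods)

cfg = SimConfig(length=150_000, n_sites=50, seed=1,
                motif=default_motif("low"), site_conservation=0.95,
                n_decoy_peaks=5)
bundle, dataset = make_benchmark_fixture(cfg)      # simulate + site benchmark
rng = np.random.default_rng(1)
mres = MotifResources(counts=cfg.motif,
                      kmers=sample_kmer_set(cfg.motif, 30, rng))
gres = GenomeResources({cfg.chrom: bundle.reference},
                       bundle.alignment, bundle.tree)
print(evaluate_all_methods(dataset, mres, gres).round(4))
```

prints

```
              auc   roc50  n_positives  n_negatives
method
pwm        0.5403  0.1136           50          442
motifscan  0.5489  0.1396           50          442
ws         0.5579  0.1748           50          442
bbls-pwm   0.5661  0.1388           50          442
bbls-ms    0.5444  0.1448           50          442
```

Each row is one method's area under the ROC curve and its ROC-50 (area
truncated after the 50 highest-scoring negatives) over 50 positive peak
regions and 442 negative 200 bp chunks.  With a weak motif, plain PWM
scanning barely beats chance, and the conservation-aware methods (WS,
BBLS) recover additional signal from cross-species conservation of the
planted sites — the toolkit's central comparative finding.  With the
information-rich built-in motif (`default_motif("high")`) the ordering
reverses: PWM alone is near AUC 1 and conservation adds nothing.

The same pipeline is scriptable from the shell: `tfbsbench simulate`,
`tfbsbench bench-build`, `tfbsbench scan`, `tfbsbench evaluate`,
`tfbsbench calibrate` (see `tfbsbench --help`).

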