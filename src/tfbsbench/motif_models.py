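"""Motif models: count matrices, log-odds PWMs, information content,
k-mer sets, and the MotifScan substitution matrix.

A motif is represented either as a 4xL nucleotide count matrix (the
classic position frequency matrix, rows A/C/G/T) or as an explicit set
of binding k-mers.  The count matrix is turned into a log-odds position
weight matrix (PWM, in bits) against a genomic background; the k-mer set
feeds the nearest-neighbour MotifScan scorer via a 4x4 substitution
matrix estimated from column co-occurrences across many motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: probability floor used when a base is absent from a background sample
BACKGROUND_FLOOR = 1e-4


@dataclass
class CountMatrix:
    """4xL non-negative nucleotide counts, rows in A, C, G, T order."""

    counts: np.ndarray
    motif_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("count matrix must be 4 x L")
        if self.counts.shape[1] < 1:
            raise ValueError("motif length must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError("negative counts in matrix")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("zero-sum column in count matrix")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def column_probabilities(self, alpha: float = 0.0,
                             background: "BaseFrequencies | None" = None
                             ) -> np.ndarray:
        """Pseudocount-smoothed per-column base probabilities."""
        bg = background.p if background is not None else np.full(4, 0.25)
        colsum = self.counts.sum(axis=0)
        return (self.counts + alpha * bg[:, None]) / (colsum + alpha)


@dataclass
class BaseFrequencies:
    """Background base probabilities p(A), p(C), p(G), p(T)."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (4,):
            raise ValueError("base frequencies must have 4 entries")
        if np.any(self.p <= 0):
            raise ValueError("base frequencies must be strictly positive")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "BaseFrequencies":
        return cls(np.full(4, 0.25))

    def __getitem__(self, base: str) -> float:
        return float(self.p[BASE_INDEX[base]])


@dataclass
class LogOddsMatrix:
    """Log-odds PWM ``W`` in bits, with the background and pseudocount
    used to build it."""

    W: np.ndarray
    motif_id: str = ""
    background: BaseFrequencies = field(default_factory=BaseFrequencies.uniform)
    alpha: float = 1.0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != 4:
            raise ValueError("PWM must be 4 x L")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("non-finite PWM entries")

    @property
    def length(self) -> int:
        return self.W.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.W.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.W.max(axis=0).sum())

    def score_kmer(self, kmer: str) -> float:
        if len(kmer) != self.length:
            raise ValueError("k-mer length does not match motif length")
        return float(sum(self.W[BASE_INDEX[b], j] for j, b in enumerate(kmer)))


@dataclass
class KmerSet:
    """Equal-length binding k-mers with multiplicities."""

    kmers: list[str]
    counts: list[int] = field(default_factory=list)
    motif_id: str = ""

    def __post_init__(self) -> None:
        if not self.kmers:
            raise ValueError("empty k-mer set")
        if not self.counts:
            self.counts = [1] * len(self.kmers)
        if len(self.counts) != len(self.kmers):
            raise ValueError("counts/kmers length mismatch")
        k = len(self.kmers[0])
        for mer in self.kmers:
            if len(mer) != k:
                raise ValueError("k-mers of unequal length")
            if any(b not in BASE_INDEX for b in mer):
                # ambiguity codes are rejected, keeping set semantics exact
                raise ValueError(f"non-ACGT character in k-mer {mer!r}")
        if any(c < 1 for c in self.counts):
            raise ValueError("k-mer multiplicities must be >= 1")

    @property
    def k(self) -> int:
        return len(self.kmers[0])

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def encoded(self) -> np.ndarray:
        """Integer-encoded k-mers, shape (n_kmers, k)."""
        return np.array(
            [[BASE_INDEX[b] for b in mer] for mer in self.kmers], dtype=np.int64
        )


@dataclass
class SubstitutionMatrix:
    """4x4 substitution weights ``s(a, b)`` in (0, 1], diagonal 1."""

    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (4, 4):
            raise ValueError("substitution matrix must be 4 x 4")
        if np.any(self.s <= 0) or np.any(self.s > 1):
            raise ValueError("substitution weights must lie in (0, 1]")
        if not np.allclose(np.diag(self.s), 1.0):
            raise ValueError("substitution matrix diagonal must be 1")
        if not np.allclose(self.s, self.s.T):
            raise ValueError("substitution matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.s[BASE_INDEX[a], BASE_INDEX[b]])


def background_from_sequence(seq: str, floor: float = BACKGROUND_FLOOR
                             ) -> BaseFrequencies:
    """Estimate background base frequencies from a sequence.

    Ambiguity codes (N etc.) are skipped.  Absent bases are floored at
    ``floor`` and the vector renormalized, so log-odds stay finite.  An
    all-ambiguous sequence falls back to the uniform background.
    """
    counts = np.zeros(4)
    for b in seq.upper():
        i = BASE_INDEX.get(b)
        if i is not None:
            counts[i] += 1
    total = counts.sum()
    if total == 0:
        warnings.warn("no unambiguous bases; using uniform background")
        return BaseFrequencies.uniform()
    p = counts / total
    p = np.maximum(p, floor)
    return BaseFrequencies(p / p.sum())


def build_pwm(counts: CountMatrix, bg: BaseFrequencies | None = None,
              alpha: float = 1.0) -> LogOddsMatrix:
    """Build a log-odds PWM from nucleotide counts.

    ``W[b, j] = log2( (counts[b, j] + alpha * p(b)) / (colsum_j + alpha)
    / p(b) )``.  The pseudocount ``alpha`` is distributed over the four
    cells in proportion to the background, so the smoothed column still
    sums to one.
    """
    if alpha <= 0:
        raise ValueError("pseudocount alpha must be > 0")
    if bg is None:
        bg = BaseFrequencies.uniform()
    q = counts.column_probabilities(alpha=alpha, background=bg)
    W = np.log2(q / bg.p[:, None])
    return LogOddsMatrix(W, motif_id=counts.motif_id, background=bg, alpha=alpha)


@dataclass
class InformationContent:
    total: float
    per_position: np.ndarray
    average: float


def information_content(counts: CountMatrix, alpha: float = 0.0,
                        background: BaseFrequencies | None = None
                        ) -> InformationContent:
    """Per-position, total and average information content in bits.

    With the default uniform background this is the classic
    ``IC_j = 2 + sum_b q_bj log2 q_bj`` (0 bits for a uniform column,
    2 bits for a fixed base).  Passing a genomic background switches to
    the relative-entropy form ``sum_b q_bj log2(q_bj / p_b)``.
    """
    if alpha < 0:
        raise ValueError("pseudocount alpha must be >= 0")
    q = counts.column_probabilities(alpha=alpha, background=background)
    with np.errstate(divide="ignore", invalid="ignore"):
        qlogq = np.where(q > 0, q * np.log2(q), 0.0)
    if background is None:
        per_pos = 2.0 + qlogq.sum(axis=0)
    else:
        per_pos = (qlogq - np.where(q > 0, q * np.log2(background.p[:, None]), 0.0)
                   ).sum(axis=0)
    total = float(per_pos.sum())
    return InformationContent(total, per_pos, total / counts.length)


def mean_pairwise_hamming(kmers: KmerSet) -> float:
    """Multiplicity-weighted mean Hamming distance over unordered k-mer
    pairs.  Pairs of copies of the same k-mer contribute distance 0."""
    enc = kmers.encoded()
    c = np.asarray(kmers.counts, dtype=float)
    n = c.sum()
    n_pairs = n * (n - 1) / 2
    if n_pairs == 0:
        raise ValueError("need at least two k-mers (counting multiplicity)")
    dist_sum = 0.0
    for i, j in combinations(range(len(enc)), 2):
        d = int((enc[i] != enc[j]).sum())
        dist_sum += c[i] * c[j] * d
    return dist_sum / n_pairs


def build_substitution_matrix(motifs: list[KmerSet], smoothing: float = 1.0
                              ) -> SubstitutionMatrix:
    """Estimate the MotifScan substitution matrix from motif k-mer stacks.

    For every motif and every column of its k-mer stack, ordered pairs of
    bases co-occurring in that column are counted (multiplicity-weighted).
    Counts are Laplace-smoothed, and normalized as
    ``s(a, b) = C(a, b) / sqrt(C(a, a) * C(b, b))`` (clipped at 1), which
    is symmetric, has unit diagonal, and approximates dividing each row
    by its (almost always maximal) diagonal entry.
    """
    C = np.full((4, 4), float(smoothing))
    any_data = False
    for motif in motifs:
        if motif.total < 2:
            continue
        any_data = True
        enc = motif.encoded()
        w = np.asarray(motif.counts, dtype=float)
        for j in range(motif.k):
            col = np.zeros(4)
            np.add.at(col, enc[:, j], w)
            # ordered co-occurrence pairs within the column
            C += np.outer(col, col) - np.diag(col)
    if not any_data:
        raise ValueError("no motif with >= 2 k-mers; cannot estimate matrix")
    d = np.sqrt(np.diag(C))
    s = np.minimum(C / np.outer(d, d), 1.0)
    np.fill_diagonal(s, 1.0)
    return SubstitutionMatrix(s)


def motif_summary_row(motif_id: str, counts: CountMatrix | None,
                      kmers: KmerSet | None) -> dict:
    """One summary row (id, length, total/avg IC, mean Hamming) for the
    motif table export."""
    row: dict = {"motif_id": motif_id}
    if counts is not None:
        ic = information_content(counts)
        row.update(length=counts.length, total_ic=round(ic.total, 2),
                   avg_ic=round(ic.average, 2))
    if kmers is not None:
        row.setdefault("length", kmers.k)
        if kmers.total >= 2:
            row["mean_hamming"] = round(mean_pairwise_hamming(kmers), 1)
    return row
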