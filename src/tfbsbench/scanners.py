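"""Single-genome motif scoring: PWM scanning and MotifScan.

Both methods emit one score per position and strand.  A score at
position ``i`` on either strand refers to a motif window whose 5' end
(in forward-genome coordinates) starts at ``i``; reverse-strand scores
are the score of the reverse-complemented window, reported at the
forward coordinate of the window start, so region-maximum extraction
works in a single coordinate system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .motif_models import (
    BASE_INDEX,
    KmerSet,
    LogOddsMatrix,
    SubstitutionMatrix,
)

# base codes 0..3 = A C G T, 4 = ambiguous
_ENCODE = np.full(256, 4, dtype=np.int64)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
# complement map over codes (ambiguous stays ambiguous)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int64)


def encode_sequence(seq: str) -> np.ndarray:
    """Integer-encode a DNA string (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    table = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(table)[::-1]


@dataclass
class ScoreTrack:
    """Per-position, per-strand scores for one sequence and one method.

    Track arrays have length ``len(seq) - L + 1`` (one entry per valid
    motif start position).
    """

    seq_id: str
    motif_length: int
    fwd: np.ndarray
    rev: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd, dtype=float)
        self.rev = np.asarray(self.rev, dtype=float)
        if self.fwd.shape != self.rev.shape:
            raise ValueError("forward/reverse track length mismatch")
        if self.fwd.size and not (np.all(np.isfinite(self.fwd))
                                  and np.all(np.isfinite(self.rev))):
            raise ValueError("non-finite scores in track")

    def __len__(self) -> int:
        return self.fwd.size

    def best(self) -> np.ndarray:
        """Per-position maximum over the two strands."""
        return np.maximum(self.fwd, self.rev)


def _empty_track(seq_id: str, L: int, method: str) -> ScoreTrack:
    warnings.warn(f"sequence {seq_id!r} shorter than motif ({L} bp)")
    return ScoreTrack(seq_id, L, np.empty(0), np.empty(0), method=method)


def scan_pwm(seq: str, pwm: LogOddsMatrix, seq_id: str = "") -> ScoreTrack:
    """Score a PWM at all positions on both strands.

    Ambiguous bases contribute the background-expected column score
    ``sum_b p(b) W[b, j]``, a deterministic, conservative stand-in.
    """
    L = pwm.length
    codes = encode_sequence(seq)
    if codes.size < L:
        return _empty_track(seq_id, L, "pwm")
    p = pwm.background.p

    def scan_matrix(W: np.ndarray) -> np.ndarray:
        Wext = np.vstack([W, p @ W])  # row 4: expected score of an N
        windows = sliding_window_view(codes, L)
        return Wext[windows, np.arange(L)].sum(axis=1)

    # reverse strand = score of the reverse-complement motif at the
    # forward coordinate: complement rows (ACGT -> TGCA) and flip columns
    W_rc = pwm.W[::-1, ::-1]
    return ScoreTrack(seq_id, L, scan_matrix(pwm.W), scan_matrix(W_rc),
                      method="pwm")


@dataclass
class MotifScanConfig:
    """MotifScan parameters: maximum mismatch count ``d_max``, k-mer
    aggregation rule, and whether the aggregate is log2(1 + .)
    transformed."""

    d_max: int = 3
    aggregation: str = "sum"
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.d_max < 0:
            raise ValueError("d_max must be >= 0")
        if self.aggregation not in ("sum", "max"):
            raise ValueError("aggregation must be 'sum' or 'max'")


def scan_motifscan(seq: str, kmers: KmerSet, s: SubstitutionMatrix,
                   cfg: MotifScanConfig | None = None, seq_id: str = ""
                   ) -> ScoreTrack:
    """Nearest-neighbour k-mer scoring.

    A motif k-mer ``m`` contributes ``prod_j s(m_j, x_j)`` to window
    ``x`` when ``Hamming(m, x) <= d_max`` (matching positions contribute
    s(a, a) = 1), else 0.  Contributions are aggregated over the k-mer
    set (multiplicity-weighted sum by default) and log2(1 + .)
    transformed.  Ambiguous window bases mismatch every base with weight
    equal to the row minimum of ``s``.
    """
    cfg = cfg or MotifScanConfig()
    k = kmers.k
    if cfg.d_max > k:
        raise ValueError(f"d_max {cfg.d_max} exceeds k-mer length {k}")
    codes = encode_sequence(seq)
    if codes.size < k:
        return _empty_track(seq_id, k, "motifscan")

    # column 4 handles ambiguous window bases: worst-case substitution
    S_ext = np.hstack([s.s, s.s.min(axis=1, keepdims=True)])
    enc = kmers.encoded()
    mult = np.asarray(kmers.counts, dtype=float)

    def strand_scores(windows: np.ndarray) -> np.ndarray:
        agg = np.zeros(windows.shape[0])
        for m_codes, m_mult in zip(enc, mult):
            vals = S_ext[m_codes[None, :], windows]
            ham = (windows != m_codes[None, :]).sum(axis=1)
            contrib = np.where(ham <= cfg.d_max, vals.prod(axis=1), 0.0)
            if cfg.aggregation == "sum":
                agg += m_mult * contrib
            else:
                np.maximum(agg, contrib, out=agg)
        return np.log2(1.0 + agg) if cfg.log_transform else agg

    windows = sliding_window_view(codes, k)
    windows_rc = _COMPLEMENT[windows[:, ::-1]]
    return ScoreTrack(seq_id, k, strand_scores(windows),
                      strand_scores(windows_rc), method="motifscan")
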