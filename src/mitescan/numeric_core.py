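"""Numeric screening for TIR pairs and TSD detection.

The scan maps each base to a complex score (A → 1, T → −1, C → j, G → −j),
so that a base and its Watson-Crick complement always sum to zero. For two
``tir_len`` windows the screen statistic is the complex sum ``C`` of their
cumulative (window) scores: a perfect inverted-repeat pair gives C = 0, and
each non-complementary pair contributes an L1 norm of exactly 2. Window sums
come from a prefix-sum vector, so every (left, right) placement within the
allowed span is screened exhaustively in vectorized passes.

The screen is a necessary condition only — compensating mismatches (e.g. an
A↔A opposite a T↔T) also sum to zero — so every screened pair is verified
position-wise before TSD search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .config import PipelineConfig
from .genome_io import GenomeSequence

_COMPLEX_MAP = np.zeros(256, dtype=np.complex128)
_COMPLEX_MAP[ord("A")] = 1
_COMPLEX_MAP[ord("T")] = -1
_COMPLEX_MAP[ord("C")] = 1j
_COMPLEX_MAP[ord("G")] = -1j

_VALID = np.zeros(256, dtype=bool)
for _b in "ACGT":
    _VALID[ord(_b)] = True

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class EncodedSequence:
    """Complex per-base scores with prefix sums for O(1) window sums."""

    scores: np.ndarray          # complex128, invalid symbols scored 0
    prefix: np.ndarray          # complex128, prefix[k] = sum(scores[:k])
    valid: np.ndarray           # bool, True where base in {A,C,G,T}
    valid_prefix: np.ndarray    # int64 running count of valid bases

    def __len__(self) -> int:
        return len(self.scores)

    def window_sum(self, start: int, width: int) -> complex:
        return complex(self.prefix[start + width] - self.prefix[start])

    def window_valid(self, start: int, width: int) -> bool:
        return bool(
            self.valid_prefix[start + width] - self.valid_prefix[start] == width
        )


def encode(bases: str, mask: np.ndarray | None = None) -> EncodedSequence:
    """Map an uppercase base string onto the complex scoring vector.

    Symbols outside {A,C,G,T} are not errors: they are flagged invalid and
    any window covering one is excluded from candidacy. An optional boolean
    ``mask`` (soft-masked positions) is treated the same way.
    """
    codes = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    scores = _COMPLEX_MAP[codes]
    valid = _VALID[codes]
    if mask is not None:
        valid = valid & ~mask
        scores = np.where(valid, scores, 0)
    prefix = np.zeros(len(codes) + 1, dtype=np.complex128)
    np.cumsum(scores, out=prefix[1:])
    valid_prefix = np.zeros(len(codes) + 1, dtype=np.int64)
    np.cumsum(valid, out=valid_prefix[1:])
    return EncodedSequence(scores, prefix, valid, valid_prefix)


@dataclass
class TIRPairCandidate:
    """A screened-and-verified placement of two TIR arm windows."""

    left_start: int
    right_start: int
    tir_len: int
    mismatches: int

    @property
    def span(self) -> int:
        return self.right_start + self.tir_len - self.left_start


@dataclass
class MITECandidate:
    """A structurally complete candidate: TIR pair + exact flanking TSD.

    ``start``/``end`` bound the MITE body (left TIR start to right TIR end),
    0-based half-open; the TSD copies sit immediately outside on both sides.
    """

    seq_id: str
    start: int
    end: int
    tir: TIRPairCandidate
    tsd_seq: str
    body: str
    left_flank: str | None = None
    right_flank: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tir_len(self) -> int:
        return self.tir.tir_len

    @property
    def tir_mismatches(self) -> int:
        return self.tir.mismatches

    @property
    def key(self) -> tuple:
        return (self.seq_id, self.start, self.end, self.tsd_seq)


def screen_tir_pairs(
    enc: EncodedSequence, cfg: PipelineConfig
) -> list[tuple[int, int]]:
    """Exhaustively enumerate window pairs passing the complex-sum screen.

    Returns every (left_start, right_start) with both windows fully valid,
    body span within [min_len, max_len], non-overlapping arms, and
    |Re(C)| + |Im(C)| ≤ score_tolerance.
    """
    pairs: list[tuple[int, int]] = []
    for left, right in _screened_pair_arrays(enc, cfg):
        pairs.extend(zip(left.tolist(), right.tolist()))
    pairs.sort()
    return pairs


def _screened_pair_arrays(
    enc: EncodedSequence, cfg: PipelineConfig
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield screened (left_starts, right_starts) arrays per arm separation."""
    n = len(enc)
    w = cfg.tir_len
    if n < cfg.min_len:
        return
    wsum = enc.prefix[w:] - enc.prefix[:-w]                      # len n-w+1
    wvalid = (enc.valid_prefix[w:] - enc.valid_prefix[:-w]) == w
    l1 = np.abs(wsum.real) + np.abs(wsum.imag)
    # d = right_start - left_start; span = d + w
    d_lo = max(cfg.min_len - w, w)
    d_hi = min(cfg.max_len - w, n - w)
    for d in range(d_lo, d_hi + 1):
        m = n - d - w + 1
        if m <= 0:
            continue
        c = wsum[:m] + wsum[d : d + m]
        ok = (np.abs(c.real) + np.abs(c.imag) <= cfg.score_tolerance)
        ok &= wvalid[:m] & wvalid[d : d + m]
        left = np.nonzero(ok)[0]
        if left.size:
            yield left, left + d


def verify_tir(
    bases: str,
    left_start: int,
    right_start: int,
    tir_len: int,
    max_mismatch: int,
) -> tuple[bool, int]:
    """Position-wise complementarity check of a screened arm pair.

    Left arm position k is aligned with right arm position tir_len−1−k;
    a pair is a mismatch unless the bases are Watson-Crick complements.
    """
    left = bases[left_start : left_start + tir_len]
    right_rc = reverse_complement(bases[right_start : right_start + tir_len])
    mismatches = sum(a != b for a, b in zip(left, right_rc))
    return mismatches <= max_mismatch, mismatches


def find_tsd(
    bases: str,
    enc: EncodedSequence,
    start: int,
    end: int,
    cfg: PipelineConfig,
) -> str | None:
    """Find the longest exact target site duplication flanking [start, end).

    Scans L from tsd_max down to tsd_min; a length qualifies when both
    windows are in range, fully valid, have identical cumulative scores and
    are identical strings. Returns None when no length qualifies (the
    candidate is then discarded).
    """
    n = len(bases)
    for length in range(cfg.tsd_max, cfg.tsd_min - 1, -1):
        ls, le = start - length, start
        rs, re = end, end + length
        if ls < 0 or re > n:
            continue
        if not (enc.window_valid(ls, length) and enc.window_valid(rs, length)):
            continue
        if enc.window_sum(ls, length) != enc.window_sum(rs, length):
            continue
        if bases[ls:le] == bases[rs:re]:
            return bases[ls:le]
    return None


def _verify_pairs_vectorized(
    enc: EncodedSequence, left: np.ndarray, right: np.ndarray, tir_len: int
) -> np.ndarray:
    """Mismatch counts for many (left, right) arm pairs at once.

    Complementarity in score space: complementary bases have scores summing
    to exactly zero (A+T = C+G = 0), and no non-complementary valid pair
    does. Both windows are fully valid by construction.
    """
    mismatches = np.zeros(len(left), dtype=np.int64)
    scores = enc.scores
    for k in range(tir_len):
        mismatches += scores[left + k] + scores[right + tir_len - 1 - k] != 0
    return mismatches


def scan_chromosome(
    genome: GenomeSequence, cfg: PipelineConfig
) -> list[MITECandidate]:
    """Full candidate scan of one chromosome: screen → verify → TSD.

    The chromosome is processed in chunks of ``cfg.chunk_size`` with enough
    right-overlap that no candidate straddling a boundary is lost; results
    are chunk-invariant. Output is sorted by (start, end).
    """
    bases = genome.bases
    n = len(bases)
    if n < cfg.min_len:
        return []
    mask = genome.mask if cfg.skip_masked else None
    full_enc: EncodedSequence | None = None
    candidates: dict[tuple[int, int], MITECandidate] = {}
    w = cfg.tir_len
    for chunk_start in range(0, n, cfg.chunk_size):
        chunk_end = min(n, chunk_start + cfg.chunk_size + cfg.scan_overlap)
        if chunk_start == 0 and chunk_end == n:
            enc = full_enc = encode(bases, mask)
            offset = 0
        else:
            sub_mask = mask[chunk_start:chunk_end] if mask is not None else None
            enc = encode(bases[chunk_start:chunk_end], sub_mask)
            offset = chunk_start
        for left, right in _screened_pair_arrays(enc, cfg):
            mm = _verify_pairs_vectorized(enc, left, right, w)
            keep = mm <= cfg.max_tir_mismatch
            # each left_start belongs to exactly one chunk's core region
            keep &= (left + offset) < (chunk_start + cfg.chunk_size)
            if not keep.any():
                continue
            if full_enc is None:
                full_enc = encode(bases, mask)
            for l, r, m in zip(
                (left[keep] + offset).tolist(),
                (right[keep] + offset).tolist(),
                mm[keep].tolist(),
            ):
                start, end = l, r + w
                tsd = find_tsd(bases, full_enc, start, end, cfg)
                if tsd is None:
                    continue
                cand = MITECandidate(
                    seq_id=genome.seq_id,
                    start=start,
                    end=end,
                    tir=TIRPairCandidate(l, r, w, m),
                    tsd_seq=tsd,
                    body=bases[start:end],
                )
                prev = candidates.get((start, end))
                if prev is None or len(tsd) > len(prev.tsd_seq):
                    candidates[(start, end)] = cand
    return [candidates[k] for k in sorted(candidates)]
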