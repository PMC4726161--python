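"""Independent oracles used by the test suite.

These deliberately avoid the implementation's mechanisms: the scanner
oracle compares characters directly against a complement table (no complex
encoding, no prefix sums, no screen), and the complexity oracle is a
literal substring-search parser of the LZ76 exhaustive history.
"""

from __future__ import annotations

import numpy as np

import mitescan as ms

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP[_a] = _b
_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def oracle_scan(bases: str, cfg: ms.PipelineConfig) -> set[tuple[int, int, str]]:
    """Brute-force structural scan: test every (left, right) arm placement
    by direct character comparison, then search the longest exact TSD.

    Returns the set of (start, end, tsd) tuples defining candidates.
    """
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    w = cfg.tir_len
    valid = np.isin(arr, _ACGT)
    vsum = np.concatenate([[0], np.cumsum(valid)])
    results: set[tuple[int, int, str]] = set()
    for i in range(n - w + 1):
        if vsum[i + w] - vsum[i] != w:
            continue
        left = arr[i : i + w]
        r_lo = max(i + cfg.min_len - w, i + w)
        r_hi = min(i + cfg.max_len - w, n - w)
        if r_lo > r_hi:
            continue
        rs = np.arange(r_lo, r_hi + 1)
        mm = np.zeros(len(rs), dtype=np.int64)
        for k in range(w):
            mm += _COMP[left[k]] != arr[rs + w - 1 - k]
        ok = (mm <= cfg.max_tir_mismatch) & ((vsum[rs + w] - vsum[rs]) == w)
        for r in rs[ok].tolist():
            start, end = i, r + w
            for L in range(cfg.tsd_max, cfg.tsd_min - 1, -1):
                if start - L < 0 or end + L > n:
                    continue
                a = bases[start - L : start]
                b = bases[end : end + L]
                if a == b and set(a) <= set("ACGT"):
                    results.add((start, end, a))
                    break
    return results


def lz76_phrases_literal(seq: str) -> int:
    """Literal LZ76 exhaustive-history parser: a phrase grows while it can
    still be copied from the sequence seen so far (one character of
    lookahead allowed), and the final phrase counts even if reproducible."""
    n = len(seq)
    count = 0
    i = 0
    while i < n:
        j = i + 1
        while j <= n and seq[i:j] in seq[: j - 1]:
            j += 1
        count += 1
        i = j
    return count


def brute_force_representative(
    family: ms.MITEFamily, cfg: ms.PipelineConfig
) -> ms.MITECandidate:
    """Exhaustive all-pairs recomputation of the representativeness argmax."""
    from mitescan._align import local_aligner

    aligner = local_aligner(cfg)
    members = family.members
    scores = []
    for i, a in enumerate(members):
        total = sum(
            aligner.score(a.body, b.body)
            for j, b in enumerate(members)
            if j != i
        )
        scores.append(total)
    best = min(
        range(len(members)),
        key=lambda i: (-scores[i], members[i].seq_id, members[i].start),
    )
    return members[best]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
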