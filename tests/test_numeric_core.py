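import numpy as np
import pytest
from hypothesis import given, strategies as st

import mitescan as ms
from mitescan.numeric_core import (
    encode,
    find_tsd,
    reverse_complement,
    scan_chromosome,
    screen_tir_pairs,
    verify_tir,
)
from oracles import oracle_scan, random_dna

ARM = "GGGCCCAAAT"  # reference 10-nt arm used across screen tests


def _l1(c: complex) -> float:
    return abs(c.real) + abs(c.imag)


class TestEncode:
    def test_mapping_schema_and_zero_window_sum(self):
        enc = encode("ACGT")
        assert enc.scores.tolist() == [1, 1j, -1j, -1]
        assert enc.window_sum(0, 4) == 0

    def test_empty_sequence(self):
        enc = encode("")
        assert len(enc) == 0 and enc.prefix.tolist() == [0]

    def test_non_acgt_invalidates_covering_windows(self):
        enc = encode("ANA")
        assert enc.valid.tolist() == [True, False, True]
        assert not enc.window_valid(0, 3)
        assert enc.window_valid(0, 1)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_window_sum_equals_direct_sum(self, s):
        enc = encode(s)
        direct = sum(enc.scores[: len(s)])
        assert enc.window_sum(0, len(s)) == pytest.approx(direct)


class TestScreen:
    def _pair_genome(self, right_arm: str, gap: int = 80) -> str:
        return ARM + "C" * gap + right_arm

    def test_perfect_inverted_pair_scores_zero_and_is_reported(self, cfg):
        s = self._pair_genome(reverse_complement(ARM))
        enc = encode(s)
        c = enc.window_sum(0, 10) + enc.window_sum(90, 10)
        assert c == 0
        assert (0, 90) in screen_tir_pairs(enc, cfg)

    def test_every_single_substitution_gives_l1_exactly_two(self, cfg):
        """All 30 single-base substitutions of the complementary right arm
        shift the screen statistic's L1 norm to exactly 2."""
        rc = reverse_complement(ARM)
        count = 0
        for pos in range(10):
            for base in "ACGT":
                if base == rc[pos]:
                    continue
                mutated = rc[:pos] + base + rc[pos + 1 :]
                s = self._pair_genome(mutated)
                enc = encode(s)
                c = enc.window_sum(0, 10) + enc.window_sum(90, 10)
                assert _l1(c) == 2
                assert (0, 90) in screen_tir_pairs(enc, cfg)
                count += 1
        assert count == 30

    def test_compensating_double_mismatch_passes_screen_fails_verify(self, cfg):
        """An A·A pair opposite a T·T pair cancels in the sum (C = 0) but
        carries 2 positional mismatches: the screen alone is unsound and
        verification must reject it."""
        left = "AAGGGCCCAT"
        right = "TTGGGCCCTA"  # A<->A at one end (+2), T<->T mirrored (-2)
        s = left + "C" * 80 + right
        enc = encode(s)
        c = enc.window_sum(0, 10) + enc.window_sum(90, 10)
        assert c == 0
        assert (0, 90) in screen_tir_pairs(enc, cfg)
        accepted, mm = verify_tir(s, 0, 90, 10, cfg.max_tir_mismatch)
        assert (accepted, mm) == (False, 2)

    def test_exhaustive_no_qualifying_pair_omitted(self, cfg, rng):
        s = random_dna(rng, 400)
        enc = encode(s)
        reported = set(screen_tir_pairs(enc, cfg))
        for i in range(0, len(s) - 10):
            for r in range(i + 40, min(i + 791, len(s) - 10 + 1)):
                span = r + 10 - i
                if not (50 <= span <= 800) or r < i + 10:
                    continue
                c = enc.window_sum(i, 10) + enc.window_sum(r, 10)
                assert ((i, r) in reported) == (_l1(c) <= 2)


class TestVerifyTir:
    def test_perfect_arms_accepted_with_zero_mismatches(self):
        s = ARM + "C" * 40 + reverse_complement(ARM)
        assert verify_tir(s, 0, 50, 10, 1) == (True, 0)

    def test_single_substitution_accepted_with_one(self):
        rc = reverse_complement(ARM)
        s = ARM + "C" * 40 + rc[:4] + "A" + rc[5:]
        assert rc[4] != "A"
        assert verify_tir(s, 0, 50, 10, 1) == (True, 1)

    @given(st.text(alphabet="ACGT", min_size=10, max_size=10))
    def test_any_arm_with_its_reverse_complement_verifies(self, arm):
        s = arm + "G" * 40 + reverse_complement(arm)
        assert verify_tir(s, 0, 50, 10, 0) == (True, 0)


class TestFindTsd:
    def _genome(self, left_ctx, tsd, right_ctx, body_len=60):
        body = ARM + "C" * (body_len - 20) + reverse_complement(ARM)
        s = left_ctx + tsd + body + tsd + right_ctx
        start = len(left_ctx) + len(tsd)
        return s, start, start + body_len

    def test_simple_ta_duplication(self, cfg):
        s, start, end = self._genome("GGGG", "TA", "GGGG")
        assert find_tsd(s, encode(s), start, end, cfg) == "TA"

    def test_longest_qualifying_tsd_wins(self, cfg):
        # left flank ends ...CTAG, right flank begins TAG...: both "TAG"
        # (L=3) and a chance shorter repeat qualify; longest is returned.
        s, start, end = self._genome("CCCC", "TAG", "CCCC")
        assert find_tsd(s, encode(s), start, end, cfg) == "TAG"

    def test_no_direct_repeat_returns_none(self, cfg):
        body = ARM + "C" * 40 + reverse_complement(ARM)
        s = "AAAA" + body + "GGGG"
        assert find_tsd(s, encode(s), 4, 4 + len(body), cfg) is None

    def test_contig_edge_disqualifies_out_of_range_lengths(self, cfg):
        body = ARM + "C" * 40 + reverse_complement(ARM)
        s = "TA" + body + "TA"  # TSD flush with both contig ends
        assert find_tsd(s, encode(s), 2, 2 + len(body), cfg) == "TA"


class TestScanChromosome:
    def test_planted_element_recovered_exactly(self, cfg, rng):
        element, meta = ms.make_mite(rng, body_len=200)
        bg = random_dna(rng, 5000)
        s = bg[:2500] + element + bg[2500:]
        g = ms.GenomeSequence("chr1", s)
        keys = {(c.start, c.end, c.tsd_seq) for c in scan_chromosome(g, cfg)}
        assert (2502, 2702, "TA") in keys

    def test_chunked_and_unchunked_scans_agree(self, cfg, rng):
        s = random_dna(rng, 6000)
        g = ms.GenomeSequence("chr1", s)
        whole = [c.key for c in scan_chromosome(g, cfg)]
        chunked = [c.key for c in scan_chromosome(g, cfg.replace(chunk_size=1000))]
        assert whole == chunked

    def test_chromosome_shorter_than_min_len_yields_nothing(self, cfg):
        assert scan_chromosome(ms.GenomeSequence("c", "ACGT" * 10), cfg) == []

    def test_strand_closure(self, cfg, rng):
        """Reverse-complementing the genome mirrors every candidate and
        reverse-complements its TSD: the TIR + direct-repeat structure is
        strand-symmetric."""
        element, _ = ms.make_mite(rng, body_len=120, tsd="TAA")
        bg = random_dna(rng, 3000)
        s = bg[:1500] + element + bg[1500:]
        n = len(s)
        fwd = {
            (c.start, c.end, c.tsd_seq)
            for c in scan_chromosome(ms.GenomeSequence("c", s), cfg)
        }
        rev = {
            (c.start, c.end, c.tsd_seq)
            for c in scan_chromosome(
                ms.GenomeSequence("c", reverse_complement(s)), cfg
            )
        }
        mirrored = {
            (n - end, n - start, reverse_complement(tsd))
            for start, end, tsd in fwd
        }
        assert mirrored == rev

    def test_matches_brute_force_oracle_on_random_sequences(self, cfg, rng):
        for _ in range(20):
            s = random_dna(rng, int(rng.integers(300, 1500)))
            got = {
                (c.start, c.end, c.tsd_seq)
                for c in scan_chromosome(ms.GenomeSequence("c", s), cfg)
            }
            assert got == oracle_scan(s, cfg)

    def test_masked_bases_excluded_in_skip_masked_mode(self, cfg, rng):
        element, _ = ms.make_mite(rng, body_len=100)
        bg = random_dna(rng, 2000)
        s = bg[:1000] + element + bg[1000:]
        mask = np.zeros(len(s), dtype=bool)
        mask[1000 : 1000 + len(element)] = True
        g = ms.GenomeSequence("chr1", s, mask=mask)
        found = scan_chromosome(g, cfg.replace(skip_masked=True))
        assert all(not (c.start >= 1000 and c.end <= 1000 + len(element)) for c in found)
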