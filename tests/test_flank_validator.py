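import numpy as np
import pytest

import mitescan as ms
from mitescan.family_builder import MITEFamily
from mitescan.flank_validator import (
    FlankPair,
    extract_flanks,
    filter_family_members,
    finalize_families,
    flank_matches,
    select_representative,
)
from mitescan.numeric_core import MITECandidate, TIRPairCandidate
from oracles import brute_force_representative, random_dna


def _candidate(seq_id="chr1", start=100, end=300, tsd="TA", body=None):
    return MITECandidate(
        seq_id=seq_id,
        start=start,
        end=end,
        tir=TIRPairCandidate(start, end - 10, 10, 0),
        tsd_seq=tsd,
        body=body if body is not None else "A" * (end - start),
    )


def _mutated(rng, seq, n_subs):
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for p in pos:
        chars[p] = next(b for b in "ACGT" if b != chars[p])
    return "".join(chars)


class TestExtractFlanks:
    def test_coordinates_outside_tsd(self, rng):
        g = ms.GenomeSequence("chr1", random_dna(rng, 1000))
        cand = _candidate(start=100, end=300, tsd="TA")
        fp = extract_flanks(g, cand, 50)
        assert fp.left == g.bases[48:98]
        assert fp.right == g.bases[302:352]

    def test_left_flank_clipped_at_contig_start(self, rng):
        g = ms.GenomeSequence("chr1", random_dna(rng, 500))
        cand = _candidate(start=30, end=130, tsd="TA")
        fp = extract_flanks(g, cand, 50)
        assert fp.left == g.bases[0:28] and len(fp.left) == 28

    def test_right_flank_empty_at_contig_end(self, rng):
        g = ms.GenomeSequence("chr1", random_dna(rng, 302))
        cand = _candidate(start=100, end=300, tsd="TA")
        fp = extract_flanks(g, cand, 50)
        assert fp.right == ""


class TestFlankMatches:
    def test_identical_fifty_mers_give_fifty(self, cfg, rng):
        f = random_dna(rng, 50)
        assert flank_matches(f, f, cfg) == 50

    def test_empty_flank_never_matches(self, cfg, rng):
        assert flank_matches("", random_dna(rng, 50), cfg) == 0

    def test_symmetric_in_arguments(self, cfg, rng):
        for _ in range(20):
            a, b = random_dna(rng, 50), random_dna(rng, 50)
            assert flank_matches(a, b, cfg) == flank_matches(b, a, cfg)

    def test_heavily_substituted_copy_scores_below_threshold(self, cfg, rng):
        f1 = random_dna(rng, 50)
        f2 = _mutated(rng, f1, 30)
        assert flank_matches(f1, f2, cfg) < 25

    def test_random_pairs_rarely_reach_threshold(self, cfg, rng):
        """Divergent (random) flanks are only rarely called similar; the
        observed false-similarity rate stays in the low percent range."""
        hits = sum(
            flank_matches(random_dna(rng, 50), random_dna(rng, 50), cfg) >= 25
            for _ in range(150)
        )
        assert hits <= 20


def _family_with_flanks(rng, n=5, cfg=None):
    """Family of n members with mutually divergent (verified) flanks."""
    cfg = cfg or ms.PipelineConfig()
    body = random_dna(rng, 150)
    members = [
        _candidate(start=1000 * (i + 1), end=1000 * (i + 1) + 150, body=body)
        for i in range(n)
    ]

    def fresh(existing):
        while True:
            f = random_dna(rng, 50)
            if all(flank_matches(f, e, cfg) < 25 for e in existing):
                return f

    lefts, rights = [], []
    for _ in members:
        lefts.append(fresh(lefts))
        rights.append(fresh(rights))
    flanks = {
        id(m): FlankPair(lefts[i], rights[i]) for i, m in enumerate(members)
    }
    return MITEFamily("famX", members), flanks


class TestFilterFamilyMembers:
    def test_worked_example_two_similar_pairs_leave_three(self, cfg, rng):
        """Five copies where members 1&2 share left flanks and members 4&5
        share right flanks: members 2 and 5 are dropped, leaving 3 valid
        members (1, 3 and 4)."""
        family, flanks = _family_with_flanks(rng, 5)
        m = family.members
        flanks[id(m[1])] = FlankPair(
            _mutated(rng, flanks[id(m[0])].left, 3), flanks[id(m[1])].right
        )
        flanks[id(m[4])] = FlankPair(
            flanks[id(m[4])].left, _mutated(rng, flanks[id(m[3])].right, 3)
        )
        retained = filter_family_members(family, flanks, 25, cfg)
        assert retained == [m[0], m[2], m[3]]

    def test_all_divergent_flanks_all_retained(self, cfg, rng):
        family, flanks = _family_with_flanks(rng, 5)
        assert filter_family_members(family, flanks, 25, cfg) == family.members

    def test_identical_left_flanks_keep_only_first(self, cfg, rng):
        family, flanks = _family_with_flanks(rng, 3)
        shared = random_dna(rng, 50)
        for m in family.members:
            flanks[id(m)] = FlankPair(shared, flanks[id(m)].right)
        retained = filter_family_members(family, flanks, 25, cfg)
        assert retained == [family.members[0]]

    def test_left_and_right_never_cross_compared(self, cfg, rng):
        family, flanks = _family_with_flanks(rng, 2)
        m = family.members
        shared = random_dna(rng, 50)
        # member 0's LEFT equals member 1's RIGHT: must not trigger a drop
        flanks[id(m[0])] = FlankPair(shared, flanks[id(m[0])].right)
        flanks[id(m[1])] = FlankPair(flanks[id(m[1])].left, shared)
        assert filter_family_members(family, flanks, 25, cfg) == m

    def test_dropped_member_does_not_disqualify_later_ones(self, cfg, rng):
        family, flanks = _family_with_flanks(rng, 3)
        m = family.members
        # member 1 conflicts with member 0; member 2 conflicts only with
        # the dropped member 1, so member 2 survives
        flanks[id(m[1])] = FlankPair(
            _mutated(rng, flanks[id(m[0])].left, 2),
            random_dna(rng, 50),
        )
        flanks[id(m[2])] = FlankPair(
            random_dna(rng, 50), flanks[id(m[1])].right
        )
        # ensure m2's right conflicts with m1's right but not with m0's
        retained = filter_family_members(family, flanks, 25, cfg)
        assert m[2] in retained and m[1] not in retained


class TestSelectRepresentative:
    def test_all_identical_members_tie_break_to_first(self, cfg, rng):
        family, _ = _family_with_flanks(rng, 4)
        rep = select_representative(family, cfg)
        assert rep is family.members[0]

    def test_identical_pair_beats_diverged_third(self, cfg, rng):
        body = random_dna(rng, 200)
        diverged = _mutated(rng, body, 30)  # ~85% identity
        a = _candidate(start=1000, end=1200, body=body)
        b = _candidate(start=2000, end=2200, body=body)
        c = _candidate(start=3000, end=3200, body=diverged)
        rep = select_representative(MITEFamily("f", [a, b, c]), cfg)
        assert rep is a

    def test_agrees_with_exhaustive_oracle(self, cfg, rng):
        for _ in range(5):
            n = int(rng.integers(3, 8))
            body = random_dna(rng, 150)
            members = [
                _candidate(
                    start=1000 * (i + 1),
                    end=1000 * (i + 1) + 150,
                    body=_mutated(rng, body, int(rng.integers(0, 20))),
                )
                for i in range(n)
            ]
            family = MITEFamily("f", members)
            assert select_representative(family, cfg) is brute_force_representative(
                family, cfg
            )


class TestFinalizeFamilies:
    def test_family_reduced_to_three_is_retained(self, cfg, rng):
        family, flanks = _family_with_flanks(rng, 5)
        m = family.members
        flanks[id(m[1])] = FlankPair(flanks[id(m[0])].left, random_dna(rng, 50))
        flanks[id(m[4])] = FlankPair(random_dna(rng, 50), flanks[id(m[3])].right)
        final = finalize_families([family], flanks, cfg)
        assert len(final) == 1 and len(final[0].members) == 3
        assert final[0].representative in final[0].members

    def test_family_reduced_below_three_is_dropped(self, cfg, rng):
        family, flanks = _family_with_flanks(rng, 3)
        shared = random_dna(rng, 50)
        for m in family.members[:2]:
            flanks[id(m)] = FlankPair(shared, flanks[id(m)].right)
        assert finalize_families([family], flanks, cfg) == []

    def test_divergent_family_passes_unchanged(self, cfg, rng):
        family, flanks = _family_with_flanks(rng, 3)
        final = finalize_families([family], flanks, cfg)
        assert len(final) == 1 and final[0].members == family.members
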