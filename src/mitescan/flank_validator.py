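"""Flank-based copy validation and representative selection.

A genuine transposition deposits copies at unrelated loci, so true family
members carry divergent flanking sequence. For each member 50 nt is taken
immediately outside each TSD copy; within a family, left flanks are compared
only with left flanks and right flanks only with right flanks. When two
flanks on the same side share ≥ 25 aligned matching bases, the later member
(genomic order) is dropped. Families keeping ≥ 3 members survive, and each
gets a representative: the member maximizing the summed optimal local
alignment score against all other retained members, which anchors the family
to exact genome coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .config import PipelineConfig
from ._align import global_free_end_aligner, local_aligner
from .family_builder import MITEFamily
from .genome_io import GenomeSequence
from .numeric_core import MITECandidate

logger = logging.getLogger(__name__)


@dataclass
class FlankPair:
    """Up to ``flank_len`` bases immediately outside each TSD copy."""

    left: str
    right: str


def extract_flanks(
    genome: GenomeSequence, cand: MITECandidate, flank_len: int = 50
) -> FlankPair:
    """Extract the flanks outside the TSD copies, clipped at contig bounds."""
    tsd = len(cand.tsd_seq)
    left_end = cand.start - tsd
    left_start = max(0, left_end - flank_len)
    right_start = cand.end + tsd
    right_end = min(len(genome.bases), right_start + flank_len)
    return FlankPair(
        left=genome.bases[left_start:left_end],
        right=genome.bases[right_start:right_end],
    )


def _matches_with_aligner(aligner, f1: str, f2: str) -> int:
    # Co-optimal alignments can differ in identity count depending on
    # argument order; canonicalize the pair so the count is symmetric and
    # deterministic.
    if not f1 or not f2:
        return 0
    if f2 < f1:
        f1, f2 = f2, f1
    aln = aligner.align(f1, f2)[0]
    return int(aln.counts().identities)


def flank_matches(f1: str, f2: str, cfg: PipelineConfig | None = None) -> int:
    """Matched bases in the optimal pairwise alignment of two flanks.

    Uses the same global free-end-gap scoring as clustering; symmetric in
    its arguments; an empty flank never matches anything.
    """
    cfg = cfg or PipelineConfig()
    return _matches_with_aligner(global_free_end_aligner(cfg), f1, f2)


@dataclass
class FlankDrop:
    """Audit record: who was dropped, on which side, against whom."""

    family_id: str
    dropped: MITECandidate
    side: str
    kept: MITECandidate
    matches: int


def filter_family_members(
    family: MITEFamily,
    flanks: Mapping[int, FlankPair],
    threshold: int = 25,
    cfg: PipelineConfig | None = None,
    drops: list[FlankDrop] | None = None,
) -> list[MITECandidate]:
    """Greedy genomic-order retention of members with divergent flanks.

    ``flanks`` maps ``id(member)`` to its FlankPair. A member is dropped when
    its left flank matches a *retained* member's left flank at ≥ threshold
    bases, or likewise on the right; left and right are never
    cross-compared. Dropped members do not disqualify later ones.
    """
    cfg = cfg or PipelineConfig()
    aligner = global_free_end_aligner(cfg)

    def matches(a: str, b: str) -> int:
        return _matches_with_aligner(aligner, a, b)

    ordered = sorted(family.members, key=lambda c: (c.seq_id, c.start, c.end))
    retained: list[MITECandidate] = []
    for member in ordered:
        fp = flanks[id(member)]
        conflict = None
        for kept in retained:
            kfp = flanks[id(kept)]
            m_left = matches(fp.left, kfp.left)
            if m_left >= threshold:
                conflict = ("left", kept, m_left)
                break
            m_right = matches(fp.right, kfp.right)
            if m_right >= threshold:
                conflict = ("right", kept, m_right)
                break
        if conflict is None:
            retained.append(member)
        elif drops is not None:
            side, kept, m = conflict
            drops.append(FlankDrop(family.family_id, member, side, kept, m))
    return retained


def select_representative(
    family: MITEFamily, cfg: PipelineConfig | None = None
) -> MITECandidate:
    """Member maximizing the summed pairwise local alignment score.

    Ties break by (seq_id, start) ascending, so selection is deterministic.
    A single-member family trivially yields that member.
    """
    cfg = cfg or PipelineConfig()
    members = family.members
    if len(members) == 1:
        return members[0]
    aligner = local_aligner(cfg)
    n = len(members)
    totals = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(members[i].body, members[j].body)
            totals[i] += s
            totals[j] += s
    best = min(
        range(n),
        key=lambda i: (-totals[i], members[i].seq_id, members[i].start),
    )
    return members[best]


def finalize_families(
    families: Sequence[MITEFamily],
    flanks: Mapping[int, FlankPair],
    cfg: PipelineConfig,
    drops: list[FlankDrop] | None = None,
) -> list[MITEFamily]:
    """Flank-filter every family, keep those with ≥ min_members retained
    members, and select each survivor's representative."""
    final: list[MITEFamily] = []
    for fam in families:
        retained = filter_family_members(
            fam, flanks, cfg.flank_match_threshold, cfg, drops
        )
        if len(retained) < cfg.min_members:
            logger.info(
                "family %s dropped: %d of %d members kept after flank filtration",
                fam.family_id, len(retained), len(fam.members),
            )
            continue
        kept = MITEFamily(family_id=fam.family_id, members=retained)
        kept.representative = select_representative(kept, cfg)
        final.append(kept)
    return final
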