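"""Shared pairwise-alignment helpers built on Bio.Align.PairwiseAligner."""

from __future__ import annotations

from Bio import Align

from .config import PipelineConfig


def global_free_end_aligner(cfg: PipelineConfig) -> Align.PairwiseAligner:
    """Global aligner with free end gaps (semi-global / overlap alignment).

    Used wherever the pipeline counts matched bases between two sequences:
    family clustering statistics and flank comparison.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = cfg.match_score
    aligner.mismatch_score = cfg.mismatch_score
    aligner.open_gap_score = cfg.gap_score
    aligner.extend_gap_score = cfg.gap_score
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


def local_aligner(cfg: PipelineConfig) -> Align.PairwiseAligner:
    """Smith-Waterman aligner for representative-selection scores."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = cfg.local_match
    aligner.mismatch_score = cfg.local_mismatch
    aligner.open_gap_score = cfg.local_open
    aligner.extend_gap_score = cfg.local_extend
    return aligner
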