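"""End-to-end orchestration: scan → filter → cluster → validate → report.

Candidates are pooled genome-wide before clustering (families may span
chromosomes) and the pooled list is sorted canonically so results do not
depend on scan order. All outputs are deterministic: rerunning on identical
inputs produces byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .config import PipelineConfig
from . import genome_io
from .genome_io import GenomeSequence
from .numeric_core import MITECandidate, scan_chromosome
from .candidate_filters import FilterReport, apply_filters, write_filter_audit
from .family_builder import (
    MITEFamily,
    cluster_candidates,
    drop_small_families,
    run_cdhit_backend,
)
from .flank_validator import FlankDrop, extract_flanks, finalize_families

logger = logging.getLogger(__name__)


@dataclass
class PipelineSummary:
    """Stage-by-stage counts plus the final families and audit records."""

    n_candidates: int = 0
    n_pass_filters: int = 0
    n_families_clustered: int = 0
    n_families_min_copy: int = 0
    n_families_final: int = 0
    n_members_final: int = 0
    n_flank_drops: int = 0
    families: list[MITEFamily] = field(default_factory=list)
    filter_reports: list[FilterReport] = field(default_factory=list)
    flank_drops: list[FlankDrop] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "candidates": self.n_candidates,
            "pass_filters": self.n_pass_filters,
            "families_clustered": self.n_families_clustered,
            "families_min_copy": self.n_families_min_copy,
            "families_final": self.n_families_final,
            "members_final": self.n_members_final,
            "flank_drops": self.n_flank_drops,
        }


def detect(
    genomes: Sequence[GenomeSequence], cfg: PipelineConfig
) -> PipelineSummary:
    """Run the full detection pipeline in memory on loaded chromosomes."""
    summary = PipelineSummary()
    candidates: list[MITECandidate] = []
    by_id = {g.seq_id: g for g in genomes}
    for g in genomes:
        chrom_cands = scan_chromosome(g, cfg)
        logger.info("scan %s (%d nt): %d candidates", g.seq_id, len(g), len(chrom_cands))
        candidates.extend(chrom_cands)
    candidates.sort(key=lambda c: (c.seq_id, c.start, c.end))
    summary.n_candidates = len(candidates)

    passing, reports = apply_filters(candidates, cfg)
    summary.filter_reports = reports
    summary.n_pass_filters = len(passing)
    logger.info("filters: %d of %d candidates pass", len(passing), len(candidates))

    if cfg.backend == "cdhit":
        families = run_cdhit_backend(passing, cfg)
    else:
        families = cluster_candidates(passing, cfg)
    summary.n_families_clustered = len(families)

    families = drop_small_families(families, cfg.min_members)
    summary.n_families_min_copy = len(families)
    logger.info(
        "clustering: %d families, %d with >=%d members",
        summary.n_families_clustered, summary.n_families_min_copy, cfg.min_members,
    )

    flanks = {}
    for fam in families:
        for member in fam.members:
            flanks[id(member)] = extract_flanks(
                by_id[member.seq_id], member, cfg.flank_len
            )
            member.left_flank = flanks[id(member)].left
            member.right_flank = flanks[id(member)].right

    drops: list[FlankDrop] = []
    final = finalize_families(families, flanks, cfg, drops)
    summary.flank_drops = drops
    summary.n_flank_drops = len(drops)
    summary.n_families_final = len(final)
    summary.n_members_final = sum(len(f.members) for f in final)
    summary.families = final
    logger.info(
        "flank validation: %d drops; %d final families, %d members",
        len(drops), summary.n_families_final, summary.n_members_final,
    )
    return summary


def run_pipeline(
    genome_path: str | Path,
    cfg: PipelineConfig,
    out_prefix: str | Path,
    write_audit: bool = False,
) -> PipelineSummary:
    """Detect MITEs in a FASTA genome and write all output files.

    Writes ``<prefix>.families.fa`` (representatives), ``<prefix>.members.gff3``,
    ``<prefix>.members.tsv`` and ``<prefix>.log``; optionally a per-candidate
    filter audit TSV.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    log_path = out_prefix.with_suffix(out_prefix.suffix + ".log")
    handler = logging.FileHandler(log_path, mode="w")
    # no timestamps: reruns must be byte-identical
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mitescan")
    root.addHandler(handler)
    prev_level = root.level
    root.setLevel(logging.INFO)
    try:
        logger.info("configuration: %s", cfg.as_dict())
        genomes = genome_io.read_genome(genome_path)
        logger.info(
            "genome %s: %d sequences, %d nt",
            genome_path, len(genomes), sum(len(g) for g in genomes),
        )
        summary = detect(genomes, cfg)
        genome_io.write_family_fasta(
            summary.families, f"{out_prefix}.families.fa"
        )
        genome_io.write_member_table(
            summary.families, f"{out_prefix}.members.gff3", "gff3"
        )
        genome_io.write_member_table(
            summary.families, f"{out_prefix}.members.tsv", "tsv"
        )
        if write_audit:
            write_filter_audit(summary.filter_reports, f"{out_prefix}.filters.tsv")
        for fam in summary.families:
            for drop in summary.flank_drops:
                if drop.family_id == fam.family_id:
                    logger.info(
                        "flank drop in %s: %s:%d-%d (%s side, %d matches vs %s:%d-%d)",
                        drop.family_id, drop.dropped.seq_id, drop.dropped.start,
                        drop.dropped.end, drop.side, drop.matches,
                        drop.kept.seq_id, drop.kept.start, drop.kept.end,
                    )
        logger.info("summary: %s", summary.counts())
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(prev_level)
    return summary
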