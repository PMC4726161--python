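"""Genome input and annotation output.

Reads a multi-FASTA genome (plain or gzip) into :class:`GenomeSequence`
records and writes the pipeline's results: one FASTA of family
representatives and a per-member annotation table (GFF3 or TSV).

Coordinates are 0-based half-open internally; every emitted file is 1-based
inclusive, following GFF3 convention.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, TYPE_CHECKING

import numpy as np
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type checkers
    from .family_builder import MITEFamily

logger = logging.getLogger(__name__)


class FastaParseError(ValueError):
    """Fatal genome-parsing failure; the message names the offending line."""


@dataclass
class GenomeSequence:
    """One named chromosome/contig/scaffold.

    ``bases`` is uppercase; the original soft-mask (lowercase) state is kept
    in ``mask`` so a scan may optionally skip masked regions.
    """

    seq_id: str
    bases: str
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mask is not None and len(self.mask) != len(self.bases):
            raise ValueError("mask length must equal sequence length")

    def __len__(self) -> int:
        return len(self.bases)


def _open_maybe_gzip(path: Path) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_genome(path: str | Path) -> list[GenomeSequence]:
    """Read a (possibly gzipped) multi-FASTA genome.

    Record order is preserved; multi-line bodies are concatenated and bases
    uppercased, with the lowercase (soft-mask) state retained per position.

    Raises
    ------
    FastaParseError
        On an empty file, content before the first header, or a duplicate
        sequence id — the message names the offending line.
    """
    path = Path(path)
    with _open_maybe_gzip(path) as handle:
        # Pre-scan for the error contract Bio.SeqIO does not report:
        # line numbers of structural problems.
        first_content_line = None
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                first_content_line = (lineno, line)
                break
        if first_content_line is None:
            raise FastaParseError(f"{path}: empty FASTA file (no records)")
        lineno, line = first_content_line
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: expected FASTA header '>', got {line.strip()[:30]!r}"
            )
    genomes: list[GenomeSequence] = []
    seen: dict[str, int] = {}
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            raw = str(record.seq)
            if record.id in seen:
                raise FastaParseError(
                    f"{path}: duplicate sequence id {record.id!r} "
                    f"(record {len(genomes) + 1})"
                )
            seen[record.id] = len(genomes)
            mask = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
            is_lower = (mask >= ord("a")) & (mask <= ord("z"))
            genomes.append(
                GenomeSequence(
                    seq_id=record.id,
                    bases=raw.upper(),
                    mask=is_lower if is_lower.any() else None,
                )
            )
    return genomes


def _require_representative(families: Sequence["MITEFamily"]) -> None:
    for fam in families:
        if fam.representative is None:
            raise ValueError(f"family {fam.family_id} has no representative")


def write_family_fasta(families: Sequence["MITEFamily"], path: str | Path) -> None:
    """Write one FASTA record per family: the representative's MITE body.

    The header carries the family id, the representative's 1-based inclusive
    genomic location, TIR length, TSD sequence and member count. TSDs are not
    part of the emitted sequence (they are genomic, not element, sequence).
    """
    _require_representative(families)
    path = Path(path)
    if not families:
        logger.warning("no families to write; %s will be empty", path)
    with open(path, "w") as out:
        for fam in families:
            rep = fam.representative
            out.write(
                f">{fam.family_id} {rep.seq_id}:{rep.start + 1}-{rep.end} "
                f"TIR_len={rep.tir_len} TSD={rep.tsd_seq} members={len(fam.members)}\n"
            )
            for i in range(0, len(rep.body), 70):
                out.write(rep.body[i : i + 70] + "\n")


_MEMBER_COLUMNS = [
    "seq_id", "start", "end", "member_id", "family_id",
    "tir_len", "tir_mismatches", "tsd_seq", "tsd_len",
]


def _member_rows(families: Sequence["MITEFamily"]) -> list[dict]:
    rows = []
    for fam in families:
        for member in fam.members:
            rows.append(
                {
                    "seq_id": member.seq_id,
                    "start": member.start,
                    "end": member.end,
                    "member_id": f"{fam.family_id}.{member.seq_id}:{member.start + 1}-{member.end}",
                    "family_id": fam.family_id,
                    "tir_len": member.tir_len,
                    "tir_mismatches": member.tir_mismatches,
                    "tsd_seq": member.tsd_seq,
                    "tsd_len": len(member.tsd_seq),
                }
            )
    rows.sort(key=lambda r: (r["seq_id"], r["start"], r["end"], r["member_id"]))
    return rows


def write_member_table(
    families: Sequence["MITEFamily"], path: str | Path, format: str = "gff3"
) -> None:
    """Write every family member as a GFF3 feature or a flat TSV row.

    Rows are ordered by (seq_id, start, end). GFF3 output is 1-based
    inclusive per the format; TSV keeps the same converted coordinates.
    """
    if format not in ("gff3", "tsv"):
        raise ValueError(f"unknown member table format: {format!r}")
    path = Path(path)
    rows = _member_rows(families)
    with open(path, "w") as out:
        if format == "gff3":
            out.write("##gff-version 3\n")
            for row in rows:
                attrs = (
                    f"ID={row['member_id']};Parent={row['family_id']};"
                    f"TIR_len={row['tir_len']};TIR_mismatches={row['tir_mismatches']};"
                    f"TSD_seq={row['tsd_seq']};TSD_len={row['tsd_len']}"
                )
                out.write(
                    "\t".join(
                        [
                            row["seq_id"], "mitescan", "MITE",
                            str(row["start"] + 1), str(row["end"]),
                            ".", "+", ".", attrs,
                        ]
                    )
                    + "\n"
                )
        else:
            header = [
                "seq_id", "start", "end", "member_id", "family_id",
                "tir_len", "tir_mismatches", "tsd_seq", "tsd_len",
            ]
            out.write("\t".join(header) + "\n")
            for row in rows:
                out.write(
                    "\t".join(
                        [
                            row["seq_id"], str(row["start"] + 1), str(row["end"]),
                            row["member_id"], row["family_id"], str(row["tir_len"]),
                            str(row["tir_mismatches"]), row["tsd_seq"], str(row["tsd_len"]),
                        ]
                    )
                    + "\n"
                )


def write_genome_fasta(genomes: Iterable[GenomeSequence], path: str | Path) -> None:
    """Write GenomeSequences as FASTA (used by the synthetic generator)."""
    with open(Path(path), "w") as out:
        for g in genomes:
            out.write(f">{g.seq_id}\n")
            for i in range(0, len(g.bases), 70):
                out.write(g.bases[i : i + 70] + "\n")
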