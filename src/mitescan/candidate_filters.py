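"""False-positive filtration of structural candidates.

A structurally valid TIR+TSD candidate is still frequently a tandem repeat,
a low-complexity tract, or a chance hit. Four rules remove these classes:

1. a TIR arm contains a homopolymer or dinucleotide stretch of ≥8 nt;
2. a TIR arm has G/C or A/T content below 20%;
3. the normalized Lempel-Ziv complexity of the body is below 0.675;
4. a 2-nt target site duplication other than 'TA'.

Every rule is evaluated for every candidate (no short-circuiting) so the
audit report records the complete set of failed rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from pathlib import Path
from typing import Sequence

from .config import PipelineConfig
from .numeric_core import MITECandidate

RULE_LZ = "lz_complexity"
RULE_STRETCH = "tir_stretch"
RULE_COMPOSITION = "tir_composition"
RULE_TSD_TA = "tsd_ta"


@dataclass
class FilterReport:
    candidate: MITECandidate
    failed_rules: frozenset[str]
    lz_value: float

    @property
    def verdict(self) -> str:
        return "fail" if self.failed_rules else "pass"


def lz76_phrases(seq: str) -> int:
    """LZ76 exhaustive-history phrase count (Kaspar-Schuster algorithm).

    Parses left to right; a phrase ends one symbol past the longest prefix
    of the remainder reproducible from the prior history. The final,
    possibly reproducible, phrase is counted.
    """
    n = len(seq)
    if n == 0:
        return 0
    if n == 1:
        return 1
    i = 0          # start of the history window being matched
    c = 1          # phrase count (first symbol is always a phrase)
    l = 1          # start of the current phrase
    k = 1          # current extension length
    k_max = 1
    while True:
        if seq[i + k - 1] == seq[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def lz_complexity(seq: str) -> float:
    """Normalized Lempel-Ziv complexity: c(n) · log4(n) / n.

    With the 4-letter normalization a uniform-random DNA sequence approaches
    1, so the 0.675 default threshold sits well below typical-complexity
    sequence and above repeats and homopolymer tracts.
    """
    n = len(seq)
    if n < 2:
        raise ValueError("lz_complexity requires a sequence of length >= 2")
    return lz76_phrases(seq) * log(n, 4) / n


def has_long_stretch(tir: str, min_stretch: int = 8) -> bool:
    """True when the arm contains a period-1 or period-2 run of ≥ min_stretch nt.

    A dinucleotide stretch with two equal alternating bases is simply a
    homopolymer and is caught by the period-1 case.
    """
    n = len(tir)
    for period in (1, 2):
        run = period
        for i in range(period, n):
            if tir[i] == tir[i - period]:
                run += 1
                if run >= min_stretch:
                    return True
            else:
                run = period
    return False


def tir_composition_ok(tir: str, min_frac: float = 0.20) -> bool:
    """True when both the G/C and the A/T fractions are at least min_frac."""
    if not tir:
        return False
    gc = (tir.count("G") + tir.count("C")) / len(tir)
    at = (tir.count("A") + tir.count("T")) / len(tir)
    return gc >= min_frac and at >= min_frac


def tsd_ta_ok(tsd: str) -> bool:
    """2-nt target duplications must be the canonical 'TA'; longer pass."""
    return not (len(tsd) == 2 and tsd != "TA")


def evaluate_candidate(cand: MITECandidate, cfg: PipelineConfig) -> FilterReport:
    failed = set()
    lz = lz_complexity(cand.body)
    if lz < cfg.lz_threshold:
        failed.add(RULE_LZ)
    left_arm = cand.body[: cand.tir_len]
    right_arm = cand.body[-cand.tir_len :]
    if has_long_stretch(left_arm, cfg.min_stretch) or has_long_stretch(
        right_arm, cfg.min_stretch
    ):
        failed.add(RULE_STRETCH)
    if not (
        tir_composition_ok(left_arm, cfg.min_comp_frac)
        and tir_composition_ok(right_arm, cfg.min_comp_frac)
    ):
        failed.add(RULE_COMPOSITION)
    if not tsd_ta_ok(cand.tsd_seq):
        failed.add(RULE_TSD_TA)
    return FilterReport(cand, frozenset(failed), lz)


def apply_filters(
    candidates: Sequence[MITECandidate], cfg: PipelineConfig
) -> tuple[list[MITECandidate], list[FilterReport]]:
    """Apply all four rules; return surviving candidates (order preserved)
    and a report per input candidate."""
    reports = [evaluate_candidate(c, cfg) for c in candidates]
    passing = [r.candidate for r in reports if not r.failed_rules]
    return passing, reports


def write_filter_audit(reports: Sequence[FilterReport], path: str | Path) -> None:
    """Optional per-candidate audit TSV."""
    with open(Path(path), "w") as out:
        out.write("seq_id\tstart\tend\tverdict\tfailed_rules\tlz_value\n")
        for r in reports:
            c = r.candidate
            rules = ",".join(sorted(r.failed_rules)) or "-"
            out.write(
                f"{c.seq_id}\t{c.start}\t{c.end}\t{r.verdict}\t{rules}\t{r.lz_value:.4f}\n"
            )
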