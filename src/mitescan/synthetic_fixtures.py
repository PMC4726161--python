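"""Synthetic genomes with planted MITE families and a ground-truth table.

The generator plants elements with the canonical structure — TIR pair,
internal spacer, exact flanking TSD copies — into a uniform-random
background, and records every copy's coordinates. Elements are constructed
to provably pass (or, for designed negatives, provably fail) specific
pipeline stages: bodies are resampled until they clear the complexity
filter and contain no secondary candidate structure, TIR arms are resampled
until they clear the composition and stretch rules, and within-family flank
pairs are re-randomized until they fall below the flank-match threshold.

Every source of randomness flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import PipelineConfig
from .genome_io import GenomeSequence
from . import numeric_core
from .numeric_core import reverse_complement, scan_chromosome, verify_tir
from .candidate_filters import (
    has_long_stretch,
    lz_complexity,
    tir_composition_ok,
)
from .family_builder import pairwise_stats
from .flank_validator import flank_matches

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlantingError(RuntimeError):
    """Raised when element construction or placement cannot satisfy its
    constraints within the retry budget."""


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _substitute(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


@dataclass
class FamilySpec:
    """Blueprint for one planted family (positives and designed negatives)."""

    copies: int = 5
    body_len: int | None = None
    tsd: str = "TA"
    tir_mismatches: int = 0
    substitution_rate: float = 0.02
    identical_flanks: bool = False
    low_complexity: bool = False
    label: str = "mite"


@dataclass
class PlantedCopy:
    """Ground truth for one planted copy (0-based half-open body bounds)."""

    family_id: str
    label: str
    seq_id: str
    start: int
    end: int
    tsd_seq: str
    tir_mismatches: int
    substitution_rate: float


def _random_tir_arm(rng: np.random.Generator, cfg: PipelineConfig) -> str:
    for _ in range(500):
        arm = _random_bases(rng, cfg.tir_len)
        if tir_composition_ok(arm, cfg.min_comp_frac) and not has_long_stretch(
            arm, cfg.min_stretch
        ):
            return arm
    raise PlantingError("could not draw a TIR arm passing the filters")


def _periodic_spacer(rng: np.random.Generator, length: int) -> str:
    """A repeat of a short unit with no inverted-repeat self-structure."""
    for _ in range(200):
        unit = _random_bases(rng, 3)
        if len(set(unit)) < 2:
            continue
        rots = {unit[i:] + unit[:i] for i in range(3)}
        rc = reverse_complement(unit)
        rc_rots = {rc[i:] + rc[:i] for i in range(3)}
        if rots & rc_rots:
            continue
        return (unit * (length // 3 + 1))[:length]
    raise PlantingError("could not draw a low-complexity spacer unit")


def _scan_keys(element: str, cfg: PipelineConfig) -> list[tuple[int, int, str]]:
    g = GenomeSequence(seq_id="_element", bases=element)
    return [(c.start, c.end, c.tsd_seq) for c in scan_chromosome(g, cfg)]


def make_mite(
    rng: np.random.Generator,
    tir_len: int = 10,
    body_len: int = 200,
    tsd: str = "TA",
    tir_mismatches: int = 0,
    cfg: PipelineConfig | None = None,
    low_complexity: bool = False,
    max_tries: int = 300,
) -> tuple[str, dict]:
    """Construct one element string ``TSD + body + TSD`` and its metadata.

    The body is resampled until its TIR arms pass the composition and
    stretch rules, its complexity is on the intended side of the threshold,
    and a scan of the element finds exactly the intended candidate (so a
    planted copy can never spawn a second, body-internal family).
    """
    cfg = cfg or PipelineConfig()
    if body_len < 2 * tir_len:
        raise PlantingError("body_len must be at least 2*tir_len")
    if not (cfg.tsd_min <= len(tsd) <= cfg.tsd_max):
        raise PlantingError("tsd length must lie within [tsd_min, tsd_max]")
    for L in range(2, len(tsd)):
        # a shifted twin candidate (arms moved 1 nt outward, 9 pairs still
        # complementary, <=1 mismatch) finds tsd[-1-L:-1] vs tsd[1:1+L] as
        # its own direct repeat; such a TSD cannot be planted cleanly
        if tsd[len(tsd) - 1 - L : len(tsd) - 1] == tsd[1 : 1 + L]:
            raise PlantingError(
                f"tsd {tsd!r}: interior direct repeat creates an intrinsic "
                "shifted twin candidate; use a TSD without one (any 2-nt, "
                "or a non-repetitive 3-nt TSD)"
            )
    if not (cfg.min_len <= body_len <= cfg.max_len):
        raise PlantingError("body_len must lie within [min_len, max_len]")
    spacer_len = body_len - 2 * tir_len
    if cfg.tir_len != tir_len:
        cfg = cfg.replace(tir_len=tir_len)
    detectable = tir_mismatches <= cfg.max_tir_mismatch
    for _ in range(max_tries):
        left = _random_tir_arm(rng, cfg)
        right = reverse_complement(left)
        if tir_mismatches:
            pos = rng.choice(tir_len, size=tir_mismatches, replace=False)
            chars = list(right)
            for p in pos:
                chars[p] = _substitute(rng, chars[p])
            right = "".join(chars)
            if has_long_stretch(right, cfg.min_stretch) or not tir_composition_ok(
                right, cfg.min_comp_frac
            ):
                continue
        if low_complexity:
            spacer = _periodic_spacer(rng, spacer_len)
        else:
            spacer = _random_bases(rng, spacer_len)
        body = left + spacer + right
        _, mm = verify_tir(body, 0, body_len - tir_len, tir_len, tir_len)
        if mm != tir_mismatches:
            continue
        lz = lz_complexity(body)
        if low_complexity != (lz < cfg.lz_threshold):
            continue
        element = tsd + body + tsd
        keys = _scan_keys(element, cfg)
        expected = (
            [(len(tsd), len(tsd) + body_len, tsd)] if detectable else []
        )
        if keys != expected:
            continue
        return element, {
            "tir_left": left,
            "tir_right": right,
            "tsd": tsd,
            "tir_mismatches": tir_mismatches,
            "body": body,
            "lz": lz,
        }
    raise PlantingError("make_mite: constraints unsatisfied after retries")


def _mutate_copy(
    rng: np.random.Generator,
    body: str,
    tir_len: int,
    rate: float,
    low_complexity: bool,
    cfg: PipelineConfig,
    max_tries: int = 100,
) -> str:
    """Substitute spacer bases at the given per-base rate; TIR arms and
    therefore detectability are untouched. Resampled if the mutated body
    crosses the complexity threshold."""
    if rate <= 0:
        return body
    spacer_lo, spacer_hi = tir_len, len(body) - tir_len
    for _ in range(max_tries):
        chars = list(body)
        hits = np.nonzero(rng.random(spacer_hi - spacer_lo) < rate)[0]
        for h in hits:
            p = spacer_lo + int(h)
            chars[p] = _substitute(rng, chars[p])
        mutated = "".join(chars)
        if low_complexity == (lz_complexity(mutated) < cfg.lz_threshold):
            return mutated
    raise PlantingError("could not mutate copy within complexity constraints")


def _longest_tsd_str(bases: str, start: int, end: int, cfg: PipelineConfig) -> str | None:
    """String-only longest-TSD check used during placement validation."""
    n = len(bases)
    for length in range(cfg.tsd_max, cfg.tsd_min - 1, -1):
        if start - length < 0 or end + length > n:
            continue
        left = bases[start - length : start]
        right = bases[end : end + length]
        if left == right and set(left) <= set("ACGT"):
            return left
    return None


@dataclass
class _Unit:
    """One string to splice into the background, with the body offset."""

    text: str
    body_offset: int          # body start relative to unit start
    body_len: int
    spec: FamilySpec
    family_id: str
    copy_body: str
    base_body: str            # the unmutated family seed body
    copy_index: int = 0


def _build_units(
    rng: np.random.Generator,
    specs: Sequence[FamilySpec],
    cfg: PipelineConfig,
    body_len_range: tuple[int, int],
) -> list[_Unit]:
    units: list[_Unit] = []
    base_bodies: list[str] = []
    for f_idx, spec in enumerate(specs):
        family_id = f"planted{f_idx + 1:03d}"
        body_len = spec.body_len or int(
            rng.integers(body_len_range[0], body_len_range[1] + 1)
        )
        for _ in range(50):
            element, meta = make_mite(
                rng,
                tir_len=cfg.tir_len,
                body_len=body_len,
                tsd=spec.tsd,
                tir_mismatches=spec.tir_mismatches,
                cfg=cfg,
                low_complexity=spec.low_complexity,
            )
            # keep planted families mutually dissimilar so the recovered
            # partition is unambiguous
            if all(
                pairwise_stats(meta["body"], prev, cfg).identity < 0.6
                for prev in base_bodies
            ):
                break
        else:
            raise PlantingError("could not draw a family distinct from others")
        base_bodies.append(meta["body"])
        shared_left = shared_right = None
        if spec.identical_flanks:
            shared_left, shared_right = _draw_shared_flanks(
                rng, element, body_len, spec, cfg
            )
        for c_idx in range(spec.copies):
            body = meta["body"] if c_idx == 0 else _mutate_copy(
                rng, meta["body"], cfg.tir_len, spec.substitution_rate,
                spec.low_complexity, cfg,
            )
            copy_element = spec.tsd + body + spec.tsd
            if spec.identical_flanks:
                text = shared_left + copy_element + shared_right
                offset = cfg.flank_len + len(spec.tsd)
            else:
                text = copy_element
                offset = len(spec.tsd)
            units.append(
                _Unit(
                    text, offset, body_len, spec, family_id, body,
                    base_body=meta["body"], copy_index=c_idx,
                )
            )
    return units


def _draw_shared_flanks(
    rng: np.random.Generator,
    element: str,
    body_len: int,
    spec: FamilySpec,
    cfg: PipelineConfig,
) -> tuple[str, str]:
    for _ in range(100):
        left = _random_bases(rng, cfg.flank_len)
        right = _random_bases(rng, cfg.flank_len)
        unit = left + element + right
        start = cfg.flank_len + len(spec.tsd)
        if _longest_tsd_str(unit, start, start + body_len, cfg) != spec.tsd:
            continue
        if spec.tir_mismatches <= cfg.max_tir_mismatch:
            if _scan_keys(unit, cfg) != [(start, start + body_len, spec.tsd)]:
                continue
        elif _scan_keys(unit, cfg):
            continue
        return left, right
    raise PlantingError("could not draw clean shared flanks")


def generate_planted_genome(
    seed: int,
    n_families: int = 10,
    copies_per_family: int = 5,
    genome_len: int = 200_000,
    cfg: PipelineConfig | None = None,
    substitution_rate: float = 0.02,
    body_len_range: tuple[int, int] = (120, 400),
    tsd: str = "TA",
    extra_families: Sequence[FamilySpec] = (),
    seq_id: str = "chr1",
) -> tuple[list[GenomeSequence], list[PlantedCopy]]:
    """Plant MITE families into a random background genome.

    Returns the genome (one chromosome) and the per-copy truth table. Copies
    within a family share the seed body at ``substitution_rate`` spacer
    substitutions (TIR arms and TSDs untouched), sit at non-adjacent loci,
    and — unless a spec plants identical flanks on purpose — carry flanks
    verified to fall below the flank-match threshold pairwise.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    specs = [
        FamilySpec(
            copies=copies_per_family,
            tsd=tsd,
            substitution_rate=substitution_rate,
        )
        for _ in range(n_families)
    ] + list(extra_families)
    units = _build_units(rng, specs, cfg, body_len_range)
    total_planted = sum(len(u.text) for u in units)
    if total_planted >= genome_len / 2:
        raise PlantingError(
            "planted length exceeds half the genome; increase genome_len"
        )

    margin = cfg.flank_len + cfg.tsd_max
    min_sep = 2 * cfg.flank_len + 40
    m = len(units)
    for _ in range(200):
        positions = np.sort(
            rng.integers(margin, genome_len - margin, size=m)
        )
        if m < 2 or np.diff(positions).min() >= min_sep:
            break
    else:
        raise PlantingError("could not place elements; increase genome_len")
    order = rng.permutation(m)

    background = _random_bases(rng, genome_len)
    parts: list[str] = []
    truths: list[PlantedCopy] = []
    cursor = 0
    built = 0
    for slot in range(m):
        pos = int(positions[slot])
        unit = units[int(order[slot])]
        parts.append(background[cursor:pos])
        built += pos - cursor
        body_start = built + unit.body_offset
        parts.append(unit.text)
        built += len(unit.text)
        cursor = pos
        truths.append(
            PlantedCopy(
                family_id=unit.family_id,
                label=unit.spec.label,
                seq_id=seq_id,
                start=body_start,
                end=body_start + unit.body_len,
                tsd_seq=unit.spec.tsd,
                tir_mismatches=unit.spec.tir_mismatches,
                substitution_rate=unit.spec.substitution_rate,
            )
        )
    parts.append(background[cursor:])
    chars = list("".join(parts))

    unit_of = {id(t): units[int(i)] for t, i in zip(truths, order)}
    spec_of = {t.family_id: unit_of[id(t)].spec for t in truths}
    for _ in range(30):
        edited = _fix_tsd_extensions(rng, chars, truths, spec_of, cfg)
        edited |= _fix_shadow_candidates(rng, chars, truths, unit_of, spec_of, cfg)
        edited |= _fix_similar_flanks(rng, chars, truths, spec_of, cfg)
        if not edited:
            break
    else:
        raise PlantingError("planting did not stabilize; increase genome_len")

    genome = GenomeSequence(seq_id=seq_id, bases="".join(chars))
    truths.sort(key=lambda t: t.start)
    return [genome], truths


def _fix_tsd_extensions(
    rng: np.random.Generator,
    chars: list[str],
    truths: list[PlantedCopy],
    spec_of: dict[str, FamilySpec],
    cfg: PipelineConfig,
    max_rounds: int = 200,
) -> bool:
    """Redraw background bases adjacent to a planted TSD whenever the
    surrounding context makes a longer direct repeat qualify (which would
    shift the annotated TSD away from the planted truth)."""
    edited = False
    for truth in truths:
        if spec_of[truth.family_id].identical_flanks:
            continue  # pre-validated against a fixed flank template
        tsd_len = len(truth.tsd_seq)
        for _ in range(max_rounds):
            bases = "".join(chars)
            found = _longest_tsd_str(bases, truth.start, truth.end, cfg)
            if found == truth.tsd_seq:
                break
            left_edge = truth.start - tsd_len - 1
            right_edge = truth.end + tsd_len
            chars[left_edge] = _substitute(rng, chars[left_edge])
            chars[right_edge] = _substitute(rng, chars[right_edge])
            edited = True
        else:
            raise PlantingError("could not stabilize a planted TSD")
    return edited


def _immutable_spans(
    truths: Sequence[PlantedCopy],
    spec_of: dict[str, FamilySpec],
    cfg: PipelineConfig,
) -> list[tuple[int, int]]:
    """Genome spans the fixers must not touch: every planted element with
    its TSD copies, plus the shared flank templates of identical-flank
    families."""
    spans = []
    for t in truths:
        pad = len(t.tsd_seq)
        if spec_of[t.family_id].identical_flanks:
            pad += cfg.flank_len
        spans.append((t.start - pad, t.end + pad))
    return spans


def _fix_shadow_candidates(
    rng: np.random.Generator,
    chars: list[str],
    truths: list[PlantedCopy],
    unit_of: dict[int, "_Unit"],
    spec_of: dict[str, FamilySpec],
    cfg: PipelineConfig,
) -> bool:
    """Dissolve chance 'shadow' candidates that overlap a planted body.

    A shadow — an unintended TIR+TSD structure sharing ≥80% of a planted
    body — can cluster into the planted family and displace the true copy
    during flank filtration. Shadows whose TSD windows touch mutable
    background are killed by redrawing those bases; element-internal
    shadows created by copy mutation are killed by re-mutating the copy.
    """
    immutable = _immutable_spans(truths, spec_of, cfg)

    def mutable(pos: int) -> bool:
        return 0 <= pos < len(chars) and not any(
            lo <= pos < hi for lo, hi in immutable
        )

    edited = False
    for truth in truths:
        spec = spec_of[truth.family_id]
        unit = unit_of[id(truth)]
        body_len = truth.end - truth.start
        tsd_len = len(truth.tsd_seq)
        margin = cfg.flank_len + cfg.tsd_max + body_len // 4 + 10
        lo = max(0, truth.start - tsd_len - margin)
        hi = min(len(chars), truth.end + tsd_len + margin)
        detectable = truth.tir_mismatches <= cfg.max_tir_mismatch
        for _ in range(100):
            window = GenomeSequence(seq_id="_w", bases="".join(chars[lo:hi]))
            shadows = []
            for c in scan_chromosome(window, cfg):
                gs, ge = lo + c.start, lo + c.end
                if detectable and (gs, ge) == (truth.start, truth.end):
                    continue
                overlap = min(ge, truth.end) - max(gs, truth.start)
                if overlap < 0.8 * body_len:
                    continue
                # only similar-length structures can meet the 99% coverage
                # rule against family members; longer/shorter chance hits
                # are harmless singletons
                if not 0.75 * body_len <= ge - gs <= 1.25 * body_len:
                    continue
                shadows.append((gs, ge, len(c.tsd_seq)))
            if not shadows:
                break
            for gs, ge, stsd in shadows:
                targets = [
                    p
                    for p in list(range(gs - stsd, gs)) + list(range(ge, ge + stsd))
                    if mutable(p)
                ]
                if targets:
                    for p in targets:
                        chars[p] = _substitute(rng, chars[p])
                else:
                    # mutation-born internal shadow: redraw this copy's
                    # spacer mutations (arms/TSDs untouched)
                    if unit.copy_index == 0:
                        raise PlantingError(
                            "internal shadow in an unmutated seed body"
                        )
                    new_body = _mutate_copy(
                        rng, unit.base_body, cfg.tir_len,
                        spec.substitution_rate, spec.low_complexity, cfg,
                    )
                    chars[truth.start : truth.end] = list(new_body)
            edited = True
        else:
            raise PlantingError("could not dissolve a shadow candidate")
    return edited


def _fix_similar_flanks(
    rng: np.random.Generator,
    chars: list[str],
    truths: list[PlantedCopy],
    spec_of: dict[str, FamilySpec],
    cfg: PipelineConfig,
    max_rounds: int = 200,
) -> bool:
    """Re-randomize a copy's flank region until every within-family flank
    pair (left-left and right-right) stays below the match threshold."""
    any_edit = False
    by_family: dict[str, list[PlantedCopy]] = {}
    for t in truths:
        by_family.setdefault(t.family_id, []).append(t)

    def flank_of(t: PlantedCopy, side: str) -> tuple[int, int]:
        tsd_len = len(t.tsd_seq)
        if side == "left":
            end = t.start - tsd_len
            return max(0, end - cfg.flank_len), end
        start = t.end + tsd_len
        return start, min(len(chars), start + cfg.flank_len)

    for family_id, members in by_family.items():
        if spec_of[family_id].identical_flanks or len(members) < 2:
            continue
        for _ in range(max_rounds):
            clean = True
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    for side in ("left", "right"):
                        a0, a1 = flank_of(members[i], side)
                        b0, b1 = flank_of(members[j], side)
                        f1 = "".join(chars[a0:a1])
                        f2 = "".join(chars[b0:b1])
                        if flank_matches(f1, f2, cfg) >= cfg.flank_match_threshold:
                            chars[b0:b1] = list(_random_bases(rng, b1 - b0))
                            # a fresh flank can re-enable a TSD extension
                            _fix_tsd_extensions(
                                rng, chars, [members[j]], spec_of, cfg
                            )
                            clean = False
                            any_edit = True
            if clean:
                break
        else:
            raise PlantingError("could not diversify planted flanks")
    return any_edit


def write_truth_tsv(
    truths: Sequence[PlantedCopy], path: str | Path, seed: int | None = None
) -> None:
    """Write the ground-truth table (0-based half-open coordinates)."""
    with open(Path(path), "w") as out:
        if seed is not None:
            out.write(f"# seed={seed}\n")
        out.write(
            "family_id\tlabel\tseq_id\tstart\tend\ttsd_seq\t"
            "tir_mismatches\tsubstitution_rate\n"
        )
        for t in truths:
            out.write(
                f"{t.family_id}\t{t.label}\t{t.seq_id}\t{t.start}\t{t.end}\t"
                f"{t.tsd_seq}\t{t.tir_mismatches}\t{t.substitution_rate}\n"
            )
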