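"""Pipeline configuration: every tunable threshold with its published default.

The defaults encode the canonical structural definition of a MITE used
throughout the pipeline: a 50-800 nt element bounded by a 10 nt terminal
inverted repeat (TIR) pair with at most one non-complementary base pair,
flanked by an exact 2-10 nt target site duplication (TSD).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates a pipeline invariant."""


@dataclass
class PipelineConfig:
    # -- candidate structure --------------------------------------------------
    tir_len: int = 10            # TIR arm length scanned (nt)
    min_len: int = 50            # minimum MITE body length, TIR start to TIR end
    max_len: int = 800           # maximum MITE body length
    tsd_min: int = 2             # minimum TSD length
    tsd_max: int = 10            # maximum TSD length
    score_tolerance: int = 2     # |Re(C)|+|Im(C)| cutoff of the numeric screen
    max_tir_mismatch: int = 1    # non-complementary pairs allowed in the TIR

    # -- false-positive filters ----------------------------------------------
    lz_threshold: float = 0.675  # normalized Lempel-Ziv complexity cutoff
    min_stretch: int = 8         # homopolymer/dinucleotide run length that kills a TIR
    min_comp_frac: float = 0.20  # minimum G/C and A/T fraction in each TIR arm

    # -- family clustering ----------------------------------------------------
    cluster_identity: float = 0.80   # matches / len(shorter)
    cluster_coverage: float = 0.99   # aligned span / len(longer)
    min_members: int = 3             # smallest valid family

    # -- flank validation ------------------------------------------------------
    flank_len: int = 50              # nt extracted outside each TSD copy
    flank_match_threshold: int = 25  # aligned matches that mark two flanks as shared

    # -- alignment scoring (clustering / flank comparison: global, free end gaps)
    match_score: int = 1
    mismatch_score: int = -1
    gap_score: int = -2

    # -- alignment scoring (representative selection: local) -------------------
    local_match: int = 2
    local_mismatch: int = -3
    local_open: int = -5
    local_extend: int = -2

    # -- engineering -----------------------------------------------------------
    chunk_size: int = 1_000_000
    backend: str = "internal"        # "internal" | "cdhit"
    skip_masked: bool = False        # treat soft-masked bases as unscannable
    seed: int | None = None          # synthetic fixtures only

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tir_len < 2:
            raise ConfigError("tir_len: must be >= 2")
        if self.min_len < 2 * self.tir_len:
            raise ConfigError("min_len: must be >= 2*tir_len")
        if self.max_len < self.min_len:
            raise ConfigError("max_len: must be >= min_len")
        if self.tsd_min < 2:
            raise ConfigError("tsd_min: must be >= 2")
        if self.tsd_max > 10:
            raise ConfigError("tsd_max: must be <= 10")
        if self.tsd_max < self.tsd_min:
            raise ConfigError("tsd_max: must be >= tsd_min")
        if not (0 < self.cluster_identity <= 1):
            raise ConfigError("cluster_identity: must be in (0, 1]")
        if not (0 < self.cluster_coverage <= 1):
            raise ConfigError("cluster_coverage: must be in (0, 1]")
        if self.score_tolerance < 0:
            raise ConfigError("score_tolerance: must be >= 0")
        if self.max_tir_mismatch < 0:
            raise ConfigError("max_tir_mismatch: must be >= 0")
        if self.min_members < 1:
            raise ConfigError("min_members: must be >= 1")
        if self.flank_len < 1:
            raise ConfigError("flank_len: must be >= 1")
        if self.chunk_size < self.max_len + 2 * self.tsd_max:
            raise ConfigError("chunk_size: must exceed max_len + 2*tsd_max")
        if self.backend not in ("internal", "cdhit"):
            raise ConfigError("backend: must be 'internal' or 'cdhit'")

    @property
    def scan_overlap(self) -> int:
        """Chunk overlap guaranteeing no candidate straddles a boundary."""
        return self.max_len + 2 * self.tsd_max

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineConfig)}


def parse_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> PipelineConfig:
    """Resolve a configuration with precedence: override > file > default.

    The file is plain ``key: value`` text (a YAML mapping). Unknown keys and
    invariant violations raise :class:`ConfigError` naming the field.
    """
    values: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path}: expected key: value lines")
        for key, val in raw.items():
            if key not in _FIELD_NAMES:
                raise ConfigError(f"{key}: unknown configuration key")
            values[key] = val
    if overrides:
        for key, val in overrides.items():
            if val is None:
                continue
            if key not in _FIELD_NAMES:
                raise ConfigError(f"{key}: unknown configuration key")
            values[key] = val
    return PipelineConfig(**values)
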