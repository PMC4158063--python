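"""Pipeline configuration shared by every stage.

Defaults mirror the analysis conditions of the sweet-orange sRNAome study
design: reads kept at >= 3 copies per library, 18-30 nt length window,
known-miRNA matching at <= 2 mismatches, CleaveLand-style target penalty
cutoff of 7, 21-nt phasing registers seeded by 22-nt 5'-U triggers, and
MISA-like SSR minimum repeat numbers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def _default_ssr_min_repeats() -> dict[int, int]:
    # mono 8, di 4, tri 3, tetra 3, penta 3, hexa 2
    return {1: 8, 2: 4, 3: 3, 4: 3, 5: 3, 6: 2}


@dataclass
class PipelineConfig:
    min_read_count: int = 3
    read_len_range: tuple[int, int] = (18, 30)
    known_max_mismatch: int = 2
    penalty_threshold: float = 7.0
    phase_length: int = 21
    trigger_length: int = 22
    require_trigger_5pU: bool = True
    fold_change_threshold: float = 2.0
    strong_fold_change_threshold: float = 4.0
    high_tpm_threshold: float = 10.0
    tpm_pseudocount: float = 0.5
    ssr_min_repeats: dict[int, int] = field(default_factory=_default_ssr_min_repeats)
    flank_for_precursor: int = 150
    # novel-miRNA hairpin criteria
    max_duplex_mismatches: int = 4
    max_asym_bulge: int = 2
    min_loop: int = 3
    # degradome
    peak_fraction: float = 0.5
    cleavage_window: int = 1
    # phasing
    phase_min_registers: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.read_len_range = tuple(self.read_len_range)  # type: ignore[assignment]
        lo, hi = self.read_len_range
        if lo > hi:
            raise ValueError("read_len_range min must be <= max")
        for name in (
            "min_read_count",
            "penalty_threshold",
            "phase_length",
            "trigger_length",
            "fold_change_threshold",
            "flank_for_precursor",
            "peak_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.known_max_mismatch < 0:
            raise ValueError("known_max_mismatch must be >= 0")
        if lo <= 0:
            raise ValueError("read lengths must be positive")
        self.ssr_min_repeats = {int(k): int(v) for k, v in self.ssr_min_repeats.items()}
        for u, m in self.ssr_min_repeats.items():
            if u < 1 or m < 1:
                raise ValueError("ssr_min_repeats entries must be positive")

    # -- YAML round trip --------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["read_len_range"] = list(self.read_len_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
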