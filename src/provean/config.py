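"""Run configuration shared by the CLI subcommands (YAML-loadable)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .align import GapConvention, GapPenalties, SubstitutionMatrix
from .homologs import DEFAULT_IDENTITY_THRESHOLD, DEFAULT_MAX_CLUSTERS
from .score import DEFAULT_THRESHOLD

__all__ = ["ProveanConfig"]


@dataclass
class ProveanConfig:
    matrix: str = "BLOSUM62"
    gap_open: int = 10
    gap_extend: int = 1
    gap_convention: str = GapConvention.FIRST_RESIDUE_COSTS_OPEN_ONLY.value
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    max_clusters: int = DEFAULT_MAX_CLUSTERS
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ProveanConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def load_matrix(self) -> SubstitutionMatrix:
        if Path(self.matrix).is_file():
            return SubstitutionMatrix.from_file(self.matrix)
        return SubstitutionMatrix.load(self.matrix)

    def gap_penalties(self) -> GapPenalties:
        return GapPenalties(
            open=self.gap_open,
            extend=self.gap_extend,
            convention=GapConvention(self.gap_convention),
        )
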