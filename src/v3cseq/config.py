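"""Run configuration with validated, convention-matching defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .digest import get_enzyme

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults for a full analysis run.

    The defaults mirror the protocol's stated parameters: HindIII primary
    digestion, top-150 peak calling, permutation nulls of 150 intervals of
    5 kb, stripe profiles of 75 bins, and a 0.8 relative motif-score
    threshold.
    """

    enzyme: str = "HindIII"
    peak_n: int = 150
    n_permutations: int = 1000
    permuted_size_bp: int = 5000
    stripe_bins: int = 75
    rel_threshold: float = 0.8
    max_anchor_mismatches: int = 0
    min_mapq: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        get_enzyme(self.enzyme)  # raises for unknown enzymes
        if self.peak_n < 1:
            raise ValueError("peak_n must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.permuted_size_bp < 1:
            raise ValueError("permuted_size_bp must be >= 1")
        if self.stripe_bins < 1:
            raise ValueError("stripe_bins must be >= 1")
        if not 0 < self.rel_threshold <= 1:
            raise ValueError("rel_threshold must be in (0, 1]")
        if self.max_anchor_mismatches < 0 or self.min_mapq < 0:
            raise ValueError("mismatch and MAPQ limits must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
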