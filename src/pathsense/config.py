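"""Run configuration: validated knobs shared by the CLI and the library."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a search run.

    diameter
        Environment diameter (in bonds) of atomic signatures; even, >= 0.
    max_steps
        Expansion depth, 1 or 2 enzymatic steps.
    threshold
        Tanimoto similarity at or above which a node counts as detectable
        (1.0 = exact fingerprint match only).
    near_threshold
        Advisory lower bound for "near-detectable" reporting.
    fingerprint_width
        Bit width of hashed circular fingerprints.
    bidirectional
        If true, every reversible reaction is matched in both directions.
    max_product_set
        Cap on the number of compounds a product multiset may resolve into.
    max_resolutions
        Cap on enumerated product-sets per reaction application.
    seed
        Seed for fixture generation.
    """

    diameter: int = 12
    max_steps: int = 2
    threshold: float = 1.0
    near_threshold: float = 0.9
    fingerprint_width: int = 2048
    bidirectional: bool = True
    max_product_set: int = 3
    max_resolutions: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter < 0 or self.diameter % 2 != 0:
            raise ValueError(f"diameter must be even and >= 0, got {self.diameter}")
        if self.max_steps not in (1, 2):
            raise ValueError(f"max_steps must be 1 or 2, got {self.max_steps}")
        for name in ("threshold", "near_threshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.fingerprint_width <= 0:
            raise ValueError("fingerprint_width must be positive")
        if self.max_product_set < 1:
            raise ValueError("max_product_set must be >= 1")
        if self.max_resolutions < 1:
            raise ValueError("max_resolutions must be >= 1")

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def header_lines(self, prefix: str = "# ") -> list[str]:
        """Config echo written at the top of every output file."""
        return [f"{prefix}{key}: {value}" for key, value in sorted(self.to_dict().items())]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a key: value config file (YAML subset), apply overrides."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain key: value pairs")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
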