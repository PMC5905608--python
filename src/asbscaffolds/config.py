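"""Pipeline configuration: size rules, fragmentation limits, reproducibility."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters governing fragmentation, pairing and scaffold derivation.

    Attributes
    ----------
    max_substituent_heavy_atoms
        Largest substituent (heavy atoms, attachment point excluded) allowed
        in a fragmentation. Restricts exchanges to the small modifications
        typical of medicinal-chemistry analog series.
    core_to_substituent_min_ratio
        The core must carry at least this many times the substituent's heavy
        atoms, so the conserved part dominates the variable part.
    max_exchange_size_difference
        Maximum heavy-atom difference between the two exchanged substituents
        of a matched molecular pair.
    max_substitution_sites
        Upper bound on attachment points of a scaffold (and on simultaneous
        cuts during multi-cut enumeration).
    min_series_size
        Minimum number of compounds for a connected component of the pair
        network to count as an analog series.
    keep_stereo
        Whether stereochemistry descriptors survive standardization.
    allow_hydrogen_site
        Whether an analog may leave a designated substitution site
        unsubstituted (hydrogen occupies the site).
    disabled_rules
        Retrosynthetic bond classes to switch off, by rule id.
    random_seed
        Seed for any randomized step (fixture generation).
    """

    max_substituent_heavy_atoms: int = 13
    core_to_substituent_min_ratio: float = 2.0
    max_exchange_size_difference: int = 8
    max_substitution_sites: int = 4
    min_series_size: int = 2
    keep_stereo: bool = True
    allow_hydrogen_site: bool = True
    disabled_rules: tuple[str, ...] = ()
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_substituent_heavy_atoms <= 0:
            raise ValueError("max_substituent_heavy_atoms must be positive")
        if self.core_to_substituent_min_ratio <= 0:
            raise ValueError("core_to_substituent_min_ratio must be positive")
        if self.max_exchange_size_difference < 0:
            raise ValueError("max_exchange_size_difference must be >= 0")
        if self.max_substitution_sites <= 0:
            raise ValueError("max_substitution_sites must be positive")
        if self.min_series_size < 2:
            raise ValueError("min_series_size must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "disabled_rules" in data:
            data["disabled_rules"] = tuple(data["disabled_rules"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["disabled_rules"] = list(data["disabled_rules"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["disabled_rules"] = list(data["disabled_rules"])
        return data
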