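"""YAML configuration: reward weights, schema compatibility, rarity, generator.

One file carries all tunables; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict

from .rewards import RewardWeights
from .schema import CompatibilityTable
from .stats import ConfigError, REFERENCE_STATS, StatsTable


class RarityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    threshold: float = 0.05
    entity_counts: Optional[dict[str, int]] = None
    relation_counts: Optional[dict[str, int]] = None

    def stats(self) -> StatsTable:
        if self.entity_counts is None and self.relation_counts is None:
            return REFERENCE_STATS
        return StatsTable(
            entity_counts=self.entity_counts or dict(REFERENCE_STATS.entity_counts),
            relation_counts=self.relation_counts or dict(REFERENCE_STATS.relation_counts),
        )


class AppConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    weights: RewardWeights = RewardWeights()
    rarity: RarityConfig = RarityConfig()
    compatibility: Optional[dict] = None
    generator: dict = {}

    def compatibility_table(self) -> CompatibilityTable:
        if self.compatibility is None:
            return CompatibilityTable.default()
        return CompatibilityTable.from_dict(self.compatibility)


def default_config_text() -> str:
    return (resources.files("drkex") / "data" / "default_config.yaml").read_text()


def load_config(path: Union[str, Path, None] = None) -> AppConfig:
    """Load a YAML config file; ``None`` returns the documented defaults."""
    if path is None:
        return AppConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return AppConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    weights_raw = raw.pop("weights", {}) or {}
    if "length_bounds" in weights_raw:
        weights_raw["length_bounds"] = tuple(weights_raw["length_bounds"])
    try:
        return AppConfig(
            weights=RewardWeights(**weights_raw),
            rarity=RarityConfig(**(raw.pop("rarity", {}) or {})),
            compatibility=raw.pop("compatibility", None),
            generator=raw.pop("generator", {}) or {},
            **raw,  # any leftover key triggers extra="forbid"
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from None
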