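"""Corpus composition tables: per-type counts and relative frequencies.

A :class:`StatsTable` records how often each entity type and each canonical
relation occurs in a reference corpus.  It backs two things: rarity decisions
in the reward (an item is "rare" when its reference share falls below a
threshold) and corpus-statistics reports.  The shipped reference table mirrors
the composition of the published DrugReC drug-repositioning corpus (1000
PubMed abstracts; 9329 entity mentions, 4879 triplets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


class ConfigError(ValueError):
    """Raised for unknown type names or malformed configuration."""


@dataclass(frozen=True)
class StatsTable:
    """Counts and relative frequencies per entity type and canonical relation."""

    entity_counts: dict[str, int] = field(default_factory=dict)
    relation_counts: dict[str, int] = field(default_factory=dict)

    @property
    def entity_total(self) -> int:
        return sum(self.entity_counts.values())

    @property
    def relation_total(self) -> int:
        return sum(self.relation_counts.values())

    def entity_frequency(self, name: str) -> float:
        if name not in self.entity_counts:
            raise ConfigError(f"unknown entity type in stats table: {name!r}")
        total = self.entity_total
        return self.entity_counts[name] / total if total else 0.0

    def relation_frequency(self, name: str) -> float:
        if name not in self.relation_counts:
            raise ConfigError(f"unknown relation in stats table: {name!r}")
        total = self.relation_total
        return self.relation_counts[name] / total if total else 0.0

    def frequency(self, name: str) -> float:
        """Relative frequency of an entity type or canonical relation."""
        if name in self.entity_counts:
            return self.entity_frequency(name)
        if name in self.relation_counts:
            return self.relation_frequency(name)
        raise ConfigError(f"unknown type or relation in stats table: {name!r}")

    def entity_shares(self) -> dict[str, float]:
        total = self.entity_total
        return {k: (v / total if total else 0.0) for k, v in self.entity_counts.items()}

    def relation_shares(self) -> dict[str, float]:
        total = self.relation_total
        return {k: (v / total if total else 0.0) for k, v in self.relation_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "entity", "name": k, "count": v, "share_pct": round(100 * f, 2)}
            for (k, v), f in zip(self.entity_counts.items(), self.entity_shares().values())
        ] + [
            {"kind": "relation", "name": k, "count": v, "share_pct": round(100 * f, 2)}
            for (k, v), f in zip(self.relation_counts.items(), self.relation_shares().values())
        ]
        return pd.DataFrame(rows, columns=["kind", "name", "count", "share_pct"])


# Reference composition of the DrugReC corpus (entity mentions / canonical
# triplets over 1000 abstracts).  Used as the default rarity reference and as
# the default generator mixture.
REFERENCE_ENTITY_COUNTS: dict[str, int] = {
    "disease": 1782,
    "drug": 1474,
    "anatomy": 1271,
    "test": 963,
    "biomarker": 957,
    "complication": 644,
    "target": 583,
    "treatment": 561,
    "symptom": 490,
    "gene": 362,
    "side_effect": 242,
}

REFERENCE_RELATION_COUNTS: dict[str, int] = {
    "is_examination_for": 886,
    "treat": 839,
    "is_biomarker_of": 837,
    "complication_of": 618,
    "is_located_in": 579,
    "is_symptom_of": 449,
    "is_target_of": 349,
    "is_side_effect_of": 303,
    "increases_expression_of": 19,
}

REFERENCE_STATS = StatsTable(
    entity_counts=dict(REFERENCE_ENTITY_COUNTS),
    relation_counts=dict(REFERENCE_RELATION_COUNTS),
)
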