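"""Named-feature containers and the feature registry.

Every feature the pipeline produces is registered to exactly one of four
subgroups: ``task`` (information-unit counts and spatial coverage — task
performance, not language), ``semantic``, ``syntactic`` and
``paralinguistic``.  The registry drives the cross-language screening (task
features are excluded from the generalizable set by definition) and the
Bonferroni multiplier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

SUBGROUPS = ("task", "semantic", "syntactic", "paralinguistic")

MISSING = math.nan


def is_missing(x: float) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class FeatureVector:
    """Values and subgroup registration for one subject's features."""

    subject_id: str = ""
    values: dict[str, float] = field(default_factory=dict)
    registry: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, value: float, subgroup: str) -> None:
        if subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {subgroup!r}")
        if name in self.registry:
            raise ValueError(f"feature {name!r} registered twice")
        self.values[name] = MISSING if value is None else float(value)
        self.registry[name] = subgroup

    def merge(self, other: "FeatureVector") -> "FeatureVector":
        for name, sub in other.registry.items():
            self.add(name, other.values[name], sub)
        return self

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __len__(self) -> int:
        return len(self.values)


def registry_counts(registry: Mapping[str, str]) -> dict[str, int]:
    """Number of registered features per subgroup."""
    out = {s: 0 for s in SUBGROUPS}
    for sub in registry.values():
        out[sub] += 1
    return out
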