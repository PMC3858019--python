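"""Pair-distance reports: the shared result container for all three spaces.

A :class:`PairDistanceReport` records, for one space (network, chemical or
metabolism), the distance of every declared pair, the pair-set mean, the global
mean over all unordered herb pairs, the direction of the comparison, and — once
a permutation test has been attached — an empirical p-value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum

__all__ = ["Direction", "PairDistanceReport"]


class Direction(str, Enum):
    """Direction of the pair-set mean relative to the global mean."""

    GREATER = "GREATER"
    LESS = "LESS"
    INDETERMINATE = "INDETERMINATE"


def _direction(pair_mean: float, global_mean: float) -> Direction:
    if math.isnan(pair_mean) or math.isnan(global_mean):
        return Direction.INDETERMINATE
    if pair_mean > global_mean:
        return Direction.GREATER
    if pair_mean < global_mean:
        return Direction.LESS
    return Direction.INDETERMINATE


@dataclass(frozen=True)
class PairDistanceReport:
    space: str
    pair_distances: tuple[tuple[tuple[str, str], float], ...]
    pair_set_mean: float
    global_mean: float
    n_pairs_used: int
    excluded: tuple[tuple[tuple[str, str], str], ...] = ()
    direction: Direction = Direction.INDETERMINATE
    p_value: float | None = None
    n_perm: int | None = None

    @classmethod
    def build(
        cls,
        space: str,
        pair_distances,
        global_mean: float,
        excluded=(),
    ) -> "PairDistanceReport":
        """Assemble a report; the pair-set mean and direction are derived."""
        pd_ = tuple((tuple(p), float(d)) for p, d in pair_distances)
        vals = [d for _, d in pd_]
        mean = float(sum(vals) / len(vals)) if vals else float("nan")
        return cls(
            space=space,
            pair_distances=pd_,
            pair_set_mean=mean,
            global_mean=float(global_mean),
            n_pairs_used=len(vals),
            excluded=tuple((tuple(p), str(r)) for p, r in excluded),
            direction=_direction(mean, float(global_mean)),
        )

    def with_p_value(self, p: float, n_perm: int) -> "PairDistanceReport":
        return replace(self, p_value=float(p), n_perm=int(n_perm))

    @property
    def all_pairs(self) -> frozenset:
        """Every declared pair, whether used or excluded (identity of the pair set)."""
        return frozenset(p for p, _ in self.pair_distances) | frozenset(
            p for p, _ in self.excluded
        )

    def to_dict(self) -> dict:
        return {
            "space": self.space,
            "pair_distances": [[list(p), d] for p, d in self.pair_distances],
            "pair_set_mean": self.pair_set_mean,
            "global_mean": self.global_mean,
            "n_pairs_used": self.n_pairs_used,
            "excluded": [[list(p), r] for p, r in self.excluded],
            "direction": self.direction.value,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PairDistanceReport":
        return cls(
            space=d["space"],
            pair_distances=tuple((tuple(p), float(v)) for p, v in d["pair_distances"]),
            pair_set_mean=float(d["pair_set_mean"]),
            global_mean=float(d["global_mean"]),
            n_pairs_used=int(d["n_pairs_used"]),
            excluded=tuple((tuple(p), r) for p, r in d.get("excluded", [])),
            direction=Direction(d["direction"]),
            p_value=None if d.get("p_value") is None else float(d["p_value"]),
            n_perm=None if d.get("n_perm") is None else int(d["n_perm"]),
        )

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)
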