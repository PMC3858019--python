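"""Declared herb-pair sets (e.g. the classical incompatible pairs)."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = ["PairSet", "canonical_pair"]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PairSet:
    """An unordered, duplicate-free set of herb-ID pairs with an optional label.

    Pairs are stored canonically ordered (lexicographically within each pair),
    in first-seen order, so iteration is deterministic.
    """

    pairs: tuple[tuple[str, str], ...]
    label: str = field(default="incompatible")

    @classmethod
    def from_pairs(cls, pairs, label: str = "incompatible") -> "PairSet":
        seen: dict[tuple[str, str], None] = {}
        for a, b in pairs:
            a, b = str(a).strip(), str(b).strip()
            if not a or not b:
                raise ValidationError(f"empty herb ID in pair ({a!r}, {b!r})")
            if a == b:
                raise ValidationError(f"pair of identical IDs: {a!r}")
            seen.setdefault(canonical_pair(a, b))
        if not seen:
            raise ValidationError("pair set is empty")
        return cls(pairs=tuple(seen), label=label)

    @property
    def herbs(self) -> tuple[str, ...]:
        return tuple(sorted({h for p in self.pairs for h in p}))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __contains__(self, pair) -> bool:
        a, b = pair
        return canonical_pair(a, b) in set(self.pairs)
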