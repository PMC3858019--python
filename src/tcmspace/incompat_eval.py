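"""Pair-set significance testing and the three-space verdict.

The underlying comparison is always the same: the mean distance of a declared
pair set (e.g. the classically incompatible herb pairs) against the global mean
over all herb pairs in that space. The classical incompatibility hypothesis
predicts a direction per space: incompatible pairs sit *farther apart* than
average in the formula network (they are rarely co-prescribed) and in chemical
space (their overall chemistries differ), but *closer together* in the
metabolism room (their compounds compete for the same CYP450 enzymes).

Significance is assessed by a Monte-Carlo permutation test: the null resamples
pair sets of the same size uniformly without replacement from all available
pairs, and the empirical p-value uses the standard +1 smoothing
p = (1 + #{null means at least as extreme}) / (n_perm + 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InvalidPairCount, PairSetMismatch
from .report import Direction, PairDistanceReport

__all__ = [
    "PermutationResult",
    "permutation_null",
    "attach_permutation",
    "IncompatEvaluation",
    "evaluate",
    "EXPECTED_DIRECTIONS",
]

#: Per-space directions under the classical incompatibility hypothesis.
EXPECTED_DIRECTIONS: dict[str, Direction] = {
    "network": Direction.GREATER,
    "chemical": Direction.GREATER,
    "metabolism": Direction.LESS,
}


@dataclass(frozen=True)
class PermutationResult:
    null_means: np.ndarray
    observed_mean: float
    p_value: float
    direction: str
    n_perm: int


def _draw_index_sets(rng: np.random.Generator, n: int, k: int, n_perm: int) -> np.ndarray:
    """(n_perm, k) indices, each row k distinct uniform draws from range(n).

    Chunked argpartition over random keys keeps memory bounded for large n.
    """
    out = np.empty((n_perm, k), dtype=np.intp)
    chunk = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        keys = rng.random((stop - start, n))
        out[start:stop] = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return out


def permutation_null(
    all_pair_distances,
    observed_mean: float,
    k: int,
    n_perm: int = 999,
    seed=None,
    direction: Direction | str = Direction.GREATER,
) -> PermutationResult:
    """Null distribution of the mean distance of k pairs drawn uniformly
    without replacement from ``all_pair_distances``, and the empirical p-value
    of ``observed_mean`` in the stated direction.

    ``direction`` may be GREATER, LESS, or the string "two-sided" (twice the
    smaller one-sided p, capped at 1).
    """
    dist = np.asarray(all_pair_distances, dtype=float)
    n = dist.size
    if not (1 <= k <= n):
        raise InvalidPairCount(f"pair-set size k={k} outside [1, {n}]")
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = _draw_index_sets(rng, n, k, n_perm)
    null_means = dist[idx].mean(axis=1)
    p_greater = (1.0 + np.count_nonzero(null_means >= observed_mean)) / (n_perm + 1.0)
    p_less = (1.0 + np.count_nonzero(null_means <= observed_mean)) / (n_perm + 1.0)
    if direction == Direction.GREATER:
        p, dlabel = p_greater, Direction.GREATER.value
    elif direction == Direction.LESS:
        p, dlabel = p_less, Direction.LESS.value
    elif str(direction) in ("two-sided", "Direction.INDETERMINATE"):
        p, dlabel = min(1.0, 2.0 * min(p_greater, p_less)), "two-sided"
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    return PermutationResult(
        null_means=null_means,
        observed_mean=float(observed_mean),
        p_value=float(p),
        direction=dlabel,
        n_perm=n_perm,
    )


def attach_permutation(
    report: PairDistanceReport,
    all_pair_distances,
    n_perm: int = 999,
    seed=None,
    direction: Direction | str | None = None,
) -> PairDistanceReport:
    """Attach a permutation p-value to a report.

    ``all_pair_distances`` must contain only pairs exchangeable with the
    observed ones (for the network space: finite path distances only, matching
    the exclusion of unreachable declared pairs from the observed mean). The
    test direction defaults to the space's classically expected direction.
    """
    if direction is None:
        direction = EXPECTED_DIRECTIONS.get(report.space, "two-sided")
    res = permutation_null(
        all_pair_distances,
        observed_mean=report.pair_set_mean,
        k=report.n_pairs_used,
        n_perm=n_perm,
        seed=seed,
        direction=direction,
    )
    return report.with_p_value(res.p_value, n_perm)


@dataclass(frozen=True)
class IncompatEvaluation:
    """Combined verdict over the three spaces.

    ``verdicts`` maps each space to its observed direction, the direction the
    incompatibility hypothesis expects there, whether they agree
    (``consistent``), and the permutation p-value when present.
    """

    reports: dict
    verdicts: dict

    @property
    def all_consistent(self) -> bool:
        return all(v["consistent"] for v in self.verdicts.values())

    def to_dict(self) -> dict:
        return {
            "reports": {s: r.to_dict() for s, r in sorted(self.reports.items())},
            "verdicts": {s: dict(v) for s, v in sorted(self.verdicts.items())},
            "all_consistent": self.all_consistent,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def summary(self) -> str:
        lines = [
            "Incompatible-pair evaluation",
            "=" * 74,
            f"{'space':<12}{'pair mean':>12}{'global mean':>13}{'direction':>15}"
            f"{'p':>9}{'consistent':>12}",
            "-" * 74,
        ]
        for s in sorted(self.verdicts):
            v = self.verdicts[s]
            r = self.reports[s]
            p = "-" if r.p_value is None else f"{r.p_value:.4f}"
            lines.append(
                f"{s:<12}{r.pair_set_mean:>12.4f}{r.global_mean:>13.4f}"
                f"{v['direction']:>15}{p:>9}{str(v['consistent']):>12}"
            )
        lines.append("-" * 74)
        lines.append(f"all spaces consistent with the incompatibility hypothesis: "
                     f"{self.all_consistent}")
        return "\n".join(lines)


def evaluate(
    network: PairDistanceReport,
    chemical: PairDistanceReport,
    metabolism: PairDistanceReport,
    expected: dict | None = None,
) -> IncompatEvaluation:
    """Combine the three per-space reports into one verdict table.

    All three reports must concern the same declared pair set (checked by pair
    identity, including pairs a space excluded); a space is "consistent" when
    its observed direction equals the expected one (INDETERMINATE never is).
    """
    expected = dict(EXPECTED_DIRECTIONS if expected is None else expected)
    reports = {"network": network, "chemical": chemical, "metabolism": metabolism}
    pair_ids = {s: r.all_pairs for s, r in reports.items()}
    if len(set(pair_ids.values())) != 1:
        raise PairSetMismatch(
            "reports built from different pair sets: "
            + ", ".join(f"{s}:{len(p)} pairs" for s, p in sorted(pair_ids.items()))
        )
    verdicts = {}
    for s, r in reports.items():
        exp = Direction(expected[s])
        consistent = r.direction == exp and r.direction != Direction.INDETERMINATE
        verdicts[s] = {
            "direction": r.direction.value,
            "expected": exp.value,
            "consistent": bool(consistent),
            "p_value": r.p_value,
        }
    return IncompatEvaluation(reports=reports, verdicts=verdicts)
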