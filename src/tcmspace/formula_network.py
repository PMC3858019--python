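"""Herb co-occurrence network built from a collection of multi-herb formulas.

Two herbs are connected whenever they appear together in at least one formula;
the edge keeps the co-occurrence count, but every topological statistic
(shortest paths, clustering, degree) is computed on the unweighted graph, since
a single shared formula already establishes the relationship.

Statistics follow the small-world / scale-free toolkit: diameter ``D`` (largest
finite shortest-path length), average path length ``L`` (mean over reachable
unordered pairs), per-node clustering ``C_i`` (fraction of a node's neighbour
pairs that are themselves connected, 0 for degree < 2), average degree
``2E/N``, and the empirical degree distribution ``P(k)`` with a power-law fit
``P(k) ∝ k^{-γ}`` by ordinary least squares on the log10–log10 mass function.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats as _stats

from .errors import (
    DegenerateGraph,
    DuplicateRecord,
    EmptyInput,
    InsufficientSupport,
    UnknownHerb,
    ValidationError,
)
from .pairs import PairSet
from .report import PairDistanceReport

__all__ = [
    "UNREACHABLE",
    "FormulaCollection",
    "PathMatrix",
    "NetworkStats",
    "DegreeDistribution",
    "PowerLawFit",
    "build_cooccurrence_network",
    "shortest_paths",
    "network_stats",
    "node_metrics",
    "degree_distribution",
    "fit_power_law",
    "pairset_path_distance",
]

#: Sentinel path length for node pairs in different connected components.
UNREACHABLE = math.inf


@dataclass(frozen=True)
class FormulaCollection:
    """A collection of formulas, each mapping a formula ID to its herb set.

    Herb lists are deduplicated (first occurrence kept) at construction, so a
    herb repeated within one formula cannot create a self-loop or double-count
    an edge downstream.
    """

    formulas: tuple[tuple[str, tuple[str, ...]], ...]

    @classmethod
    def from_records(cls, records) -> "FormulaCollection":
        records = list(records)
        if not records:
            raise EmptyInput("formula collection is empty")
        seen_ids: set[str] = set()
        out = []
        for fid, herbs in records:
            fid = str(fid).strip()
            if not fid:
                raise ValidationError("formula with empty ID")
            if fid in seen_ids:
                raise DuplicateRecord(f"duplicate formula_id: {fid!r}")
            seen_ids.add(fid)
            dedup: dict[str, None] = {}
            for h in herbs:
                h = str(h).strip()
                if not h:
                    raise ValidationError(f"formula {fid!r} contains an empty herb ID")
                dedup.setdefault(h)
            if not dedup:
                raise ValidationError(f"formula {fid!r} has no herbs")
            out.append((fid, tuple(dedup)))
        return cls(formulas=tuple(out))

    @property
    def herbs(self) -> tuple[str, ...]:
        """Sorted union of all herb IDs appearing in at least one formula."""
        return tuple(sorted({h for _, hs in self.formulas for h in hs}))

    def __len__(self) -> int:
        return len(self.formulas)

    def __iter__(self):
        return iter(self.formulas)


def build_cooccurrence_network(collection: FormulaCollection) -> nx.Graph:
    """Build the co-occurrence graph: one node per herb, one edge per pair that
    shares at least one formula, with a ``count`` attribute giving the number of
    shared formulas.

    Nodes are inserted in sorted herb-ID order, making iteration order (and
    every downstream output) independent of formula order.
    """
    if isinstance(collection, (list, tuple)):
        collection = FormulaCollection.from_records(collection)
    if not len(collection):
        raise EmptyInput("formula collection is empty")
    net = nx.Graph()
    net.add_nodes_from(collection.herbs)
    counts: dict[tuple[str, str], int] = {}
    for _, herbs in collection:
        for a, b in itertools.combinations(sorted(set(herbs)), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    for (a, b) in sorted(counts):
        net.add_edge(a, b, count=counts[(a, b)])
    return net


@dataclass(frozen=True)
class PathMatrix:
    """All-pairs unweighted shortest-path lengths (edge counts).

    ``lengths[i, j]`` is the BFS distance between ``nodes[i]`` and ``nodes[j]``
    or :data:`UNREACHABLE` across components; the diagonal is zero.
    """

    nodes: tuple[str, ...]
    lengths: np.ndarray  # (n, n) float array, inf = unreachable

    def get(self, a: str, b: str) -> float:
        idx = self.index
        try:
            return float(self.lengths[idx[a], idx[b]])
        except KeyError as e:
            raise UnknownHerb(f"herb not in network: {e.args[0]!r}") from None

    @property
    def index(self) -> dict[str, int]:
        return {h: i for i, h in enumerate(self.nodes)}

    def finite_upper(self) -> np.ndarray:
        """Finite distances over unordered pairs i<j (the reachable pairs)."""
        n = len(self.nodes)
        iu = np.triu_indices(n, k=1)
        vals = self.lengths[iu]
        return vals[np.isfinite(vals)]


def shortest_paths(net: nx.Graph) -> PathMatrix:
    """BFS shortest-path lengths for every ordered node pair."""
    if net.number_of_nodes() == 0:
        raise EmptyInput("network has no nodes")
    nodes = tuple(sorted(net.nodes))
    idx = {h: i for i, h in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), UNREACHABLE)
    np.fill_diagonal(d, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(net):
        i = idx[src]
        for dst, dist in lengths.items():
            d[i, idx[dst]] = dist
    return PathMatrix(nodes=nodes, lengths=d)


@dataclass(frozen=True)
class NetworkStats:
    diameter: int
    average_distance: float
    average_clustering: float
    average_degree: float
    n_nodes: int
    n_edges: int
    n_components: int

    def to_dict(self) -> dict:
        return {
            "diameter": self.diameter,
            "average_distance": self.average_distance,
            "average_clustering": self.average_clustering,
            "average_degree": self.average_degree,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_components": self.n_components,
        }


def network_stats(net: nx.Graph, pm: PathMatrix | None = None) -> NetworkStats:
    """Topological summary of the network.

    ``average_distance`` is the mean over reachable unordered pairs only;
    ``n_components`` is reported so callers can see when that restriction
    matters. Raises :class:`DegenerateGraph` when no two nodes are connected
    (diameter and average distance undefined).
    """
    if net.number_of_nodes() == 0:
        raise EmptyInput("network has no nodes")
    if pm is None:
        pm = shortest_paths(net)
    finite = pm.finite_upper()
    if finite.size == 0:
        raise DegenerateGraph("no reachable node pairs: diameter/average distance undefined")
    clustering = nx.clustering(net)  # C_i = 0 for degree < 2
    n = net.number_of_nodes()
    e = net.number_of_edges()
    return NetworkStats(
        diameter=int(finite.max()),
        average_distance=float(finite.mean()),
        average_clustering=float(sum(clustering.values()) / n),
        average_degree=2.0 * e / n,
        n_nodes=n,
        n_edges=e,
        n_components=nx.number_connected_components(net),
    )


def node_metrics(net: nx.Graph):
    """Per-herb degree ``k_i`` and clustering ``C_i`` as a DataFrame."""
    import pandas as pd

    nodes = sorted(net.nodes)
    clustering = nx.clustering(net)
    return pd.DataFrame(
        {
            "degree": [net.degree(h) for h in nodes],
            "clustering": [clustering[h] for h in nodes],
        },
        index=pd.Index(nodes, name="herb_id"),
    )


@dataclass(frozen=True)
class DegreeDistribution:
    """Empirical degree mass function P(k) over observed degrees."""

    support: np.ndarray  # sorted distinct degrees
    probabilities: np.ndarray  # P(k), sums to 1
    counts: np.ndarray  # node counts per degree

    @property
    def mean_degree(self) -> float:
        return float(np.dot(self.support, self.probabilities))


def degree_distribution(net: nx.Graph) -> DegreeDistribution:
    if net.number_of_nodes() == 0:
        raise EmptyInput("network has no nodes")
    degrees = np.array([d for _, d in net.degree()], dtype=int)
    support, counts = np.unique(degrees, return_counts=True)
    return DegreeDistribution(
        support=support,
        probabilities=counts / counts.sum(),
        counts=counts,
    )


@dataclass(frozen=True)
class PowerLawFit:
    """Fit of P(k) ∝ k^{-γ}.

    ``gamma`` is minus the slope of the OLS regression of log10 P(k) on
    log10 k (method "ols"), or the discrete maximum-likelihood exponent
    (method "mle", Clauset-style continuous approximation). The log-log
    regression diagnostics are reported for either method.
    """

    gamma: float
    slope: float
    intercept: float
    r_squared: float
    method: str
    n_support: int


def fit_power_law(dd: DegreeDistribution, method: str = "ols") -> PowerLawFit:
    mask = (dd.support > 0) & (dd.probabilities > 0)
    k = dd.support[mask].astype(float)
    pk = dd.probabilities[mask].astype(float)
    if len(np.unique(k)) < 3:
        raise InsufficientSupport(
            f"need >= 3 distinct positive degrees with P(k) > 0, got {len(np.unique(k))}"
        )
    res = _stats.linregress(np.log10(k), np.log10(pk))
    if method == "ols":
        gamma = -res.slope
    elif method == "mle":
        # discrete MLE: maximize the zeta likelihood P(k) = k^-g / ζ(g, kmin)
        # over k >= kmin, with counts as frequency weights
        from scipy.optimize import minimize_scalar
        from scipy.special import zeta

        counts = dd.counts[mask].astype(float)
        kmin = k.min()
        n = counts.sum()
        slogk = float(np.dot(counts, np.log(k)))

        def negloglik(g):
            return n * np.log(zeta(g, kmin)) + g * slogk

        opt = minimize_scalar(negloglik, bounds=(1.0 + 1e-9, 20.0), method="bounded")
        gamma = opt.x
    else:
        raise ValueError(f"unknown method: {method!r}")
    return PowerLawFit(
        gamma=float(gamma),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        method=method,
        n_support=int(mask.sum()),
    )


def pairset_path_distance(pm: PathMatrix, pairs: PairSet) -> PairDistanceReport:
    """Path distances of a declared pair set against the network's average
    distance (the global mean over all reachable unordered pairs).

    Pairs whose members sit in different components are listed under
    ``excluded`` with reason "unreachable" and left out of the pair-set mean.
    """
    idx = pm.index
    used, excluded = [], []
    for a, b in pairs:
        if a not in idx:
            raise UnknownHerb(f"pair member not in network: {a!r}")
        if b not in idx:
            raise UnknownHerb(f"pair member not in network: {b!r}")
        d = float(pm.lengths[idx[a], idx[b]])
        if math.isinf(d):
            excluded.append(((a, b), "unreachable"))
        else:
            used.append(((a, b), d))
    finite = pm.finite_upper()
    global_mean = float(finite.mean()) if finite.size else float("nan")
    return PairDistanceReport.build(
        space="network", pair_distances=used, global_mean=global_mean, excluded=excluded
    )
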