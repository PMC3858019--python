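"""Descriptor spaces: weight-center treatment, PCA projection, 3D distances.

The same machinery serves two spaces: a "chemical space" built from molecular
descriptors of every compound (120 columns in the reference setting) and a
"metabolism room" built from docking scores of every compound against a panel
of cytochrome P450 enzymes (one column per enzyme, 15 in the reference
setting).

The pipeline per space:

1. *Weight-center treatment*: every herb's compounds are collapsed to a single
   point, the mass-weighted centroid of their descriptor vectors (equal masses
   by default — relative compound abundances are usually unknown).
2. *Projection*: herb centroids are z-score standardized per descriptor and
   projected onto the top principal components (3 by default, so herbs live in
   an (X, Y, Z) coordinate system); explained-variance ratios are reported and
   a cumulative ratio below 80% triggers a warning.
3. *Spatial distance*: D = [(X_j − X_i)² + (Y_j − Y_i)² + (Z_j − Z_i)²]^1/2 in
   the embedded coordinates — deliberately the 3D distance, not the full
   descriptor-space distance (available separately for diagnostics).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import (
    EmptyGroup,
    InsufficientData,
    InvalidMass,
    SpaceMismatch,
    UnknownHerb,
    ValidationError,
)
from .pairs import PairSet
from .report import PairDistanceReport

__all__ = [
    "CompoundDescriptorTable",
    "HerbCentroids",
    "SpaceEmbedding",
    "EmbeddedPoint",
    "weight_center",
    "project",
    "spatial_distance",
    "distance_summary",
    "centroid_distance_matrix",
]

_META_COLUMNS = ("compound_id", "herb_id", "mass")


@dataclass(frozen=True)
class CompoundDescriptorTable:
    """Per-compound descriptor vectors tagged with their parent herb.

    ``data`` holds columns ``compound_id``, ``herb_id``, ``mass`` plus the
    numeric descriptor columns; ``descriptor_columns`` fixes their order.
    """

    data: pd.DataFrame
    descriptor_columns: tuple[str, ...]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        descriptor_columns=None,
        impute_missing: bool = False,
    ) -> "CompoundDescriptorTable":
        df = df.copy()
        for col in ("compound_id", "herb_id"):
            if col not in df.columns:
                raise ValidationError(f"missing required column {col!r}")
        if "mass" not in df.columns:
            df["mass"] = 1.0
        if descriptor_columns is None:
            descriptor_columns = [c for c in df.columns if c not in _META_COLUMNS]
        descriptor_columns = tuple(descriptor_columns)
        if len(descriptor_columns) < 2:
            raise ValidationError(
                f"need at least 2 descriptor columns, got {len(descriptor_columns)}"
            )
        if df.empty:
            raise ValidationError("descriptor table has no rows")
        if df["compound_id"].duplicated().any():
            dups = df.loc[df["compound_id"].duplicated(), "compound_id"].tolist()
            raise ValidationError(f"duplicate compound IDs: {dups[:5]}")
        desc = df[list(descriptor_columns)].apply(pd.to_numeric, errors="coerce")
        if desc.isna().any().any():
            if impute_missing:
                desc = desc.fillna(desc.mean())
            else:
                rows, cols_ = np.where(desc.isna().to_numpy())
                bad = [
                    (str(df.iloc[r]["compound_id"]), descriptor_columns[c])
                    for r, c in zip(rows, cols_)
                ][:5]
                raise ValidationError(f"missing/non-numeric descriptor values at {bad}")
        df[list(descriptor_columns)] = desc
        mass = pd.to_numeric(df["mass"], errors="coerce")
        if not np.all(np.isfinite(mass)) or (mass <= 0).any():
            raise InvalidMass("all masses must be finite and > 0")
        df["mass"] = mass.astype(float)
        df = df.reset_index(drop=True)
        return cls(data=df, descriptor_columns=descriptor_columns)

    @property
    def herb_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["herb_id"].unique()))

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_columns)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class HerbCentroids:
    """One point per herb: the mass-weighted mean of its compound vectors."""

    centroids: pd.DataFrame  # index herb_id (sorted), columns = descriptors
    n_compounds: pd.Series
    total_mass: pd.Series

    @property
    def herb_ids(self) -> tuple[str, ...]:
        return tuple(self.centroids.index)


def weight_center(table: CompoundDescriptorTable, herbs=None) -> HerbCentroids:
    """Collapse each herb's compound cloud to its (mass-weighted) centroid.

    ``herbs`` optionally declares the expected herb vocabulary; a declared herb
    with no compounds raises :class:`EmptyGroup`.
    """
    df = table.data
    cols = list(table.descriptor_columns)
    if herbs is not None:
        missing = sorted(set(herbs) - set(df["herb_id"]))
        if missing:
            raise EmptyGroup(f"herbs with zero compounds: {missing[:5]}")
    w = df["mass"].to_numpy()[:, None]
    weighted = df[cols].to_numpy() * w
    num = pd.DataFrame(weighted, index=df["herb_id"]).groupby(level=0).sum()
    denom = df.groupby("herb_id")["mass"].sum()
    centroids = num.div(denom, axis=0)
    centroids.columns = cols
    centroids = centroids.sort_index()
    centroids.index.name = "herb_id"
    return HerbCentroids(
        centroids=centroids,
        n_compounds=df.groupby("herb_id").size().reindex(centroids.index),
        total_mass=denom.reindex(centroids.index),
    )


def centroid_distance_matrix(centroids: HerbCentroids) -> pd.DataFrame:
    """Full descriptor-space Euclidean distances between herb centroids
    (diagnostic; the spatial distance of record is the 3D embedded one)."""
    m = squareform(pdist(centroids.centroids.to_numpy()))
    return pd.DataFrame(m, index=centroids.centroids.index, columns=centroids.centroids.index)


@dataclass(frozen=True)
class EmbeddedPoint:
    herb_id: str
    coordinates: tuple[float, ...]
    space_id: str


@dataclass(frozen=True)
class SpaceEmbedding:
    """Per-herb coordinates in the reduced space plus the PCA bookkeeping.

    ``loadings`` has orthonormal columns (one per retained component);
    ``explained_variance_ratios`` are non-increasing and sum to
    ``cumulative_ratio`` ≤ 1. ``space_id`` fingerprints the embedding so
    distances between points of different embeddings are refused.
    """

    coordinates: pd.DataFrame  # index herb_id, columns X, Y, Z (or PC<i>)
    loadings: pd.DataFrame  # index descriptor, columns as coordinates
    explained_variance_ratios: tuple[float, ...]
    cumulative_ratio: float
    standardization_mean: pd.Series
    standardization_sd: pd.Series
    dropped_descriptors: tuple[str, ...] = ()
    scaled: bool = True
    space_id: str = field(default="")

    @property
    def herb_ids(self) -> tuple[str, ...]:
        return tuple(self.coordinates.index)

    def point(self, herb_id: str) -> EmbeddedPoint:
        if herb_id not in self.coordinates.index:
            raise UnknownHerb(f"herb not embedded: {herb_id!r}")
        return EmbeddedPoint(
            herb_id=herb_id,
            coordinates=tuple(float(v) for v in self.coordinates.loc[herb_id]),
            space_id=self.space_id,
        )

    def distance_matrix(self) -> pd.DataFrame:
        m = squareform(pdist(self.coordinates.to_numpy()))
        return pd.DataFrame(m, index=self.coordinates.index, columns=self.coordinates.index)


def _axis_names(k: int) -> list[str]:
    base = ["X", "Y", "Z"]
    return base[:k] if k <= 3 else base + [f"PC{i}" for i in range(4, k + 1)]


def project(
    centroids: HerbCentroids,
    n_components: int = 3,
    scale: bool = True,
) -> SpaceEmbedding:
    """Standardize herb centroids per descriptor and project onto the top
    principal components.

    With ``scale=True`` (default) each descriptor is z-scored, i.e. the PCA is
    of the correlation structure — the appropriate choice when descriptors
    carry wildly different units. Zero-variance descriptors are dropped with a
    warning before standardization. Loadings follow a fixed sign convention
    (largest-magnitude entry positive) so coordinates are reproducible across
    linear-algebra backends; distances are unaffected.
    """
    X = centroids.centroids
    n, p = X.shape
    if n < n_components + 1:
        raise InsufficientData(
            f"need at least {n_components + 1} herbs for {n_components} components, got {n}"
        )
    sd_all = X.std(axis=0, ddof=1)
    dropped = tuple(sd_all.index[sd_all.to_numpy() == 0.0])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance descriptor(s) before standardization",
            stacklevel=2,
        )
        X = X.drop(columns=list(dropped))
    if X.shape[1] < n_components:
        raise InsufficientData(
            f"only {X.shape[1]} informative descriptors for {n_components} components"
        )
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    Xs = (X - mean) / sd if scale else X - mean
    A = Xs.to_numpy(dtype=float)
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    comps = vt[:n_components]
    # sign convention: largest-|loading| entry of each component made positive
    for i in range(n_components):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    scores = A @ comps.T
    var = s**2
    ratios = tuple(float(v) for v in var[:n_components] / var.sum())
    cumulative = float(sum(ratios))
    if cumulative < 0.80:
        warnings.warn(
            f"cumulative contribution rate of the {n_components} retained components "
            f"is {cumulative:.1%} (< 80%): the reduced space may lose information",
            stacklevel=2,
        )
    axes = _axis_names(n_components)
    coords = pd.DataFrame(scores, index=X.index, columns=axes)
    loadings = pd.DataFrame(comps.T, index=X.columns, columns=axes)
    digest = hashlib.sha1(
        np.ascontiguousarray(np.round(scores, 9)).tobytes()
        + ",".join(X.index).encode()
    ).hexdigest()[:16]
    return SpaceEmbedding(
        coordinates=coords,
        loadings=loadings,
        explained_variance_ratios=ratios,
        cumulative_ratio=cumulative,
        standardization_mean=mean,
        standardization_sd=sd if scale else pd.Series(1.0, index=X.columns),
        dropped_descriptors=dropped,
        scaled=scale,
        space_id=digest,
    )


def spatial_distance(a: EmbeddedPoint, b: EmbeddedPoint) -> float:
    """Euclidean distance between two embedded herbs (3D in the default
    setting): D = [(X_j−X_i)² + (Y_j−Y_i)² + (Z_j−Z_i)²]^1/2."""
    if a.space_id != b.space_id:
        raise SpaceMismatch(
            f"points from different embeddings: {a.space_id} vs {b.space_id}"
        )
    u = np.asarray(a.coordinates) - np.asarray(b.coordinates)
    return float(np.sqrt(np.dot(u, u)))


def distance_summary(
    emb: SpaceEmbedding, pairs: PairSet, space: str = "chemical"
) -> PairDistanceReport:
    """Per-pair embedded distances against the global mean distance over all
    C(n, 2) unordered herb pairs in the embedding."""
    coords = emb.coordinates
    for a, b in pairs:
        for h in (a, b):
            if h not in coords.index:
                raise UnknownHerb(f"pair member not embedded: {h!r}")
    P = coords.to_numpy()
    idx = {h: i for i, h in enumerate(coords.index)}
    used = []
    for a, b in pairs:
        u = P[idx[a]] - P[idx[b]]
        used.append(((a, b), float(np.sqrt(np.dot(u, u)))))
    global_mean = float(pdist(P).mean()) if len(coords) > 1 else float("nan")
    return PairDistanceReport.build(space=space, pair_distances=used, global_mean=global_mean)
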