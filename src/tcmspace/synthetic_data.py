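"""Synthetic study generator.

Emulates the statistical structure the analysis assumes, at configurable
scale, so every stage is testable without the proprietary source databases:

* a formula collection with right-skewed herb popularity (Zipf-weighted
  sampling), within which a set of planted "incompatible" pairs never
  co-occurs (rejection sampling keeps formula sizes as drawn);
* per-herb compound clouds scattered around latent herb centroids that carry a
  low-dimensional cluster structure, mapped into descriptor space through an
  orthonormal basis — low-rank by design, so that three principal components
  capture the bulk of the variance, as observed for real descriptor and
  CYP-docking tables;
* a controllable chemical separation effect (planted pairs' centroids pushed
  apart along their separating direction) and metabolism attraction effect
  (planted pairs' centroids pulled toward their midpoint).

All randomness flows from a single seed through one numpy Generator, so a
config reproduces its study byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationFailure, ValidationError
from .feature_space import CompoundDescriptorTable
from .formula_network import FormulaCollection
from .pairs import PairSet, canonical_pair

__all__ = ["StudyConfig", "SyntheticStudy", "gen_formulas", "gen_descriptor_table", "gen_study"]

_MAX_TRIES = 1000


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one synthetic study.

    Scales default to a small, fast world (50 herbs, 100 formulas, ~5 compounds
    per herb); :meth:`reference_scale` is a preset at the reference study's scale
    (383 herbs, 362 formulas, ~8,500 compounds). Effect sizes are in descriptor
    units: ``within_herb_sd`` is the isotropic per-descriptor scatter of
    compounds around their herb centroid, and the two planted effects default
    to 10 of those units (5.0), comfortably above the scatter.
    """

    n_herbs: int = 50
    n_formulas: int = 100
    formula_size_min: int = 4
    formula_size_max: int = 10
    zipf_exponent: float = 1.0
    n_incompatible_pairs: int = 10
    compounds_per_herb: float = 5.0  # Poisson mean, floored at 1 per herb
    p_chemical: int = 120
    p_metabolism: int = 15
    n_clusters: int = 5
    latent_dim: int = 3
    cluster_spread: float = 3.0  # sd of cluster means per latent axis
    herb_scatter: float = 1.0  # sd of herb centroid around its cluster mean
    within_herb_sd: float = 0.5  # sd of compounds around their herb centroid
    chemical_separation: float = 5.0  # δ_chem: extra separation of planted pairs
    metabolism_attraction: float = 5.0  # δ_met: pull of planted pairs toward midpoint
    network_exclusion: bool = True  # planted pairs never share a formula
    seed: int = 0

    def __post_init__(self):
        if min(self.n_herbs, self.n_formulas, self.p_chemical, self.p_metabolism,
               self.n_clusters, self.latent_dim, self.formula_size_min) < 1:
            raise ValidationError("all counts must be positive")
        if self.formula_size_max < self.formula_size_min:
            raise ValidationError("formula_size_max < formula_size_min")
        if self.formula_size_max > self.n_herbs:
            raise ValidationError("formula_size_max exceeds n_herbs")
        if self.n_incompatible_pairs < 0:
            raise ValidationError("n_incompatible_pairs must be >= 0")
        if 2 * self.n_incompatible_pairs > self.n_herbs:
            raise ValidationError(
                "planted pairs use disjoint herbs: need n_herbs >= 2 * n_incompatible_pairs"
            )
        if self.n_incompatible_pairs > math.comb(self.n_herbs, 2):
            raise ValidationError("more planted pairs than available herb pairs")
        if min(self.chemical_separation, self.metabolism_attraction) < 0:
            raise ValidationError("effect sizes must be >= 0")
        if min(self.cluster_spread, self.herb_scatter) < 0 or self.within_herb_sd < 0:
            raise ValidationError("scatter parameters must be >= 0")
        if self.compounds_per_herb <= 0 or self.zipf_exponent < 0:
            raise ValidationError("compounds_per_herb must be > 0, zipf_exponent >= 0")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "StudyConfig":
        """A no-effect world: planted pairs exist as labels but have no
        network exclusion and zero chemical/metabolism displacement."""
        kw = dict(
            chemical_separation=0.0,
            metabolism_attraction=0.0,
            network_exclusion=False,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def reference_scale(cls, seed: int = 0, **overrides) -> "StudyConfig":
        """Preset at the reference study's scale: 383 herbs, 362 formulas,
        ~8,514 compounds, 120 chemical descriptors, 15 CYP enzymes, 37
        classical incompatible pairs."""
        kw = dict(
            n_herbs=383,
            n_formulas=362,
            formula_size_min=4,
            formula_size_max=12,
            n_incompatible_pairs=37,
            compounds_per_herb=8514 / 383,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **kw) -> "StudyConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _herb_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"H{i:0{width}d}" for i in range(1, n + 1)]


def _draw_planted_pairs(cfg: StudyConfig, rng: np.random.Generator) -> PairSet | None:
    if cfg.n_incompatible_pairs == 0:
        return None
    herbs = _herb_ids(cfg.n_herbs)
    chosen = rng.choice(cfg.n_herbs, size=2 * cfg.n_incompatible_pairs, replace=False)
    pairs = [
        canonical_pair(herbs[chosen[2 * i]], herbs[chosen[2 * i + 1]])
        for i in range(cfg.n_incompatible_pairs)
    ]
    return PairSet.from_pairs(pairs, label="planted-incompatible")


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1, dtype=float) ** s
    return w / w.sum()


def _gen_formulas(
    cfg: StudyConfig, rng: np.random.Generator, planted: PairSet | None
) -> FormulaCollection:
    herbs = _herb_ids(cfg.n_herbs)
    weights = _zipf_weights(cfg.n_herbs, cfg.zipf_exponent)
    forbidden: set[frozenset] = set()
    if planted is not None and cfg.network_exclusion:
        forbidden = {frozenset(p) for p in planted}
    partner: dict[str, set[str]] = {}
    for fs in forbidden:
        a, b = tuple(fs)
        partner.setdefault(a, set()).add(b)
        partner.setdefault(b, set()).add(a)

    records = []
    for i in range(cfg.n_formulas):
        size = int(rng.integers(cfg.formula_size_min, cfg.formula_size_max + 1))
        for _ in range(_MAX_TRIES):
            draw = rng.choice(cfg.n_herbs, size=size, replace=False, p=weights)
            members = sorted(herbs[j] for j in draw)
            if not any(
                frozenset((a, b)) in forbidden
                for a, b in itertools.combinations(members, 2)
            ):
                break
        else:
            raise GenerationFailure(
                f"could not draw formula {i + 1} without a planted pair "
                f"after {_MAX_TRIES} tries"
            )
        records.append((f"F{i + 1:04d}", tuple(members)))

    # coverage: every herb must appear in >= 1 formula; inject missing herbs
    # into the first compatible formula in a random order
    present = {h for _, hs in records for h in hs}
    missing = [h for h in herbs if h not in present]
    for h in missing:
        order = rng.permutation(len(records))
        for j in order:
            fid, members = records[j]
            if not (partner.get(h, set()) & set(members)):
                records[j] = (fid, tuple(sorted(members + (h,))))
                break
        else:
            raise GenerationFailure(f"could not place herb {h} in any formula")
    return FormulaCollection.from_records(records)


def gen_formulas(cfg: StudyConfig) -> FormulaCollection:
    """Standalone formula generation (draws its own planted pairs from
    ``cfg.seed``, exactly as :func:`gen_study` does first)."""
    rng = np.random.default_rng(cfg.seed)
    planted = _draw_planted_pairs(cfg, rng)
    return _gen_formulas(cfg, rng, planted)


def _latent_positions(
    cfg: StudyConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster labels and latent herb positions (n_herbs × latent_dim)."""
    labels = rng.integers(0, cfg.n_clusters, size=cfg.n_herbs)
    means = rng.normal(0.0, cfg.cluster_spread, size=(cfg.n_clusters, cfg.latent_dim))
    z = means[labels] + rng.normal(0.0, cfg.herb_scatter, size=(cfg.n_herbs, cfg.latent_dim))
    return labels, z


def _apply_effects(
    z: np.ndarray,
    herb_index: dict[str, int],
    planted: PairSet | None,
    mode: str,
    delta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Displace planted pairs' latent centroids: push apart (chemical) by δ
    along the separating direction, or pull each endpoint up to δ toward the
    pair midpoint (metabolism)."""
    z = z.copy()
    if planted is None or delta == 0.0:
        return z
    for a, b in planted:
        ia, ib = herb_index[a], herb_index[b]
        u = z[ia] - z[ib]
        norm = float(np.linalg.norm(u))
        if norm == 0.0:
            u = rng.normal(size=z.shape[1])
            norm = float(np.linalg.norm(u))
        u = u / norm
        if mode == "chemical":
            z[ia] += (delta / 2.0) * u
            z[ib] -= (delta / 2.0) * u
        elif mode == "metabolism":
            step = min(delta, norm / 2.0)
            z[ia] -= step * u
            z[ib] += step * u
        else:
            raise ValueError(f"unknown mode: {mode!r}")
    return z


def _descriptor_table(
    cfg: StudyConfig,
    mode: str,
    rng: np.random.Generator,
    planted: PairSet | None,
) -> tuple[CompoundDescriptorTable, pd.DataFrame]:
    p = cfg.p_chemical if mode == "chemical" else cfg.p_metabolism
    delta = cfg.chemical_separation if mode == "chemical" else cfg.metabolism_attraction
    herbs = _herb_ids(cfg.n_herbs)
    herb_index = {h: i for i, h in enumerate(herbs)}
    labels, z = _latent_positions(cfg, rng)
    z = _apply_effects(z, herb_index, planted, mode, delta, rng)
    # orthonormal basis latent -> descriptor space (isometric for the signal)
    basis, _ = np.linalg.qr(rng.normal(size=(p, cfg.latent_dim)))
    baseline = rng.normal(0.0, 1.0, size=p)  # per-descriptor offset
    centroids = z @ basis.T + baseline
    n_compounds = np.maximum(1, rng.poisson(cfg.compounds_per_herb, size=cfg.n_herbs))
    rows_herb = np.repeat(np.arange(cfg.n_herbs), n_compounds)
    noise = rng.normal(0.0, cfg.within_herb_sd, size=(len(rows_herb), p))
    X = centroids[rows_herb] + noise
    prefix = "C" if mode == "chemical" else "M"
    df = pd.DataFrame(X, columns=[f"d{j + 1}" for j in range(p)])
    df.insert(0, "mass", 1.0)
    df.insert(0, "herb_id", [herbs[i] for i in rows_herb])
    df.insert(0, "compound_id", [f"{prefix}{i + 1:05d}" for i in range(len(rows_herb))])
    table = CompoundDescriptorTable.from_dataframe(df)
    truth = pd.DataFrame(centroids, index=pd.Index(herbs, name="herb_id"),
                         columns=[f"d{j + 1}" for j in range(p)])
    return table, truth, pd.Series(labels, index=truth.index, name=f"{mode}_cluster")


def gen_descriptor_table(cfg: StudyConfig, mode: str = "chemical") -> CompoundDescriptorTable:
    """Standalone descriptor-table generation (own rng from ``cfg.seed``;
    planted pairs drawn first, as in :func:`gen_study`)."""
    if mode not in ("chemical", "metabolism"):
        raise ValueError(f"mode must be 'chemical' or 'metabolism', got {mode!r}")
    rng = np.random.default_rng(cfg.seed)
    planted = _draw_planted_pairs(cfg, rng)
    table, _, _ = _descriptor_table(cfg, mode, rng, planted)
    return table


@dataclass(frozen=True)
class SyntheticStudy:
    """One fully generated study: formulas, both descriptor tables, the
    planted pair set, and the ground truth behind them."""

    config: StudyConfig
    formulas: FormulaCollection
    chemical: CompoundDescriptorTable
    metabolism: CompoundDescriptorTable
    pairs: PairSet | None
    true_chemical_centroids: pd.DataFrame
    true_metabolism_centroids: pd.DataFrame
    cluster_labels: pd.DataFrame = field(repr=False, default=None)

    def write(self, outdir, force: bool = False) -> dict:
        """Write all standard input files; returns the path map."""
        from . import io as tio

        return tio.write_study(self, outdir, force=force)


def gen_study(cfg: StudyConfig) -> SyntheticStudy:
    """Generate a complete study from one config/seed.

    Draw order (fixed, so outputs are reproducible): planted pairs → formulas
    → chemical table → metabolism table.
    """
    rng = np.random.default_rng(cfg.seed)
    planted = _draw_planted_pairs(cfg, rng)
    formulas = _gen_formulas(cfg, rng, planted)
    chem_table, chem_truth, chem_labels = _descriptor_table(cfg, "chemical", rng, planted)
    met_table, met_truth, met_labels = _descriptor_table(cfg, "metabolism", rng, planted)
    return SyntheticStudy(
        config=cfg,
        formulas=formulas,
        chemical=chem_table,
        metabolism=met_table,
        pairs=planted,
        true_chemical_centroids=chem_truth,
        true_metabolism_centroids=met_truth,
        cluster_labels=pd.concat([chem_labels, met_labels], axis=1),
    )
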