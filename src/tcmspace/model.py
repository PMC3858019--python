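"""Model-style front door: fit the three-space incompatibility analysis.

:class:`IncompatibilityModel` holds the data of one study — a formula
collection, two compound descriptor tables (chemical descriptors and CYP450
docking profiles) and a declared pair set — and :meth:`~IncompatibilityModel.fit`
runs the full analysis: co-occurrence network topology, weight-center + PCA
embeddings of both descriptor spaces, per-space pair-set distance reports with
permutation p-values, and the combined directional verdict. The returned
:class:`IncompatibilityResults` carries every intermediate and renders a
``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from . import feature_space as fs
from . import formula_network as fn
from . import incompat_eval as ie
from .errors import InsufficientSupport
from .pairs import PairSet
from .report import PairDistanceReport

__all__ = ["IncompatibilityModel", "IncompatibilityResults"]


class IncompatibilityModel:
    """The three-space incompatibility analysis for one study.

    Parameters
    ----------
    formulas : FormulaCollection
        Formula-ID → herb-list records; basis of the co-occurrence network.
    chemical, metabolism : CompoundDescriptorTable
        Per-compound descriptor tables (any dimensionality ≥ 2); each is
        collapsed to herb centroids and embedded by PCA.
    pairset : PairSet
        The declared (e.g. classically incompatible) herb pairs.
    n_components : int
        Retained principal components per space (3 → an (X, Y, Z) space).
    pca_scale : bool
        z-score descriptors before PCA (correlation-structure PCA); the
        default, since descriptor units are heterogeneous.
    expected_directions : dict, optional
        Per-space direction the hypothesis predicts; defaults to
        network GREATER, chemical GREATER, metabolism LESS.
    """

    def __init__(
        self,
        formulas,
        chemical,
        metabolism,
        pairset: PairSet,
        n_components: int = 3,
        pca_scale: bool = True,
        expected_directions: dict | None = None,
    ):
        self.formulas = formulas
        self.chemical = chemical
        self.metabolism = metabolism
        self.pairset = pairset
        self.n_components = n_components
        self.pca_scale = pca_scale
        self.expected_directions = dict(
            ie.EXPECTED_DIRECTIONS if expected_directions is None else expected_directions
        )

    @classmethod
    def from_files(cls, formulas_path, chemical_path, metabolism_path, pairs_path, **kw):
        from . import io as tio

        return cls(
            formulas=tio.read_formulas(formulas_path),
            chemical=tio.read_descriptors(chemical_path),
            metabolism=tio.read_descriptors(metabolism_path),
            pairset=tio.read_pairset(pairs_path),
            **kw,
        )

    @classmethod
    def from_synthetic(cls, config=None, **kw):
        """Build from a generated study (default :class:`StudyConfig` if none
        given); the study is kept on the model as ``.study``."""
        from .synthetic_data import StudyConfig, gen_study

        if config is None:
            config = StudyConfig()
        study = gen_study(config)
        model = cls(
            formulas=study.formulas,
            chemical=study.chemical,
            metabolism=study.metabolism,
            pairset=study.pairs,
            **kw,
        )
        model.study = study
        return model

    def fit(self, n_perm: int = 999, seed: int = 0) -> "IncompatibilityResults":
        """Run the full analysis; all randomness (the permutation nulls) flows
        from ``seed`` through three independent child streams."""
        children = np.random.SeedSequence(seed).spawn(3)

        net = fn.build_cooccurrence_network(self.formulas)
        pm = fn.shortest_paths(net)
        stats = fn.network_stats(net, pm)
        dd = fn.degree_distribution(net)
        try:
            plaw = fn.fit_power_law(dd)
        except InsufficientSupport:
            plaw = None
        net_report = fn.pairset_path_distance(pm, self.pairset)
        net_report = ie.attach_permutation(
            net_report,
            pm.finite_upper(),
            n_perm=n_perm,
            seed=np.random.default_rng(children[0]),
            direction=self.expected_directions["network"],
        )

        embeddings, reports = {}, {"network": net_report}
        for i, (space, table) in enumerate(
            (("chemical", self.chemical), ("metabolism", self.metabolism)), start=1
        ):
            centroids = fs.weight_center(table)
            emb = fs.project(centroids, n_components=self.n_components, scale=self.pca_scale)
            report = fs.distance_summary(emb, self.pairset, space=space)
            report = ie.attach_permutation(
                report,
                pdist(emb.coordinates.to_numpy()),
                n_perm=n_perm,
                seed=np.random.default_rng(children[i]),
                direction=self.expected_directions[space],
            )
            embeddings[space] = emb
            reports[space] = report

        evaluation = ie.evaluate(
            network=reports["network"],
            chemical=reports["chemical"],
            metabolism=reports["metabolism"],
            expected=self.expected_directions,
        )
        return IncompatibilityResults(
            model=self,
            network=net,
            path_matrix=pm,
            network_stats=stats,
            degree_distribution=dd,
            power_law=plaw,
            embeddings=embeddings,
            reports=reports,
            evaluation=evaluation,
            n_perm=n_perm,
            seed=seed,
            study=getattr(self, "study", None),
        )


@dataclass
class IncompatibilityResults:
    """Everything one fit produced; render with :meth:`summary`."""

    model: IncompatibilityModel
    network: object
    path_matrix: fn.PathMatrix
    network_stats: fn.NetworkStats
    degree_distribution: fn.DegreeDistribution
    power_law: fn.PowerLawFit | None
    embeddings: dict
    reports: dict[str, PairDistanceReport]
    evaluation: ie.IncompatEvaluation
    n_perm: int
    seed: int
    study: object = field(default=None, repr=False)

    @property
    def verdicts(self) -> dict:
        return self.evaluation.verdicts

    @property
    def all_consistent(self) -> bool:
        return self.evaluation.all_consistent

    def to_dict(self) -> dict:
        s = self.network_stats
        out = {
            "seed": self.seed,
            "n_perm": self.n_perm,
            "network": {
                **s.to_dict(),
                "power_law_gamma": None if self.power_law is None else self.power_law.gamma,
                "power_law_r_squared": (
                    None if self.power_law is None else self.power_law.r_squared
                ),
            },
            "embeddings": {
                space: {
                    "explained_variance_ratios": list(emb.explained_variance_ratios),
                    "cumulative_ratio": emb.cumulative_ratio,
                }
                for space, emb in sorted(self.embeddings.items())
            },
            "evaluation": self.evaluation.to_dict(),
        }
        return out

    def to_json(self) -> str:
        """Stable JSON: identical data + seed → identical bytes."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def summary(self) -> str:
        s = self.network_stats
        lines = [
            "Incompatibility analysis results",
            "=" * 74,
            "Formula co-occurrence network",
            f"  nodes: {s.n_nodes}   edges: {s.n_edges}   components: {s.n_components}",
            f"  diameter D: {s.diameter}   average distance L: {s.average_distance:.4f}",
            f"  clustering coefficient: {s.average_clustering:.4f}"
            f"   average degree: {s.average_degree:.4f}",
        ]
        if self.power_law is not None:
            lines.append(
                f"  degree distribution P(k) ∝ k^-γ: γ = {self.power_law.gamma:.4f}"
                f"  (log-log R² = {self.power_law.r_squared:.3f})"
            )
        for space, emb in sorted(self.embeddings.items()):
            r = ", ".join(f"{v:.2%}" for v in emb.explained_variance_ratios)
            lines.append(
                f"{space.capitalize()} space PCA contribution rates: {r}"
                f"  (cumulative {emb.cumulative_ratio:.2%})"
            )
        lines.append("")
        lines.append(self.evaluation.summary())
        return "\n".join(lines)

    def save(self, outdir, force: bool = False) -> dict:
        """Persist every artifact (network, stats, embeddings, reports,
        evaluation, summary) into ``outdir``; returns the path map."""
        from pathlib import Path

        from . import io as tio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["network"] = outdir / "network.net"
        tio.write_pajek(self.network, paths["network"], force=force)

        paths["network_stats"] = outdir / "network_stats.json"
        tio._check_overwrite(paths["network_stats"], force)
        stats = {
            **self.network_stats.to_dict(),
            "power_law_gamma": None if self.power_law is None else self.power_law.gamma,
            "seed": self.seed,
        }
        paths["network_stats"].write_text(json.dumps(stats, sort_keys=True, indent=2) + "\n")

        paths["node_metrics"] = outdir / "node_metrics.csv"
        tio._check_overwrite(paths["node_metrics"], force)
        fn.node_metrics(self.network).to_csv(paths["node_metrics"], lineterminator="\n")

        for space, emb in self.embeddings.items():
            tio.write_embedding(emb, outdir / f"{space}_space", seed=self.seed, force=force)
            paths[f"{space}_space"] = outdir / f"{space}_space_coordinates.csv"
        for space, report in self.reports.items():
            paths[f"{space}_report"] = outdir / f"{space}_report.json"
            tio.write_report(report, paths[f"{space}_report"], force=force)

        paths["evaluation"] = outdir / "evaluation.json"
        tio._check_overwrite(paths["evaluation"], force)
        paths["evaluation"].write_text(self.evaluation.to_json() + "\n")

        paths["summary"] = outdir / "summary.txt"
        tio._check_overwrite(paths["summary"], force)
        paths["summary"].write_text(self.summary() + "\n")
        return {k: str(v) for k, v in paths.items()}
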