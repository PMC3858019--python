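"""End-to-end pipeline: validated run configuration → fitted results on disk.

A :class:`RunConfig` either points at the three input files plus a pair set,
or asks for a synthetic study (optionally from a YAML study config). Stages
run network → spaces → evaluation; the first failing stage aborts with a
stage-tagged error, and every intermediate is persisted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import TCMSpaceError, ValidationError
from .model import IncompatibilityModel

__all__ = ["RunConfig", "load_run_config", "run_pipeline"]

log = logging.getLogger("tcmspace")


@dataclass
class RunConfig:
    formulas: str | None = None
    chemical: str | None = None
    metabolism: str | None = None
    pairset: str | None = None
    synthetic: dict | None = None  # StudyConfig overrides; used when no input paths
    n_components: int = 3
    pca_scale: bool = True
    n_perm: int = 999
    seed: int = 0
    outdir: str = "tcmspace_out"
    force: bool = False
    log_level: str = "INFO"

    def validate(self):
        paths = [self.formulas, self.chemical, self.metabolism, self.pairset]
        if self.synthetic is None:
            missing = [p for p in paths if p is None]
            if missing:
                raise ValidationError(
                    "run config needs either 'synthetic' or all four input paths "
                    "(formulas, chemical, metabolism, pairset)"
                )
            absent = [p for p in paths if not Path(p).exists()]
            if absent:
                raise ValidationError(f"input path(s) do not exist: {absent}")
        return self


def load_run_config(path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(payload, dict):
        raise ValidationError(f"run config must be a mapping, got {type(payload).__name__}")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(payload) - known
    if unknown:
        raise ValidationError(f"unknown run-config keys: {sorted(unknown)}")
    return RunConfig(**payload).validate()


def run_pipeline(cfg: RunConfig):
    """Execute the full analysis described by ``cfg``; returns the fitted
    :class:`~tcmspace.model.IncompatibilityResults` (artifacts on disk)."""
    cfg.validate()
    logging.basicConfig(level=cfg.log_level.upper(), format="%(levelname)s %(message)s")
    stage = "load"
    try:
        if cfg.synthetic is not None:
            from .synthetic_data import StudyConfig

            overrides = dict(cfg.synthetic)
            overrides.setdefault("seed", cfg.seed)
            study_cfg = StudyConfig(**overrides)
            log.info("generating synthetic study (%d herbs, %d formulas, seed %d)",
                     study_cfg.n_herbs, study_cfg.n_formulas, study_cfg.seed)
            model = IncompatibilityModel.from_synthetic(
                study_cfg, n_components=cfg.n_components, pca_scale=cfg.pca_scale
            )
        else:
            model = IncompatibilityModel.from_files(
                cfg.formulas, cfg.chemical, cfg.metabolism, cfg.pairset,
                n_components=cfg.n_components, pca_scale=cfg.pca_scale,
            )
        stage = "fit"
        log.info("fitting (n_perm=%d, seed=%d)", cfg.n_perm, cfg.seed)
        results = model.fit(n_perm=cfg.n_perm, seed=cfg.seed)
        stage = "save"
        outdir = Path(cfg.outdir)
        if results.study is not None:
            results.study.write(outdir / "inputs", force=cfg.force)
        results.save(outdir, force=cfg.force)
        log.info("artifacts written to %s", outdir)
        return results
    except TCMSpaceError as e:
        raise type(e)(f"[stage: {stage}] {e}") from e
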