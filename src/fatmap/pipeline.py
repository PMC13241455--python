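"""Pipeline orchestration: generate -> extract -> spm -> models from one config.

A single global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``, so stages are decoupled but the
whole run is reproducible: identical config + seed gives byte-identical
artifacts and an identical hash manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .mapping import cohort_curves_and_metrics, curves_wide
from .models import (activity_regression, build_long_table, chronicity_regression,
                     mixed_fi_model, subject_mean_metrics)
from .spm import spm_test
from .synthetic import CovariateSpec, EffectSpec, SliceGeometry, generate_cohort

log = logging.getLogger(__name__)

LEVELS = ("L4L5", "L5S1")


@dataclass
class PipelineConfig:
    outdir: Path
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    effects: list[EffectSpec] = field(default_factory=list)
    geometry: SliceGeometry = field(default_factory=SliceGeometry)
    noise_sd: float = 4.0
    subject_sd: float = 0.0
    spm_targets: tuple[str, ...] = ("chronicity", "activity")
    spm_adjusters: tuple[str, ...] = ("age", "sex", "bmi")
    alpha: float = 0.05
    two_tailed: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cov = CovariateSpec(**raw.get("covariates", {}))
        effects = [EffectSpec(**e) for e in raw.get("effects", [])]
        geom = SliceGeometry(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in raw.get("geometry", {}).items()})
        return cls(
            outdir=Path(raw["outdir"]),
            covariates=cov,
            effects=effects,
            geometry=geom,
            noise_sd=raw.get("noise_sd", 4.0),
            subject_sd=raw.get("subject_sd", 0.0),
            spm_targets=tuple(raw.get("spm_targets", ("chronicity", "activity"))),
            spm_adjusters=tuple(raw.get("spm_adjusters", ("age", "sex", "bmi"))),
            alpha=raw.get("alpha", 0.05),
            two_tailed=raw.get("two_tailed", True),
            seed=raw.get("seed", 0),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"[stage:{name}] {e}") from e
        return wrapped
    return deco


@_stage("generate")
def stage_generate(cfg: PipelineConfig):
    spec = dataclasses.replace(cfg.covariates, seed=int(
        np.random.SeedSequence(cfg.seed).spawn(1)[0].generate_state(1)[0] % (2**31)))
    cohort, subjects = generate_cohort(
        spec, effects=cfg.effects, geometry=cfg.geometry, noise_sd=cfg.noise_sd,
        subject_sd=cfg.subject_sd,
    )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "cohort.csv", index=False, float_format="%.6f")
    images = outdir / "images"
    for s in subjects:
        for slc in s.slices:
            fio.write_slice(slc, images)
    truth = [dataclasses.asdict(e) for e in cfg.effects]
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return cohort, subjects


@_stage("extract")
def stage_extract(cfg: PipelineConfig, cohort: pd.DataFrame):
    outdir = Path(cfg.outdir)
    images = outdir / "images"
    if not images.is_dir():
        raise FileNotFoundError(f"images directory missing: {images}")
    slices = fio.read_cohort_slices(images, cohort)
    curves, metrics = cohort_curves_and_metrics(slices)
    curves.to_csv(outdir / "curves.csv", index=False, float_format="%.6f")
    metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.6f")
    return curves, metrics


@_stage("spm")
def stage_spm(cfg: PipelineConfig, curves: pd.DataFrame, cohort: pd.DataFrame):
    outdir = Path(cfg.outdir)
    reports = {}
    tfields = []
    indexed = cohort.set_index("id")
    for level in LEVELS:
        ids, Y = curves_wide(curves, level)
        sub = indexed.loc[ids].reset_index()
        for target in cfg.spm_targets:
            res = spm_test(Y, sub, target, cfg.spm_adjusters, cfg.alpha,
                           cfg.two_tailed, level=level)
            reports[f"{target}_{level}"] = res.report()
            tfields.append(pd.DataFrame({
                "level": level, "target": target,
                "node_pct": np.linspace(0, 100, Y.shape[1]), "t": res.t_field,
                "t_crit": res.t_crit,
            }))
    (outdir / "spm_clusters.json").write_text(json.dumps(reports, indent=1))
    pd.concat(tfields, ignore_index=True).to_csv(outdir / "spm_tfields.csv",
                                                 index=False, float_format="%.6f")
    return reports


@_stage("models")
def stage_models(cfg: PipelineConfig, metrics: pd.DataFrame, cohort: pd.DataFrame):
    outdir = Path(cfg.outdir)
    per_subject = subject_mean_metrics(metrics, cohort)
    long_table = build_long_table(metrics, cohort)
    fits = {
        "chronicity_deep15": chronicity_regression(per_subject, "deep15"),
        "chronicity_overall": chronicity_regression(per_subject, "overall"),
        "activity": activity_regression(per_subject),
        "mixed_deep15": mixed_fi_model(long_table, "deep15"),
        "mixed_overall": mixed_fi_model(long_table, "overall"),
    }
    for name, fit in fits.items():
        fit.table.round(6).to_csv(outdir / f"model_{name}.csv", index_label="term")
    return fits


def run_all(cfg: PipelineConfig) -> dict:
    """Run all four stages and return a manifest of artifact hashes."""
    cohort, _ = stage_generate(cfg)
    curves, metrics = stage_extract(cfg, cohort)
    stage_spm(cfg, curves, cohort)
    stage_models(cfg, metrics, cohort)
    outdir = Path(cfg.outdir)
    artifacts = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": cfg.seed,
        "n_subjects": cfg.covariates.n_subjects,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
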