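"""End-to-end orchestration: simulate/load -> phenotype (both CPs) ->
stratified prevalence -> TOST equivalence, with a machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

import phenoequiv
from phenoequiv.cp1 import classify_cp1
from phenoequiv.cp2 import T2D_RULE_MODES, classify_cp2
from phenoequiv.datamodel import EhrBundle, load_bundle, write_bundle
from phenoequiv.prevalence import eligible_patients, prevalence_table
from phenoequiv.simulate import SimulationConfig, generate_population, write_truth
from phenoequiv.tost import equivalence_table

__all__ = ["PipelineConfig", "PipelineError", "load_pipeline_config", "run_pipeline"]

log = logging.getLogger("phenoequiv.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str
    prevalence_year: int = 2022
    simulate: SimulationConfig | None = None
    input_dir: str | None = None
    cp2_mode: str = "or_printed"
    delta: float = 2.5
    alpha: float = 0.05
    convention: str = "analytic"
    seed: int | None = None  # overrides simulate.seed when given

    def validate(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ValueError("exactly one input source (simulate | input_dir) must be set")
        if self.cp2_mode not in T2D_RULE_MODES:
            raise ValueError(f"unknown cp2_mode {self.cp2_mode!r}")
        if self.simulate is not None:
            self.simulate.validate()


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if isinstance(raw.get("simulate"), dict):
        raw["simulate"] = SimulationConfig(**raw["simulate"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            return out
        return wrapper
    return deco


@_stage("input")
def _obtain_bundle(config: PipelineConfig, out_dir: Path, written: list[Path]) -> EhrBundle:
    if config.simulate is not None:
        sim = config.simulate
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        bundle, truth = generate_population(sim)
        data_dir = out_dir / "synthetic"
        write_bundle(bundle, data_dir)
        written.extend(sorted(data_dir.iterdir()))
        written.append(write_truth(truth, data_dir))
        log.info("simulate: %d patients, %s", len(bundle.patients), bundle.row_counts())
        return bundle
    bundle = load_bundle(config.input_dir)
    log.info("load: %s", bundle.row_counts())
    return bundle


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write outputs under ``config.out_dir``, return the manifest.

    On any stage failure the partial outputs written by this run are removed
    and a :class:`PipelineError` naming the stage is raised.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        bundle = _obtain_bundle(config, out_dir, written)

        @_stage("phenotype")
        def _phenotype():
            labels1 = classify_cp1(bundle, config.prevalence_year)
            labels2 = classify_cp2(bundle, config.prevalence_year, mode=config.cp2_mode)
            for name, df in (("cp1_labels.csv", labels1), ("cp2_labels.csv", labels2)):
                path = out_dir / name
                df.to_csv(path, index=False)
                written.append(path)
            log.info("phenotype: cp1 %s | cp2 %s",
                     labels1["label"].value_counts().to_dict(),
                     labels2["label"].value_counts().to_dict())
            return labels1, labels2

        labels1, labels2 = _phenotype()

        @_stage("prevalence")
        def _prevalence():
            tables = {}
            for cp, labels in (("cp1", labels1), ("cp2", labels2)):
                eligible = eligible_patients(bundle, cp, config.prevalence_year)
                table = prevalence_table(labels, eligible, bundle.patients,
                                         config.prevalence_year)
                path = out_dir / f"{cp}_prevalence.csv"
                table.to_csv(path, index=False)
                written.append(path)
                log.info("prevalence %s: N=%d", cp, len(eligible))
                tables[cp] = table
            return tables

        tables = _prevalence()

        @_stage("tost")
        def _tost():
            eq = equivalence_table(tables["cp1"], tables["cp2"], delta=config.delta,
                                   alpha=config.alpha, convention=config.convention)
            path = out_dir / "equivalence.csv"
            eq.to_csv(path, index=False)
            written.append(path)
            log.info("tost: %d strata, %d equivalent", len(eq), int(eq["reject_null"].sum()))
            return eq

        eq = _tost()

        manifest = {
            "package_version": phenoequiv.__version__,
            "python": platform.python_version(),
            "config": _config_dict(config),
            "row_counts": bundle.row_counts(),
            "n_strata": len(eq),
            "n_equivalent": int(eq["reject_null"].sum()),
            "outputs": [p.name for p in written],
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str) + "\n")
        return manifest
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulate is not None:
        sim = dataclasses.asdict(config.simulate)
        if sim.get("stratum_mix"):
            sim["stratum_mix"] = {"|".join(k): v for k, v in sim["stratum_mix"].items()}
        for key in ("true_t2d_prev", "true_t1d_prev"):
            if isinstance(sim.get(key), dict):
                sim[key] = {"|".join(k): v for k, v in sim[key].items()}
        d["simulate"] = sim
    return d
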