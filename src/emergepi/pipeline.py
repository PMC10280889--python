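"""End-to-end reproducible pipeline: raw admissions to competence lists.

Stages run in the order the analysis prescribes — parse, truncate to
3-character categories, exclude Z-chapter discharges, tabulate per scope
(all admissions, each capital-letter chapter group, each duty-roster arm),
rank with 95% prediction intervals, fit the exponential and Pareto laws,
compare them, and extract the vital-few competence list. A JSON manifest
records seed, config hash, versions and per-stage record counts so a run is
fully reproducible; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

from . import __version__
from .distribution_fitting import (
    DegenerateSampleError,
    compare_models,
    fit_exponential,
    fit_pareto,
    write_fits_json,
)
from .frequency_analysis import Scale, rank_by_mean, rank_stability, tabulate
from .icd_processing import (
    RosterMapping,
    preprocess,
    read_admissions_csv,
)
from .synthetic_data import ConfigurationError, SimulationConfig, generate_admissions
from .vital_few import (
    EmptyScopeError,
    cumulative_curve,
    top_k_share,
    vital_few_set,
    write_vital_few_csv,
    write_vital_few_json,
)

logger = logging.getLogger("emergepi")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-loadable, flag-overridable)."""

    output_dir: str | Path
    input_csv: str | Path | None = None
    simulate: SimulationConfig | None = None
    populations: dict[int, float] = field(default_factory=dict)
    roster_mapping_path: str | Path | None = None
    coverage_truncation: float = 1.0
    scale: Scale = "per_100k"
    criterion: Literal["sse", "aic"] = "sse"
    vital_few_threshold: float = 0.8
    on_malformed: Literal["drop", "strict"] = "drop"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input_csv is None) == (self.simulate is None):
            raise ConfigurationError(
                "input_csv/simulate", "exactly one input source must be configured"
            )
        if self.simulate is not None and not self.populations:
            self.populations = dict(self.simulate.population_per_year)
        if not self.populations:
            raise ConfigurationError("populations", "per-year populations are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim = raw.get("simulate")
        simulate = SimulationConfig.from_dict(sim) if sim else None
        return cls(
            output_dir=raw["output_dir"],
            input_csv=raw.get("input_csv"),
            simulate=simulate,
            populations={int(y): float(p) for y, p in (raw.get("populations") or {}).items()},
            roster_mapping_path=raw.get("roster_mapping_path"),
            coverage_truncation=float(raw.get("coverage_truncation", 1.0)),
            scale=raw.get("scale", "per_100k"),
            criterion=raw.get("criterion", "sse"),
            vital_few_threshold=float(raw.get("vital_few_threshold", 0.8)),
            on_malformed=raw.get("on_malformed", "drop"),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
        )

    def to_dict(self) -> dict:
        return {
            "output_dir": str(self.output_dir),
            "input_csv": str(self.input_csv) if self.input_csv else None,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "populations": {int(y): p for y, p in self.populations.items()},
            "roster_mapping_path": str(self.roster_mapping_path)
            if self.roster_mapping_path
            else None,
            "coverage_truncation": self.coverage_truncation,
            "scale": self.scale,
            "criterion": self.criterion,
            "vital_few_threshold": self.vital_few_threshold,
            "on_malformed": self.on_malformed,
            "seed": self.seed,
        }

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()


def _scope_dirname(scope: str) -> str:
    return scope.replace(":", "_").replace("/", "")


def _analyze_scope(scope, records, populations, cfg, outdir):
    """Rank, fit, compare and extract the vital few for one scope."""
    table = tabulate(records, populations, scope=scope)
    if table.total == 0:
        logger.info("scope %s is empty; skipped", scope)
        return None
    profile = rank_by_mean(
        table,
        coverage_truncation=cfg.coverage_truncation,
        scale=cfg.scale,
    )
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "frequency_table.csv")
    profile.to_csv(outdir / "ranked_profile.csv")
    profile.to_json(outdir / "ranked_profile.json")

    summary: dict = {"scope": scope, "n_records": table.total, "n_categories": len(profile)}

    exp_fit = pareto_fit = comparison = None
    if len(profile) >= 3:
        exp_fit = fit_exponential(profile)
        try:
            pareto_fit = fit_pareto(profile)
            comparison = compare_models(profile, exp_fit, pareto_fit, criterion=cfg.criterion)
        except DegenerateSampleError:
            logger.warning("scope %s: flat profile, Pareto fit skipped", scope)
        write_fits_json(outdir / "fits.json", exp_fit, pareto_fit, comparison)
        if comparison is not None:
            with open(outdir / "comparison.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "preferred": comparison.preferred,
                        "criterion": comparison.criterion,
                        "exponential_score": comparison.exponential_score,
                        "pareto_score": comparison.pareto_score,
                    },
                    fh,
                    indent=2,
                )
                fh.write("\n")
            summary["preferred_model"] = comparison.preferred

    try:
        curve = cumulative_curve(profile)
        report = vital_few_set(curve, threshold=cfg.vital_few_threshold)
        roster_of = {r.icd10_code: r.roster for r in records if r.roster}
        write_vital_few_csv(curve, report, outdir / "vital_few.csv", roster_of=roster_of)
        write_vital_few_json(report, outdir / "vital_few.json")
        summary["n_vital_few"] = len(report.categories)
        summary["top10_share"] = top_k_share(curve, 10)
        summary["pareto_principle_met"] = report.pareto_principle_met
    except EmptyScopeError:
        pass

    if table.n_years >= 2 and len(profile) >= 2:
        stab = rank_stability(table)
        if math.isfinite(stab.mean):
            summary["rank_stability_mean"] = stab.mean
            summary["rank_stability_min"] = stab.minimum
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk).

    Any stage error aborts with a stage-named :class:`PipelineError`; in that
    case a manifest marked ``"status": "incomplete"`` is still written so
    partial outputs are recognizable.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    import numpy, pandas, scipy  # versions recorded for reproducibility

    manifest: dict = {
        "emergepi_version": __version__,
        "library_versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "status": "incomplete",
    }
    stage = "ingest"
    t0 = time.perf_counter()
    try:
        if config.simulate is not None:
            sim = config.simulate
            if sim.seed != config.seed:
                sim = SimulationConfig(
                    law=sim.law,
                    years=sim.years,
                    population_per_year=sim.population_per_year,
                    z_fraction=sim.z_fraction,
                    noise=sim.noise,
                    seed=config.seed,
                    year_factors=sim.year_factors,
                )
            raw_records = generate_admissions(sim)
        else:
            raw_records = read_admissions_csv(config.input_csv)
        logger.info("stage %s: %d records (%.2fs)", stage, len(raw_records), time.perf_counter() - t0)

        stage = "preprocess"
        t0 = time.perf_counter()
        mapping = (
            RosterMapping.from_yaml(config.roster_mapping_path)
            if config.roster_mapping_path
            else RosterMapping.default()
        )
        retained, z_excluded, malformed = preprocess(
            raw_records, on_malformed=config.on_malformed, roster_mapping=mapping
        )
        manifest["counts"] = {
            "input": len(raw_records),
            "retained": len(retained),
            "z_excluded": z_excluded,
            "malformed_dropped": malformed,
        }
        logger.info(
            "stage %s: retained %d, Z-excluded %d, malformed %d (%.2fs)",
            stage,
            len(retained),
            z_excluded,
            malformed,
            time.perf_counter() - t0,
        )

        stage = "analyze"
        t0 = time.perf_counter()
        chapter_groups = sorted({r.icd10_code[0] if r.icd10_code[0] not in "AB" else "A/B" for r in retained})
        rosters = sorted({r.roster for r in retained if r.roster and r.roster != "unassigned"})
        scopes = ["all"] + [f"chapter:{g}" for g in chapter_groups] + [f"roster:{lab}" for lab in rosters]
        manifest["scopes"] = []
        for scope in scopes:
            scope_dir = outdir if scope == "all" else outdir / "scopes" / _scope_dirname(scope)
            summary = _analyze_scope(scope, retained, config.populations, config, scope_dir)
            if summary is not None:
                manifest["scopes"].append(summary)
        logger.info("stage %s: %d scopes (%.2fs)", stage, len(manifest["scopes"]), time.perf_counter() - t0)

        manifest["status"] = "complete"
    except Exception as exc:
        _write_manifest(outdir, manifest)
        raise PipelineError(stage, exc) from exc

    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
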