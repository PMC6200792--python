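"""End-to-end orchestration: (simulate | ingest) → impute → fit → compare → upscale.

A pipeline run is described by a single YAML/dict config and leaves
behind a run manifest (JSON) recording the config snapshot, dataset
hash, seeds, per-stage wall time, per-group convergence diagnostics,
and every output path — enough to reproduce all outputs bit-identically
from the same inputs.

Convergence failures (R̂ at or above the threshold) are surfaced as a
warning block in the manifest; ``strict`` escalates them to an error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .bayes_model import ModelConfig, PosteriorResult, fit_all
from .data_io import (
    GROUPING_VARIABLES,
    group_by,
    read_dataset,
    write_measurements,
    write_results,
)
from .post_analysis import (
    RangeSummary,
    posterior_ratio,
    range_overlap_matrix,
    upscale,
    UpscaleTable,
)
from .sd_imputation import compute_cv_table, impute_sd
from .synthetic_data import SimulationConfig, GroupSpec, default_config, generate_dataset

logger = logging.getLogger("aquacarb")

RHAT_THRESHOLD = 1.1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


class ConvergenceError(PipelineError):
    """Raised under strict mode when any R̂ exceeds the threshold."""


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    dataset_hash: str | None = None
    stage_seconds: dict[str, float] = field(default_factory=dict)
    rhat: dict[str, dict[str, dict[str, float | None]]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _sim_config(section: Mapping, seed: int) -> SimulationConfig:
    if section.get("default", False):
        cfg = default_config(seed=seed)
        if "sd_missing_prob" in section:
            cfg.sd_missing_prob = float(section["sd_missing_prob"])
        return cfg
    groups = [
        GroupSpec(
            label=g["label"],
            mu=float(g["mu"]),
            tau=float(g["tau"]),
            n=int(g["n"]),
            ecosystem_category=g.get("ecosystem_category", g["label"]),
            salinity_class=g.get("salinity_class"),
            inundation_class=g.get("inundation_class"),
        )
        for g in section["groups"]
    ]
    return SimulationConfig(
        groups=groups,
        cv_range=tuple(section.get("cv_range", (0.1, 0.6))),
        sd_missing_prob=float(section.get("sd_missing_prob", 0.58)),
        seed=seed,
    )


def run_pipeline(
    config: str | Path | Mapping, strict: bool = False
) -> RunManifest:
    """Execute the configured pipeline and return its manifest.

    Config keys (all optional unless noted): ``output_dir`` (required),
    ``seed``, ``input: {path, grouping_config}`` or ``simulate: {...}``,
    ``model: {...}`` (ModelConfig overrides), ``groupings`` (list of
    grouping variables to fit), ``overlap: {metric}``,
    ``ratios: [{grouping, a, b, mode}]``,
    ``upscale: {areas: {label: {area_m2, citation}}}``,
    ``export_chains`` (bool).
    """
    cfg = _load_config(config)
    if "output_dir" not in cfg:
        raise PipelineError("config: missing required key 'output_dir'")
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    manifest = RunManifest(version=__version__, seed=seed, config=cfg)

    def _record(path: Path) -> Path:
        manifest.outputs.append(str(path))
        return path

    # -- stage: acquire data ------------------------------------------------
    t0 = time.perf_counter()
    try:
        if "simulate" in cfg:
            sim_cfg = _sim_config(cfg["simulate"], seed)
            measurements, truth = generate_dataset(sim_cfg)
            data_path = _record(out_dir / "dataset.csv")
            write_measurements(measurements, data_path)
            truth.to_json(_record(out_dir / "truth.json"))
        elif "input" in cfg:
            data_path = Path(cfg["input"]["path"])
            measurements, report = read_dataset(
                data_path, cfg["input"].get("grouping_config")
            )
            logger.info(
                "ingest: %d accepted / %d total (%d SD-reported)",
                report.n_accepted,
                report.n_total,
                report.n_sd_reported,
            )
            if report.n_rejected:
                manifest.warnings.append(
                    f"ingest: rejected {report.n_rejected} rows"
                )
        else:
            raise PipelineError("config: need either 'simulate' or 'input'")
    except (ValueError, OSError) as exc:
        raise PipelineError(f"stage ingest: {exc}") from exc
    manifest.dataset_hash = _sha256(data_path)
    manifest.stage_seconds["ingest"] = time.perf_counter() - t0

    # -- stage: impute ------------------------------------------------------
    t0 = time.perf_counter()
    impute_grouping = cfg.get("impute", {}).get("grouping", "ecosystem_category")
    try:
        grouped_for_cv = group_by(measurements, impute_grouping)
        cv_table = compute_cv_table(grouped_for_cv)
        measurements = impute_sd(measurements, cv_table)
    except ValueError as exc:
        raise PipelineError(f"stage impute: {exc}") from exc
    cv_table.to_csv(_record(out_dir / "cv_table.csv"))
    write_measurements(measurements, _record(out_dir / "dataset_imputed.csv"))
    manifest.stage_seconds["impute"] = time.perf_counter() - t0

    # -- stage: fit ---------------------------------------------------------
    model_cfg = ModelConfig(seed=seed, **cfg.get("model", {}))
    groupings = cfg.get("groupings", ["ecosystem_category"])
    results: dict[str, PosteriorResult] = {}
    for variable in groupings:
        if variable not in GROUPING_VARIABLES:
            raise PipelineError(f"stage fit: unknown grouping {variable!r}")
        t0 = time.perf_counter()
        try:
            grouped = group_by(measurements, variable)
            result = fit_all(grouped, model_cfg)
        except (ValueError, RuntimeError) as exc:
            raise PipelineError(f"stage fit[{variable}]: {exc}") from exc
        results[variable] = result
        manifest.rhat[variable] = {
            label: {"mu": g.rhat_mu, "tau": g.rhat_tau}
            for label, g in result.groups.items()
        }
        for label, g in result.groups.items():
            logger.info(
                "fit[%s] %s: q50=%.2f rhat_mu=%.4f tau_acc=%.2f",
                variable,
                label,
                g.q50,
                g.rhat_mu,
                -1 if g.tau_acceptance is None else g.tau_acceptance,
            )
            for name, value in (("mu", g.rhat_mu), ("tau", g.rhat_tau)):
                if value is not None and value >= RHAT_THRESHOLD:
                    manifest.warnings.append(
                        f"convergence: {variable}/{label} rhat_{name}={value:.3f} "
                        f">= {RHAT_THRESHOLD}"
                    )
        write_results(result, _record(out_dir / f"summary_{variable}.csv"))
        write_results(result, _record(out_dir / f"summary_{variable}.json"))
        if cfg.get("export_chains", False):
            result.chains_frame().to_csv(
                _record(out_dir / f"chains_{variable}.csv"), index=False
            )
        manifest.stage_seconds[f"fit[{variable}]"] = time.perf_counter() - t0

    # -- stage: compare -----------------------------------------------------
    if "overlap" in cfg:
        t0 = time.perf_counter()
        variable = cfg["overlap"].get("grouping", "ecosystem_category")
        metric = cfg["overlap"]["metric"]
        try:
            grouped = group_by(measurements, variable)
            overlap = range_overlap_matrix(RangeSummary.from_grouped(grouped), metric)
        except ValueError as exc:
            raise PipelineError(f"stage overlap: {exc}") from exc
        path = _record(out_dir / f"overlap_{variable}_{metric}.csv")
        overlap.matrix.to_csv(path)
        with open(_record(out_dir / f"overlap_{variable}_{metric}.json"), "w") as fh:
            json.dump({"metric": metric, "average": overlap.average}, fh, indent=2)
        manifest.stage_seconds["overlap"] = time.perf_counter() - t0

    if "ratios" in cfg:
        t0 = time.perf_counter()
        rows = []
        for spec in cfg["ratios"]:
            variable = spec.get("grouping", "ecosystem_category")
            if variable not in results:
                raise PipelineError(
                    f"stage ratio: grouping {variable!r} was not fitted"
                )
            try:
                ratio = posterior_ratio(
                    results[variable][spec["a"]],
                    results[variable][spec["b"]],
                    mode=spec.get("mode", "median_ratio"),
                    seed=seed,
                )
            except KeyError as exc:
                raise PipelineError(f"stage ratio: unknown group {exc}") from exc
            rows.append(
                {
                    "grouping": variable,
                    "a": spec["a"],
                    "b": spec["b"],
                    "mode": ratio.mode,
                    "ratio": ratio.ratio,
                    "q2.5": ratio.q2_5,
                    "q97.5": ratio.q97_5,
                }
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(_record(out_dir / "ratios.csv"), index=False)
        manifest.stage_seconds["ratio"] = time.perf_counter() - t0

    if "upscale" in cfg:
        t0 = time.perf_counter()
        variable = cfg["upscale"].get("grouping", "ecosystem_category")
        if variable not in results:
            raise PipelineError(f"stage upscale: grouping {variable!r} was not fitted")
        table = []
        for label, area_spec in cfg["upscale"]["areas"].items():
            area = float(area_spec["area_m2"]) if isinstance(area_spec, Mapping) else float(area_spec)
            try:
                table.append(upscale(results[variable][label], area))
            except KeyError:
                raise PipelineError(f"stage upscale: unknown group {label!r}") from None
        write_results(UpscaleTable(table), _record(out_dir / "upscale.csv"))
        manifest.stage_seconds["upscale"] = time.perf_counter() - t0

    convergence_warnings = [w for w in manifest.warnings if w.startswith("convergence")]
    if strict and convergence_warnings:
        manifest.to_json(out_dir / "manifest.json")
        raise ConvergenceError("; ".join(convergence_warnings))

    manifest_path = out_dir / "manifest.json"
    manifest.outputs.append(str(manifest_path))
    manifest.to_json(manifest_path)
    return manifest
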