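"""End-to-end orchestration: seed counts → RF; depths → calls → landscapes.

A validated YAML config drives the stages; every stochastic stage draws
its seed deterministically from the master seed and the stage name, and a
machine-readable manifest records resolved parameters, seeds and output
checksums so that re-running the same config reproduces byte-identical
numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import __version__
from . import landscape as ls
from . import seed_rf, xo_mapper

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "stage_seed", "load_config"]

logger = logging.getLogger("xomap")


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str, record: str | None = None):
        self.stage = stage
        self.record = record
        suffix = f" (record {record})" if record else ""
        super().__init__(f"stage {stage!r}: {message}{suffix}")


class CallingParams(BaseModel):
    min_depth: int = 20
    het_band: tuple[float, float] = (0.30, 0.70)
    hom_max: float = 0.15
    min_flank: int = 2


class LandscapeParams(BaseModel):
    window: int = Field(1000, gt=0)
    step: int = Field(100, gt=0)
    smear: bool = False


class RfParams(BaseModel):
    n_boot: int = Field(2000, ge=100)
    level: float = Field(0.95, gt=0.0, lt=1.0)


class RunConfig(BaseModel):
    """Pipeline configuration; file paths are resolved at validation time."""

    seed: int = Field(..., ge=0, lt=2**31, description="master RNG seed")
    out_dir: Path
    seed_counts: Path | None = None
    depths: Path | None = None
    snps: Path | None = None
    hotspots: Path | None = None
    control_xo: Path | None = None
    interval_cm: float | None = Field(None, ge=0.0)
    rf: RfParams = RfParams()
    calling: CallingParams = CallingParams()
    landscape: LandscapeParams = LandscapeParams()

    @field_validator("seed_counts", "depths", "snps", "hotspots", "control_xo")
    @classmethod
    def _must_exist(cls, v: Path | None) -> Path | None:
        if v is not None and not Path(v).is_file():
            raise ValueError(f"input file not found: {v}")
        return v

    @model_validator(mode="after")
    def _check_stage_inputs(self) -> "RunConfig":
        if self.depths is not None and self.snps is None:
            raise ValueError("depths input requires a snps marker map")
        if self.seed_counts is None and self.depths is None:
            raise ValueError("config drives no stage: give seed_counts and/or depths")
        return self


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31; no hidden global RNG."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_snp_map(path: Path) -> xo_mapper.SnpMap:
    if str(path).endswith(".vcf"):
        return xo_mapper.read_snp_map_vcf(path)
    return xo_mapper.read_snp_map_tsv(path)


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    outputs: dict[str, str] = {}
    stage_seeds: dict[str, int] = {}
    summary: dict = {}
    interval_cm = config.interval_cm

    def finish(stage: str, t0: float) -> None:
        logger.info("stage %s finished in %.2f s", stage, time.time() - t0)

    try:
        if config.seed_counts is not None:
            t0 = time.time()
            stage_seeds["rf"] = stage_seed(config.seed, "rf")
            try:
                counts = seed_rf.read_seed_counts(config.seed_counts)
                table = seed_rf.rf_table(
                    counts,
                    n_boot=config.rf.n_boot,
                    level=config.rf.level,
                    rng_seed=stage_seeds["rf"],
                )
                rf_path = out / "rf.tsv"
                seed_rf.write_rf_table(table, rf_path)
                outputs["rf"] = str(rf_path)
                pooled = table.loc[table.cross_id == "POOLED", "cm"]
                summary["rf_pooled_cm"] = (
                    float(pooled.iloc[0]) if len(pooled) else float(table.cm.iloc[0])
                )
                summary["rf_mean_cm"] = float(
                    table.loc[~table.cross_id.isin(["MEAN", "POOLED"]), "cm"].mean()
                )
                if interval_cm is None:
                    interval_cm = summary["rf_pooled_cm"]
            except (ValueError, OSError) as exc:
                raise PipelineError("rf", str(exc)) from exc
            finish("rf", t0)

        calls = None
        snps = None
        if config.depths is not None:
            t0 = time.time()
            try:
                snps = _read_snp_map(config.snps)
                tables = xo_mapper.read_depth_tables(config.depths, snps)
                calls, tally = xo_mapper.map_population(
                    tables,
                    snps,
                    min_depth=config.calling.min_depth,
                    het_band=config.calling.het_band,
                    hom_max=config.calling.hom_max,
                    min_flank=config.calling.min_flank,
                )
                xo_path = out / "xo.bed"
                xo_mapper.write_crossover_bed(calls, xo_path)
                outputs["crossovers"] = str(xo_path)
                summary["call_tally"] = {k.value: v for k, v in tally.items()}
            except (ValueError, OSError) as exc:
                raise PipelineError("call", str(exc)) from exc
            finish("call", t0)

        if calls is not None:
            t0 = time.time()
            try:
                ok = [c for c in calls if c.status is xo_mapper.CallStatus.OK]
                if not ok:
                    raise ValueError("no OK crossover calls; cannot build landscapes")
                edges = snps.positions
                dist = ls.build_distribution(ok, edges, smear=config.landscape.smear)
                dist_path = out / "distribution.bedgraph"
                ls.write_bedgraph(dist, dist_path, chrom=snps.chrom)
                outputs["distribution"] = str(dist_path)

                if interval_cm is not None:
                    track = ls.moving_average_cm_per_mb(
                        ok,
                        interval_cm,
                        (snps.start, snps.end),
                        window=config.landscape.window,
                        step=config.landscape.step,
                    )
                    cm_path = out / "cm_per_mb.bedgraph"
                    ls.write_bedgraph(track, cm_path, chrom=snps.chrom)
                    outputs["cm_per_mb"] = str(cm_path)
                    summary["track_integral_cm"] = ls.track_integral_cm(track)

                hotspots = (
                    ls.read_hotspot_bed(config.hotspots) if config.hotspots else None
                )
                usage = None
                if hotspots:
                    usage = ls.hotspot_usage(ok, hotspots)
                    usage_path = out / "usage.tsv"
                    ls.write_usage_tsv(usage, usage_path)
                    outputs["usage"] = str(usage_path)
                    summary["hotspot_usage"] = dict(usage.shares)

                if config.control_xo is not None:
                    control_calls = xo_mapper.read_crossover_bed(config.control_xo)
                    control_ok = [
                        c for c in control_calls if c.status is xo_mapper.CallStatus.OK
                    ]
                    control_dist = ls.build_distribution(control_ok, edges)
                    diff = ls.differential_track(dist, control_dist)
                    diff_path = out / "difference.bedgraph"
                    ls.write_bedgraph(diff, diff_path, chrom=snps.chrom)
                    outputs["difference"] = str(diff_path)
                    if hotspots and usage is not None:
                        control_usage = ls.hotspot_usage(control_ok, hotspots)
                        red_rows = [
                            dict(
                                hotspot=h.name,
                                reduction_pct=ls.hotspot_reduction(
                                    usage, control_usage, h.name
                                ),
                            )
                            for h in hotspots
                            if control_usage.shares.get(h.name, 0) > 0
                        ]
                        import pandas as pd

                        red_path = out / "reduction.tsv"
                        pd.DataFrame(red_rows).to_csv(
                            red_path, sep="\t", index=False, float_format="%.6g"
                        )
                        outputs["reduction"] = str(red_path)
                        summary["hotspot_reduction_pct"] = {
                            r["hotspot"]: r["reduction_pct"] for r in red_rows
                        }
            except PipelineError:
                raise
            except (ValueError, OSError) as exc:
                raise PipelineError("landscape", str(exc)) from exc
            finish("landscape", t0)

        manifest = dict(
            xomap_version=__version__,
            config=json.loads(config.model_dump_json()),
            resolved_parameters=dict(
                rf=config.rf.model_dump(),
                calling=config.calling.model_dump(),
                landscape=config.landscape.model_dump(),
                interval_cm=interval_cm,
            ),
            stage_seeds=stage_seeds,
            outputs={k: dict(path=v, sha256=_sha256(Path(v))) for k, v in outputs.items()},
            summary=summary,
        )
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        logger.info("wrote manifest %s", manifest_path)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
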