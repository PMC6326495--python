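"""Run configuration and orchestration: simulate → prioritize → evaluate → report.

The four named scenarios pair an objective with a hierarchical removal-mask
construction:

====================================  =========  =================================
scenario                              objective  cells locked into the top ranks
====================================  =========  =================================
prioritize_richness                   ABF        protected areas
prioritize_rarity                     CAZ        protected areas
prioritize_richness_outside_focal     ABF        protected areas + focal areas
prioritize_rarity_outside_focal       CAZ        protected areas + focal areas
====================================  =========  =================================

The "outside" scenarios rank what matters beyond the existing estate by
forcing protected and focal cells to be the final cells removed.
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

from . import io as rio
from .coverage import (
    coverage_vs_random,
    equal_area_comparison,
    records_to_frame,
)
from .errors import ConfigError
from .grids import LandscapeStack, RegionMask
from .prioritizer import (
    PrioritizerConfig,
    RankMap,
    RemovalMask,
    rank_landscape,
)
from .simulate import SimConfig, SimResult, simulate_landscape
from .threats import evaluate_threats
from .threats import records_to_frame as threat_records_to_frame

__all__ = [
    "SCENARIOS",
    "RunConfig",
    "build_removal_mask",
    "run_pipeline",
    "write_simulated_inputs",
    "load_run_config",
]

log = logging.getLogger(__name__)

#: scenario name -> (objective, lock focal areas into the top ranks?)
SCENARIOS: dict[str, tuple[str, bool]] = {
    "prioritize_richness": ("abf", False),
    "prioritize_rarity": ("caz", False),
    "prioritize_richness_outside_focal": ("abf", True),
    "prioritize_rarity_outside_focal": ("caz", True),
}


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    sim: SimConfig = field(default_factory=SimConfig)
    scenarios: tuple[str, ...] = tuple(SCENARIOS)
    z_exponent: float = 0.25
    warp: int = 1
    outdir: str = "runs/out"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ConfigError(f"unknown scenarios: {sorted(unknown)}")


def load_run_config(path) -> RunConfig:
    """Read a YAML (or JSON — a YAML subset) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", {})
    if "umbrella_assoc" in sim_raw and sim_raw["umbrella_assoc"] is not None:
        sim_raw["umbrella_assoc"] = tuple(sim_raw["umbrella_assoc"])
    if "range_size_bounds" in sim_raw:
        sim_raw["range_size_bounds"] = tuple(sim_raw["range_size_bounds"])
    if "assoc_bounds" in sim_raw:
        sim_raw["assoc_bounds"] = tuple(sim_raw["assoc_bounds"])
    if "scenarios" in raw:
        raw["scenarios"] = tuple(raw["scenarios"])
    try:
        return RunConfig(sim=SimConfig(**sim_raw), **raw)
    except TypeError as exc:
        raise ConfigError(f"bad run configuration {path}: {exc}") from exc


def build_removal_mask(
    scenario: str,
    protected: RegionMask | None,
    focal: RegionMask | None,
    grid=None,
) -> RemovalMask:
    """Hierarchical removal mask for a named scenario.

    Protected cells sit at level 1 in every scenario (the last cells removed,
    hence top-ranked); the "outside" scenarios raise focal cells to level 1
    as well. With no masks supplied all cells stay at level 0.
    """
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}")
    _, lock_focal = SCENARIOS[scenario]
    if grid is None:
        for m in (protected, focal):
            if m is not None:
                grid = m.grid
                break
    if grid is None:
        raise ConfigError("build_removal_mask needs a grid or at least one mask")
    level = np.zeros(grid.shape, dtype=np.int64)
    if protected is not None:
        level[protected.member] = 1
    if lock_focal and focal is not None:
        level[focal.member] = 1
    return RemovalMask(grid, level)


def _json_safe(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _json_safe(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, np.ndarray):
        return _json_safe(obj.tolist())
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_simulated_inputs(result: SimResult, outdir) -> Path:
    """Write a simulated input set to disk: GeoTIFFs, manifest CSV, truth JSON."""
    out = Path(outdir)
    (out / "features").mkdir(parents=True, exist_ok=True)
    rows = []
    for layer, row in zip(result.raw_species_layers, result.truth.features.itertuples(index=False)):
        p = out / "features" / f"{layer.layer_id}.tif"
        rio.write_raster(layer, p)
        rows.append((row.feature_id, row.species_id, row.season_tag, f"features/{p.name}"))
    manifest = pd.DataFrame(rows, columns=rio.MANIFEST_COLUMNS)
    rio.write_manifest(manifest, out / "manifest.csv")
    rio.write_raster(result.umbrella, out / "umbrella.tif")
    rio.write_raster(result.landcover_baseline, out / "landcover_baseline.tif")
    for fut in result.landcover_futures:
        rio.write_raster(fut, out / f"{fut.layer_id}.tif")
    rio.write_raster(result.rr_class, out / "rr_class.tif")
    rio.write_raster(result.stack.analysis_mask, out / "analysis_mask.tif")
    rio.write_raster(result.stack.focal_mask, out / "focal_mask.tif")
    rio.write_raster(result.stack.protected_mask, out / "protected_mask.tif")
    truth = {
        "features": result.truth.features.to_dict(orient="records"),
        "scenario_threat_bias": result.truth.scenario_threat_bias,
        "realized_focal_fraction": result.truth.realized_focal_fraction,
        "seed": result.truth.seed,
    }
    (out / "truth.json").write_text(json.dumps(_json_safe(truth), indent=1))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Stages: simulate the landscape, rank it under each configured scenario,
    evaluate focal-area coverage against the random baseline and the
    equal-area prioritizations, and summarize threat exposure inside vs
    outside the focal region. Outputs land in ``config.outdir`` together with
    a checksummed output manifest and a machine-readable run log; runs are
    deterministic for a fixed config.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    log.info("simulating landscape (seed=%d)", config.seed)
    result = simulate_landscape(config.sim, seed=config.seed)
    stack = result.stack
    features = stack.features
    analysis, focal, protected = stack.analysis_mask, stack.focal_mask, stack.protected_mask
    current_region = focal.union(protected, "focal_plus_protected")

    rank_maps: dict[str, RankMap] = {}
    prio_log: dict[str, dict] = {}
    for scenario in config.scenarios:
        objective, _ = SCENARIOS[scenario]
        pconf = PrioritizerConfig(objective=objective, z_exponent=config.z_exponent,
                                  warp=config.warp)
        mask = build_removal_mask(scenario, protected, focal, stack.grid)
        log.info("ranking scenario %s (%s)", scenario, objective)
        rank_map, table = rank_landscape(stack, pconf, mask)
        rank_maps[scenario] = rank_map
        p_rank = out / f"rank_{scenario}.tif"
        rio.write_raster(rank_map, p_rank)
        p_perf = out / f"performance_{scenario}.csv"
        table.to_frame().to_csv(p_perf, index=False)
        written += [p_rank, p_perf]
        prio_log[scenario] = {
            "objective": pconf.objective,
            "z_exponent": pconf.z_exponent,
            "warp": pconf.warp,
            "tie_break": pconf.tie_break,
        }

    log.info("evaluating focal-area coverage")
    records, cov_summary = coverage_vs_random(features, focal, analysis)
    p_cov = out / "coverage.csv"
    records_to_frame(records).to_csv(p_cov, index=False)
    written.append(p_cov)

    equal_area = {}
    for scenario in ("prioritize_richness", "prioritize_rarity"):
        if scenario in rank_maps:
            frame, test = equal_area_comparison(features, current_region, rank_maps[scenario])
            p = out / f"equal_area_{scenario}.csv"
            frame.to_csv(p, index=False)
            written.append(p)
            equal_area[scenario] = {
                "mean_current": float(frame.current_coverage.mean()),
                "mean_prioritized": float(frame.prioritized_coverage.mean()),
                "test": test,
            }
    cov_payload = {"summary": cov_summary, "equal_area": equal_area}
    p_cov_json = out / "coverage_summary.json"
    p_cov_json.write_text(json.dumps(_json_safe(cov_payload), indent=1))
    written.append(p_cov_json)

    threat_payload = {}
    if result.lulc_threats:
        lulc_records, lulc_summary = evaluate_threats(
            features, result.lulc_threats, focal, analysis
        )
        cheat_records, cheat_summary = evaluate_threats(
            features, [result.cheatgrass_threat], focal, analysis
        )
        p_exp = out / "threat_exposure.csv"
        threat_records_to_frame(lulc_records + cheat_records).to_csv(p_exp, index=False)
        written.append(p_exp)
        threat_payload = {"lulc": lulc_summary, "cheatgrass": cheat_summary}
        p_thr = out / "threat_summary.json"
        p_thr.write_text(json.dumps(_json_safe(threat_payload), indent=1))
        written.append(p_thr)
    else:
        log.warning("no threat layers available; threat stage skipped")

    run_log = {
        "seed": config.seed,
        "scenarios": list(config.scenarios),
        "prioritizer": prio_log,
        "sim": _json_safe(dataclasses.asdict(config.sim)),
        "realized_focal_fraction": result.truth.realized_focal_fraction,
        "n_features": len(features),
    }
    p_run = out / "run_log.json"
    p_run.write_text(json.dumps(_json_safe(run_log), indent=1))
    written.append(p_run)

    manifest = {str(p.relative_to(out)): _sha256(p) for p in written}
    (out / "outputs_manifest.json").write_text(json.dumps(manifest, indent=1))

    return {
        "result": result,
        "rank_maps": rank_maps,
        "coverage_records": records,
        "coverage_summary": cov_summary,
        "equal_area": equal_area,
        "threats": threat_payload,
        "outdir": out,
    }
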