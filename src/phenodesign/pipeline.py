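"""Pipeline orchestration: simulate, sweep blocking arrangements, compare
designs; everything written as CSV plus a JSON run manifest and a log.

Identical config + seed => byte-identical outputs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .designs import figure_style_sweep
from .efficiency import compare_designs, efficiency_table, relative_precision
from .field import FieldParams, make_field, simulate_uniformity
from .layout import GridLayout
from .tactics import GrowthParams, Tactic, build_schedule, simulate_tactic_response


def _field_params(config: RunConfig) -> FieldParams:
    return FieldParams(
        zone_mean=config.zone_mean,
        zone_sd=config.zone_sd,
        pos_slope=config.pos_slope,
        lane_effects=config.lane_effects or None,
        shaded_lanes=frozenset(config.shaded_lanes),
        shade_penalty=config.shade_penalty,
        ar1_rho=config.ar1_rho,
        seed=config.seed,
    )


def _simulate_stage(config: RunConfig, outdir: Path, log: list[str]):
    params = _field_params(config)
    if config.tactic:
        tactic = Tactic(config.tactic)
        n_lanes = max(config.n_lanes, tactic.cycle_lanes[1])
        lane_effects = config.lane_effects or None
        if lane_effects is not None and len(lane_effects) != n_lanes:
            lane_effects = tuple(lane_effects) + (0.0,) * (n_lanes - len(lane_effects))
        house = GridLayout(n_lanes=n_lanes, n_positions=config.n_positions)
        house_params = FieldParams(
            zone_mean=config.zone_mean,
            zone_sd=config.zone_sd,
            pos_slope=config.pos_slope,
            lane_effects=lane_effects,
            shaded_lanes=frozenset(config.shaded_lanes),
            shade_penalty=config.shade_penalty,
            ar1_rho=config.ar1_rho,
            seed=config.seed,
        )
        surface = make_field(house, house_params)
        schedule = build_schedule(tactic, house, n_timepoints=config.n_timepoints)
        schedule.to_csv(outdir / "schedule.csv")
        growth = GrowthParams(
            baseline_rate=config.growth_rate,
            initial_value=config.initial_value,
            log_sd=config.growth_log_sd,
            seed=config.seed,
        )
        traj, data = simulate_tactic_response(schedule, surface, growth)
        traj.to_csv(outdir / "trajectories.csv", index=False)
        log.append(f"simulated tactic '{config.tactic}' over {config.n_timepoints} time points")
    else:
        layout = GridLayout(n_lanes=config.n_lanes, n_positions=config.n_positions)
        surface = make_field(layout, params)
        data = simulate_uniformity(surface, params)
        log.append("simulated uniformity data (no relocation)")
    data.to_csv(outdir / "uniformity.csv")
    return data


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> blocking sweep -> design comparison.

    Returns the manifest (also written to ``<outdir>/manifest.json``);
    a stage failure aborts with the manifest recording completed stages.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "config.txt")
    log: list[str] = []
    manifest: dict = {
        "config": config.as_dict(),
        "stages": [],
        "files": ["config.txt"],
    }

    def finish_stage(name: str, t0: float) -> None:
        manifest["stages"].append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})

    try:
        t0 = time.perf_counter()
        data = _simulate_stage(config, outdir, log)
        manifest["files"].append("uniformity.csv")
        finish_stage("simulate", t0)

        t0 = time.perf_counter()
        rows = [relative_precision(data, arr) for arr in figure_style_sweep(data.layout)]
        pd.DataFrame(rows).to_csv(outdir / "blocking.csv", index=False)
        manifest["files"].append("blocking.csv")
        log.append(f"blocking sweep: {len(rows)} arrangements")
        finish_stage("blocking_sweep", t0)

        t0 = time.perf_counter()
        results = compare_designs(
            data,
            menu=config.menu,
            n_samples=config.n_samples,
            alpha=config.alpha,
            seed=config.seed + 1,
        )
        table = efficiency_table(results)
        table.to_csv(outdir / "designs_re.csv", index=False)
        manifest["files"].append("designs_re.csv")
        n_fail = int(table["n_failures"].sum())
        n_iter = int(table["n_samples"].sum())
        log.append(
            f"design comparison: {len(results)} entries, {n_iter} MC iterations, "
            f"{n_fail} failed fits"
        )
        manifest["mc_iterations"] = n_iter
        manifest["mc_failures"] = n_fail
        finish_stage("compare_designs", t0)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        log.append(f"ABORTED: {manifest['error']}")
        _write_manifest(outdir, manifest, log)
        raise
    _write_manifest(outdir, manifest, log)
    return manifest


def _write_manifest(outdir: Path, manifest: dict, log: list[str]) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (outdir / "run.log").write_text("\n".join(log) + "\n")
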