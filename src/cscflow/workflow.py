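"""End-to-end pipeline: sample -> simulate -> PRCC -> levels -> bifurcation.

Each stage persists its artifacts so stages are independently re-runnable,
and a JSON manifest (seed, versions, timings, failure counts) makes the
bundle reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .bifurcation import scan_parameter
from .config import ExperimentConfig
from .ensemble import TimeGrid, outputs_at_time, save_ensemble, simulate_ensemble
from .levels import colored_scatter, colored_traces, combine_columns, partition_range
from .models import get_model
from .sampling import lhs_sample, resolve_interval, write_design
from .sensitivity import plot_prcc_time_courses, prcc_over_time

log = logging.getLogger(__name__)

__all__ = ["run_workflow", "WorkflowResult"]

# the population model's progenitor pool is reported as one pooled variable
_CSC_DISPLAY = ["N_CSC", ("N_PC", ["N_PC1", "N_PC2"]), "N_TC", "N_DC"]


@dataclass
class WorkflowResult:
    output_dir: Path
    manifest: dict
    artifacts: dict[str, str] = field(default_factory=dict)


def _grid_from_config(cfg: ExperimentConfig) -> TimeGrid:
    tg = cfg.time_grid
    if tg.explicit is not None:
        return TimeGrid(np.asarray(tg.explicit, dtype=float))
    return TimeGrid.uniform(tg.t_ini, tg.t_end, tg.points)


def run_workflow(cfg: ExperimentConfig) -> WorkflowResult:
    """Execute the full three-phase workflow described by a config."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.yaml").write_text(cfg.normalized_yaml())

    manifest: dict = {
        "tool": "cscflow",
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "model": cfg.model,
        "n": cfg.n,
        "stages": {},
    }
    artifacts: dict[str, str] = {}
    stage_t0 = time.perf_counter()

    def finish_stage(name: str, **extra) -> None:
        nonlocal stage_t0
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - stage_t0, 3), **extra}
        stage_t0 = time.perf_counter()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    try:
        model = get_model(cfg.model)
        specs = cfg.specs()
        design = lhs_sample(specs, cfg.n, cfg.seed)
        write_design(design, out / "design.csv")
        artifacts["design"] = str(out / "design.csv")
        finish_stage("sample", k=design.k)

        grid = _grid_from_config(cfg)
        y0 = np.asarray(cfg.initial_state, float) if cfg.initial_state is not None else None
        Y = simulate_ensemble(
            model, design, grid, y0=y0,
            rtol=cfg.solver.rtol, atol=cfg.solver.atol, method=cfg.solver.method,
        )
        save_ensemble(Y, out / "ensemble")
        artifacts["ensemble"] = str(out / "ensemble")
        finish_stage("simulate", failures=len(Y.failure_log))

        sens = prcc_over_time(design, Y, alpha=cfg.alpha)
        sens.save(out / "sensitivity")
        plot_prcc_time_courses(sens, out / "sensitivity",
                               formats=tuple(cfg.plot.formats),
                               highlight=tuple(cfg.key_parameters))
        artifacts["sensitivity"] = str(out / "sensitivity")
        finish_stage("prcc", n_effective=sens.n_effective)

        display = _CSC_DISPLAY if cfg.model == "csc" else None
        scatter_times = cfg.scatter_times or [grid.t_end]
        for key in cfg.key_parameters:
            lo, hi = resolve_interval(design.specs[design.parameter_names.index(key)])
            part = partition_range(lo, hi, cfg.r, parameter=key)
            key_col = design.column(key)
            lvl_dir = out / "levels" / key
            colored_traces(Y, key_col, part, lvl_dir, scale=cfg.plot.scale,
                           variables=display, formats=tuple(cfg.plot.formats),
                           log_floor=cfg.plot.log_floor)
            for t in scatter_times:
                table, t_used = outputs_at_time(Y, t, snap=True)
                table = table.iloc[Y.surviving()]
                for var in Y.variable_names:
                    colored_scatter(table, key_col[Y.surviving()], part, var, lvl_dir,
                                    time=t_used, formats=tuple(cfg.plot.formats))
                for expr in cfg.combinations:
                    xcol = combine_columns(expr, design)[Y.surviving()]
                    colored_scatter(table, xcol, part, str(Y.variable_names[0]), lvl_dir,
                                    time=t_used, x_label=expr,
                                    color_values=key_col[Y.surviving()],
                                    formats=tuple(cfg.plot.formats))
            artifacts[f"levels/{key}"] = str(lvl_dir)
        finish_stage("levels", keys=list(cfg.key_parameters))

        for bcfg in cfg.bifurcation:
            diagram = scan_parameter(model, model.default_parameters, bcfg.parameter,
                                     (bcfg.min, bcfg.max), n_points=bcfg.points)
            stem = out / f"bifurcation_{bcfg.parameter}"
            diagram.save(stem.with_suffix(".csv"))
            diagram.plot(stem.with_suffix(".png"), state_index=0,
                         state_label=model.state_names[0])
            artifacts[f"bifurcation/{bcfg.parameter}"] = str(stem.with_suffix(".csv"))
            manifest.setdefault("transcritical_points", {})[bcfg.parameter] = [
                tp.parameter_value for tp in diagram.transcritical_points
            ]
        finish_stage("bifurcation", scans=len(cfg.bifurcation))
    except Exception as exc:
        manifest["failed_stage"] = {
            "error": f"{type(exc).__name__}: {exc}",
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    manifest["artifacts"] = artifacts
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return WorkflowResult(output_dir=out, manifest=manifest, artifacts=artifacts)
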