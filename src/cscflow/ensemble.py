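"""Batch ODE integration over a design: the output matrix Y.

Phase 1.2 of the workflow: every row of the Latin hypercube design is used
as the parameter vector of one numerical integration over a common time
grid, producing an ``n x m x v`` output array (samples x times x state
variables).  Integration failures are recorded per row rather than aborting
the batch, and downstream statistics use the surviving rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._errors import ContractError, DomainError
from .models import ModelDefinition
from .sampling import SampleDesign

__all__ = ["TimeGrid", "SimulationResult", "EnsembleOutput", "simulate_one",
           "simulate_ensemble", "outputs_at_time", "save_ensemble", "load_ensemble"]

log = logging.getLogger(__name__)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_METHOD = "LSODA"  # stiff-capable; the workflow does not depend on the choice


@dataclass(frozen=True)
class TimeGrid:
    """Ordered output times including both interval endpoints."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise DomainError("a time grid needs at least two points")
        if not np.all(np.diff(pts) > 0):
            raise DomainError("time grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @classmethod
    def uniform(cls, t_ini: float, t_end: float, m: int) -> "TimeGrid":
        if not t_ini < t_end:
            raise DomainError(f"need t_ini < t_end, got {(t_ini, t_end)}")
        if m < 2:
            raise DomainError(f"need at least 2 grid points, got {m}")
        return cls(np.linspace(t_ini, t_end, m))

    @property
    def t_ini(self) -> float:
        return float(self.points[0])

    @property
    def t_end(self) -> float:
        return float(self.points[-1])

    @property
    def m(self) -> int:
        return self.points.size


@dataclass
class SimulationResult:
    """Outcome of one integration: an m x v trace or a structured failure."""

    trace: np.ndarray | None
    success: bool
    message: str = ""


@dataclass
class EnsembleOutput:
    """The Y matrix: n runs x m times x v variables, with success flags."""

    grid: TimeGrid
    variable_names: tuple[str, ...]
    values: np.ndarray
    success: np.ndarray
    failure_log: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variable_names = tuple(self.variable_names)
        n, m, v = self.values.shape
        if m != self.grid.m or v != len(self.variable_names):
            raise ContractError(
                f"Y shape {self.values.shape} inconsistent with grid ({self.grid.m} points) "
                f"and variables ({len(self.variable_names)})"
            )
        if self.success.shape != (n,):
            raise ContractError("success flags must have one entry per sample")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_success(self) -> int:
        return int(self.success.sum())

    def surviving(self) -> np.ndarray:
        """Indices of the rows whose integration succeeded."""
        return np.flatnonzero(self.success)


def simulate_one(
    model: ModelDefinition,
    params: np.ndarray,
    y0: np.ndarray,
    grid: TimeGrid,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> SimulationResult:
    """Integrate one parameter set, returning the solution at the grid times.

    Failures (step-size collapse, divergence) come back as structured
    results, not exceptions, so an ensemble keeps running.
    """
    if rtol <= 0 or atol <= 0:
        raise DomainError("solver tolerances must be positive")
    y0, params = model.check_vectors(y0, params)
    jac = None
    if model.jacobian is not None:
        jac = lambda t, y: model.jacobian(y, params)  # noqa: E731

    def guarded_rhs(t, y):
        # fail fast on blow-up instead of letting the solver grind
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > 1e15:
            raise FloatingPointError(f"state overflow during integration at t={t:g}")
        return model.rhs(y, params, t)

    try:
        sol = solve_ivp(
            guarded_rhs,
            (grid.t_ini, grid.t_end),
            y0,
            method=method,
            t_eval=grid.points,
            rtol=rtol,
            atol=atol,
            jac=jac,
        )
    except (ValueError, FloatingPointError, OverflowError) as exc:
        return SimulationResult(trace=None, success=False, message=str(exc))
    if not sol.success or sol.y.shape[1] != grid.m or not np.all(np.isfinite(sol.y)):
        return SimulationResult(trace=None, success=False,
                                message=sol.message or "non-finite solution")
    return SimulationResult(trace=sol.y.T.copy(), success=True)


def simulate_ensemble(
    model: ModelDefinition,
    design: SampleDesign,
    grid: TimeGrid,
    y0: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
    max_failure_fraction: float = 0.5,
) -> EnsembleOutput:
    """Integrate the model once per design row and assemble Y.

    Design columns override the model defaults by name; parameters absent
    from the design keep their defaults.  Failed rows are flagged, logged
    and excluded from downstream statistics; more than
    ``max_failure_fraction`` failures is treated as a setup error.
    """
    unknown = set(design.parameter_names) - set(model.parameter_names)
    if unknown:
        raise ContractError(
            f"design columns {sorted(unknown)} are not parameters of model {model.name!r}"
        )
    y0 = model.default_initial_state if y0 is None else np.asarray(y0, dtype=float)
    index = [model.parameter_names.index(name) for name in design.parameter_names]
    base = model.default_parameters
    rows = design.matrix.to_numpy()

    n = design.n
    values = np.full((n, grid.m, model.n_states), np.nan)
    success = np.zeros(n, dtype=bool)
    failures: list[tuple[int, str]] = []
    for i in range(n):
        p = base.copy()
        p[index] = rows[i]
        res = simulate_one(model, p, y0, grid, rtol=rtol, atol=atol, method=method)
        if res.success:
            values[i] = res.trace
            success[i] = True
        else:
            failures.append((i, res.message))
    if failures:
        log.warning("%d of %d integrations failed; surviving rows feed the statistics",
                    len(failures), n)
    if len(failures) > max_failure_fraction * n:
        raise RuntimeError(
            f"{len(failures)}/{n} integrations failed; review solver tolerances "
            "and parameter ranges"
        )
    return EnsembleOutput(
        grid=grid,
        variable_names=model.state_names,
        values=values,
        success=success,
        failure_log=failures,
    )


def outputs_at_time(
    output: EnsembleOutput, t: float, snap: bool = False
) -> tuple[pd.DataFrame, float]:
    """Slice Y at one grid time, returning an n x v table and the time used.

    With ``snap=False`` the requested time must coincide with a grid point;
    with ``snap=True`` the nearest grid time is used and reported.
    """
    pts = output.grid.points
    if t < pts[0] or t > pts[-1]:
        raise DomainError(f"t={t} outside the grid range [{pts[0]}, {pts[-1]}]")
    j = int(np.argmin(np.abs(pts - t)))
    if not snap and not np.isclose(pts[j], t, rtol=0.0, atol=1e-12 * max(1.0, abs(t))):
        raise DomainError(
            f"t={t} is not a grid point (nearest: {pts[j]}); pass snap=True to use it"
        )
    table = pd.DataFrame(output.values[:, j, :], columns=list(output.variable_names))
    return table, float(pts[j])


# --------------------------------------------------------------------------
# persistence: one wide CSV per variable + a JSON metadata sidecar
# --------------------------------------------------------------------------

def save_ensemble(output: EnsembleOutput, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for j, var in enumerate(output.variable_names):
        frame = pd.DataFrame(output.values[:, :, j], columns=[f"{t:.10g}" for t in output.grid.points])
        frame.to_csv(directory / f"Y_{var}.csv", index=False, float_format="%.17g")
    meta = {
        "variable_names": list(output.variable_names),
        "grid": [float(t) for t in output.grid.points],
        "success": output.success.astype(int).tolist(),
        "failure_log": [[int(i), msg] for i, msg in output.failure_log],
    }
    (directory / "ensemble.json").write_text(json.dumps(meta, indent=1))
    return directory


def load_ensemble(directory) -> EnsembleOutput:
    directory = Path(directory)
    meta = json.loads((directory / "ensemble.json").read_text())
    grid = TimeGrid(np.asarray(meta["grid"], dtype=float))
    names = meta["variable_names"]
    mats = [
        pd.read_csv(directory / f"Y_{var}.csv", float_precision="round_trip").to_numpy()
        for var in names
    ]
    values = np.stack(mats, axis=-1)
    return EnsembleOutput(
        grid=grid,
        variable_names=tuple(names),
        values=values,
        success=np.asarray(meta["success"], dtype=bool),
        failure_log=[(int(i), m) for i, m in meta["failure_log"]],
    )
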