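"""Color-coded partitioning of a key parameter and the colored plots.

Phase 3.1-3.2 of the workflow: the variation range of an identified key
parameter (or a derived combination of parameters) is split into ``r``
equal-width levels, each level gets a color (black / blue / red / green for
the default r = 4, lowest to highest), and every model trace or scatter
point is drawn in the color of the level containing its parameter value.
Switch-like behavior then shows up as color-stratified bundles.
"""

from __future__ import annotations

import ast
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DomainError
from .ensemble import EnsembleOutput
from .sampling import SampleDesign

__all__ = ["LevelPartition", "partition_range", "assign_level", "assign_levels",
           "combine_columns", "colored_traces", "colored_scatter", "format_bound"]

log = logging.getLogger(__name__)

DEFAULT_COLORS = ("black", "blue", "red", "green")
DEFAULT_LOG_FLOOR = 1e-3  # cells; values at/below 0 are clipped here on log axes


def format_bound(x: float) -> str:
    """Legend printing of a boundary: round half-up to 2 decimals.

    Internal boundaries keep full precision; only the printed legend is
    rounded (a published table of such partitions truncates instead, so a
    boundary of exactly x.xx5 may print one last digit higher here).
    """
    return str(Decimal(x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LevelPartition:
    """r equal-width, color-labeled subintervals of one parameter's range.

    Bracket convention: the first interval is closed on both ends, the rest
    are left-open right-closed, i.e. ``[min, b1] (b1, b2] ... (b_{r-1}, max]``.
    """

    parameter: str
    min: float
    max: float
    r: int
    boundaries: np.ndarray
    labels: tuple[str, ...]

    @property
    def intervals(self) -> list[tuple[float, float]]:
        edges = np.concatenate([[self.min], self.boundaries, [self.max]])
        return [(float(edges[i]), float(edges[i + 1])) for i in range(self.r)]

    def legend_entries(self) -> list[str]:
        brackets = [("[", "]")] + [("(", "]")] * (self.r - 1)
        return [
            f"{self.labels[i]}: {lo_b}{format_bound(lo)}, {format_bound(hi)}{hi_b}"
            for i, ((lo, hi), (lo_b, hi_b)) in enumerate(zip(self.intervals, brackets))
        ]


def _palette(r: int) -> tuple[str, ...]:
    if r == len(DEFAULT_COLORS):
        return DEFAULT_COLORS
    import matplotlib
    from matplotlib.colors import to_hex

    cmap = matplotlib.colormaps["viridis"].resampled(r)
    return tuple(to_hex(cmap(i)) for i in range(r))


def partition_range(
    min: float,
    max: float,
    r: int = 4,
    parameter: str = "",
    labels: tuple[str, ...] | None = None,
) -> LevelPartition:
    """Partition [min, max] into r equal-width color-coded levels."""
    if not min < max:
        raise DomainError(f"partition needs min < max, got {(min, max)}")
    if r < 2:
        raise DomainError(f"partition needs r >= 2 levels, got {r}")
    boundaries = min + (max - min) * np.arange(1, r) / r
    if labels is None:
        labels = _palette(r)
    if len(labels) != r:
        raise DomainError(f"need exactly r={r} labels, got {len(labels)}")
    return LevelPartition(
        parameter=parameter,
        min=float(min),
        max=float(max),
        r=r,
        boundaries=boundaries,
        labels=tuple(labels),
    )


def assign_level(value: float, partition: LevelPartition) -> int:
    """1-based index of the level containing ``value``.

    A value exactly on an interior boundary belongs to the lower level
    (left-open right-closed intervals); the minimum belongs to level 1.
    """
    return int(assign_levels(np.asarray([value]), partition)[0])


def assign_levels(values: np.ndarray, partition: LevelPartition) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if np.any(values < partition.min) or np.any(values > partition.max):
        bad = values[(values < partition.min) | (values > partition.max)][0]
        raise DomainError(
            f"value {bad} outside partition range [{partition.min}, {partition.max}]; "
            "clip or extend the partition explicitly"
        )
    # number of interior boundaries strictly below the value -> 0-based level
    return np.searchsorted(partition.boundaries, values, side="left") + 1


# --------------------------------------------------------------------------
# derived parameter combinations
# --------------------------------------------------------------------------

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult)


def _eval_node(node: ast.AST, columns: pd.DataFrame) -> np.ndarray | float:
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, columns)
    if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
        left = _eval_node(node.left, columns)
        right = _eval_node(node.right, columns)
        if isinstance(node.op, ast.Add):
            return left + right
        if isinstance(node.op, ast.Sub):
            return left - right
        return left * right
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        operand = _eval_node(node.operand, columns)
        return -operand if isinstance(node.op, ast.USub) else operand
    if isinstance(node, ast.Name):
        if node.id not in columns.columns:
            raise DomainError(
                f"unknown identifier {node.id!r}; design columns: {list(columns.columns)}"
            )
        return columns[node.id].to_numpy(dtype=float)
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        return float(node.value)
    raise DomainError(
        f"disallowed construct {type(node).__name__} in combination expression; "
        "only identifiers, numbers, +, -, * and parentheses are supported"
    )


def combine_columns(expression: str, design: SampleDesign) -> np.ndarray:
    """Evaluate a restricted arithmetic expression over design columns.

    Grammar: identifiers (design column names), numeric literals, ``+``,
    ``-``, ``*`` and parentheses.  The result is an n-vector usable anywhere
    a raw parameter column is (partitioning, scatter axes).
    """
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise DomainError(f"could not parse combination expression {expression!r}: {exc}") from exc
    result = _eval_node(tree, design.matrix)
    result = np.broadcast_to(np.asarray(result, dtype=float), (design.n,)).copy()
    return result


# --------------------------------------------------------------------------
# colored figures
# --------------------------------------------------------------------------

def _sidecar(path: Path, payload: dict) -> None:
    path.with_suffix(".json").write_text(json.dumps(payload, indent=1))


def _level_counts(levels: np.ndarray, r: int) -> list[int]:
    return [int(np.sum(levels == i)) for i in range(1, r + 1)]


def colored_traces(
    Y: EnsembleOutput,
    key_column: np.ndarray,
    partition: LevelPartition,
    directory,
    scale: str = "linear",
    variables: list[str | tuple[str, list[str]]] | None = None,
    formats: tuple[str, ...] = ("png",),
    log_floor: float = DEFAULT_LOG_FLOOR,
) -> dict[str, Path]:
    """One trace figure per output variable, each trajectory in its level color.

    ``variables`` entries are either state names or ``(display_name,
    [component names])`` pairs whose components are summed — e.g. the total
    progenitor pool from its two levels.  On a log axis, values at or below
    zero are clipped to ``log_floor`` and the clipped count is recorded in
    the figure's JSON sidecar.
    """
    import matplotlib.pyplot as plt

    key_column = np.asarray(key_column, dtype=float)
    if key_column.shape != (Y.n,):
        raise DomainError(f"key column length {key_column.shape} != ensemble size {Y.n}")
    if scale not in ("linear", "log"):
        raise DomainError(f"scale must be 'linear' or 'log', got {scale!r}")
    rows = Y.surviving()
    levels = assign_levels(key_column[rows], partition)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    if variables is None:
        variables = list(Y.variable_names)
    name_index = {v: i for i, v in enumerate(Y.variable_names)}
    out: dict[str, Path] = {}
    for entry in variables:
        if isinstance(entry, tuple):
            display, components = entry
            missing = [c for c in components if c not in name_index]
            if missing:
                raise DomainError(f"unknown variable(s) {missing} in {display!r}")
            data = Y.values[rows][:, :, [name_index[c] for c in components]].sum(axis=2)
        else:
            display = entry
            if entry not in name_index:
                raise DomainError(f"unknown variable {entry!r}; have {list(Y.variable_names)}")
            data = Y.values[rows, :, name_index[entry]]
        clipped = 0
        if scale == "log":
            clipped = int(np.sum(data <= 0.0))
            if clipped:
                log.info("%s: clipped %d non-positive values to %g for the log axis",
                         display, clipped, log_floor)
            data = np.maximum(data, log_floor)
        fig, ax = plt.subplots(figsize=(7, 4))
        for i in range(data.shape[0]):
            ax.plot(Y.grid.points, data[i], color=partition.labels[levels[i] - 1],
                    lw=0.6, alpha=0.8)
        if scale == "log":
            ax.set_yscale("log")
        handles = [plt.Line2D([], [], color=partition.labels[i], lw=2) for i in range(partition.r)]
        ax.legend(handles, partition.legend_entries(), fontsize=7,
                  title=partition.parameter or "key parameter")
        ax.set_xlabel("time")
        ax.set_ylabel(display)
        ax.set_title(f"{display} colored by {partition.parameter or 'key parameter'}")
        fig.tight_layout()
        path = directory / f"traces_{display}.{formats[0]}"
        for fmt in formats:
            fig.savefig(directory / f"traces_{display}.{fmt}", dpi=120)
        plt.close(fig)
        _sidecar(path, {
            "kind": "colored_traces",
            "variable": display,
            "parameter": partition.parameter,
            "scale": scale,
            "bounds": [partition.min, *partition.boundaries.tolist(), partition.max],
            "counts_per_level": _level_counts(levels, partition.r),
            "clipped_points": clipped,
        })
        out[display] = path
    return out


def colored_scatter(
    outputs_t: pd.DataFrame,
    x_column: np.ndarray,
    partition: LevelPartition,
    variable: str,
    directory,
    time: float | None = None,
    x_label: str | None = None,
    color_values: np.ndarray | None = None,
    formats: tuple[str, ...] = ("png",),
) -> Path:
    """Scatter of one output (at a fixed time) versus a parameter or combination.

    The x axis may be any raw or derived column; colors come from the
    partition level of ``color_values`` (the key parameter), which defaults
    to the x column itself — so an output can be plotted against one
    parameter while staying colored by another.
    """
    import matplotlib.pyplot as plt

    if variable not in outputs_t.columns:
        raise DomainError(f"variable {variable!r} not among {list(outputs_t.columns)}")
    x = np.asarray(x_column, dtype=float)
    if x.shape != (outputs_t.shape[0],):
        raise DomainError("x column length does not match the output table")
    cv = x if color_values is None else np.asarray(color_values, dtype=float)
    if cv.shape != x.shape:
        raise DomainError("color_values length does not match the output table")
    levels = assign_levels(cv, partition)
    y = outputs_t[variable].to_numpy(dtype=float)

    fig, ax = plt.subplots(figsize=(5.5, 4))
    for lvl in range(1, partition.r + 1):
        mask = levels == lvl
        ax.scatter(x[mask], y[mask], s=12, color=partition.labels[lvl - 1],
                   label=partition.legend_entries()[lvl - 1])
    ax.set_xlabel(x_label or partition.parameter)
    ax.set_ylabel(variable)
    title = f"{variable} vs {x_label or partition.parameter}"
    if time is not None:
        title += f" at t = {time:g}"
    ax.set_title(title)
    ax.legend(fontsize=6)
    fig.tight_layout()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"scatter_{variable}_vs_{(x_label or partition.parameter).replace('*', 'x').replace(' ', '')}"
    path = directory / f"{stem}.{formats[0]}"
    for fmt in formats:
        fig.savefig(directory / f"{stem}.{fmt}", dpi=120)
    plt.close(fig)
    _sidecar(path, {
        "kind": "colored_scatter",
        "variable": variable,
        "x": x_label or partition.parameter,
        "time": time,
        "bounds": [partition.min, *partition.boundaries.tolist(), partition.max],
        "counts_per_level": _level_counts(levels, partition.r),
    })
    return path
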