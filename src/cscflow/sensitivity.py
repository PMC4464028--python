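"""Partial rank correlation coefficients over the time course.

Phase 2 of the workflow.  PRCC measures the monotone association between a
sampled parameter and a model output after removing, in rank space, the
linear effect of all other sampled parameters: rank-transform every column,
residualize the parameter's ranks and the output's ranks on the remaining
parameters (plus intercept) by least squares, and correlate the two
residual vectors.  Significance follows the classical Student-t statistic
for a partial correlation,

    t = r * sqrt((n - 2 - p) / (1 - r^2)),   p = k - 1 conditioning columns,

with n - 2 - p degrees of freedom; the per-time critical magnitude
``r_crit = t_crit / sqrt(t_crit^2 + dof)`` bounds the non-significant band
drawn in the time-course plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DomainError, SingularityError
from .ensemble import EnsembleOutput
from .sampling import SampleDesign

__all__ = ["rank_transform", "prcc", "prcc_over_time", "SensitivityResult",
           "plot_prcc_time_courses"]


def rank_transform(column: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties averaged."""
    column = np.asarray(column, dtype=float)
    if column.ndim != 1 or column.size < 2:
        raise DomainError("rank_transform needs a 1-d column with n >= 2")
    return stats.rankdata(column, method="average")


def _is_degenerate(column: np.ndarray) -> bool:
    return bool(np.all(column == column[0]))


class _RankResidualizers:
    """Precomputed per-parameter residualizers for a fixed rank design.

    For parameter j, ``Q[j]`` is an orthonormal basis of span{1, ranks of
    the other k-1 columns} and ``u[j]`` the residual of rank(x_j) on it.
    Residualizing any output is then two matrix products, which makes the
    full time-course sweep cheap.
    """

    def __init__(self, X: np.ndarray, names: list[str]):
        n, k = X.shape
        self.n, self.k, self.names = n, k, names
        degenerate = [names[j] for j in range(k) if _is_degenerate(X[:, j])]
        if degenerate:
            raise DomainError(
                f"constant design column(s) {degenerate}: PRCC is undefined for them"
            )
        R = np.column_stack([rank_transform(X[:, j]) for j in range(k)])
        self.Q: list[np.ndarray] = []
        self.u: list[np.ndarray] = []
        for j in range(k):
            others = np.column_stack([np.ones(n), np.delete(R, j, axis=1)])
            q, r = np.linalg.qr(others)
            diag = np.abs(np.diag(r))
            if np.any(diag < 1e-10 * max(1.0, diag.max())):
                bad = [names[i] for i in range(k) if i != j]
                raise SingularityError(
                    f"rank-deficient residualization conditioning on {bad}; "
                    "remove collinear columns"
                )
            self.Q.append(q)
            self.u.append(R[:, j] - q @ (q.T @ R[:, j]))

    def coefficients(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """PRCC and two-sided p-value of each parameter against one output."""
        n, k = self.n, self.k
        out = np.full(k, np.nan)
        pval = np.full(k, np.nan)
        if _is_degenerate(y):
            return out, pval
        ry = rank_transform(y)
        dof = n - 2 - (k - 1)
        for j in range(k):
            v = ry - self.Q[j] @ (self.Q[j].T @ ry)
            u = self.u[j]
            denom = np.sqrt((u @ u) * (v @ v))
            if denom == 0.0:
                continue
            r = float(np.clip((u @ v) / denom, -1.0, 1.0))
            out[j] = r
            if dof > 0:
                if abs(r) == 1.0:
                    pval[j] = 0.0
                else:
                    tstat = r * np.sqrt(dof / (1.0 - r * r))
                    pval[j] = 2.0 * stats.t.sf(abs(tstat), dof)
        return out, pval


def prcc(
    design_matrix: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    parameter_names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """PRCC of each design column against one output vector.

    Returns (coefficients, two-sided p-values), both length k.  A constant
    output yields NaN markers with a warning; constant or collinear design
    columns are errors naming the offending columns.
    """
    if isinstance(design_matrix, pd.DataFrame):
        parameter_names = list(design_matrix.columns)
        X = design_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(design_matrix, dtype=float)
        if parameter_names is None:
            parameter_names = [f"x{j + 1}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if y.shape != (n,):
        raise DomainError(f"output length {y.shape} does not match design rows {n}")
    if n <= k + 1:
        raise DomainError(f"PRCC needs n > k + 1 (got n={n}, k={k})")
    res = _RankResidualizers(X, parameter_names)
    coef, pval = res.coefficients(y)
    if np.all(np.isnan(coef)):
        warnings.warn("output is constant across samples; PRCC undefined", stacklevel=2)
    return coef, pval


@dataclass
class SensitivityResult:
    """Time-resolved PRCCs: arrays of shape m x k x v plus the significance band."""

    times: np.ndarray
    parameter_names: tuple[str, ...]
    variable_names: tuple[str, ...]
    prcc: np.ndarray
    pvalue: np.ndarray
    n_effective: int
    alpha: float
    r_crit: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long table (time, parameter, variable, prcc, pvalue)."""
        m, k, v = self.prcc.shape
        t_idx, p_idx, v_idx = np.meshgrid(
            np.arange(m), np.arange(k), np.arange(v), indexing="ij"
        )
        return pd.DataFrame(
            {
                "time": self.times[t_idx.ravel()],
                "parameter": np.asarray(self.parameter_names)[p_idx.ravel()],
                "variable": np.asarray(self.variable_names)[v_idx.ravel()],
                "prcc": self.prcc.ravel(),
                "pvalue": self.pvalue.ravel(),
            }
        )

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "prcc.csv", index=False)
        summary = {
            "n_effective": int(self.n_effective),
            "alpha": self.alpha,
            "times": self.times.tolist(),
            "r_crit": self.r_crit.tolist(),
            "parameters": list(self.parameter_names),
            "variables": list(self.variable_names),
        }
        pd.Series(summary).to_json(directory / "prcc_summary.json")
        return directory


def prcc_over_time(
    design: SampleDesign,
    Y: EnsembleOutput,
    alpha: float = 0.01,
    stride: int = 1,
) -> SensitivityResult:
    """PRCC at every grid time (optionally strided) and output variable.

    Rows whose integration failed are dropped listwise.  Output variables
    that are constant across samples at some time (e.g. the shared initial
    state at t = 0) produce NaN markers at that time, not an error.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if stride < 1:
        raise DomainError("stride must be >= 1")
    rows = Y.surviving()
    k = design.k
    n = rows.size
    if n < k + 2:
        raise DomainError(
            f"only {n} surviving rows for k={k} parameters; need at least k + 2"
        )
    X = design.matrix.to_numpy(dtype=float)[rows]
    res = _RankResidualizers(X, design.parameter_names)

    times = Y.grid.points[::stride]
    m = times.size
    v = len(Y.variable_names)
    coef = np.full((m, k, v), np.nan)
    pval = np.full((m, k, v), np.nan)
    for a, j in enumerate(range(0, Y.grid.m, stride)):
        for b in range(v):
            y = Y.values[rows, j, b]
            coef[a, :, b], pval[a, :, b] = res.coefficients(y)

    dof = n - 2 - (k - 1)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    r_crit = np.full(m, t_crit / np.sqrt(t_crit**2 + dof))
    return SensitivityResult(
        times=times,
        parameter_names=tuple(design.parameter_names),
        variable_names=Y.variable_names,
        prcc=coef,
        pvalue=pval,
        n_effective=n,
        alpha=alpha,
        r_crit=r_crit,
    )


def plot_prcc_time_courses(
    result: SensitivityResult,
    directory,
    formats: tuple[str, ...] = ("png",),
    highlight: tuple[str, ...] = (),
) -> list[Path]:
    """One PRCC-vs-time figure per output variable.

    The shaded horizontal band marks |PRCC| below the per-time critical
    value, i.e. coefficients not significantly different from zero at the
    result's alpha.
    """
    import matplotlib.pyplot as plt

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for b, var in enumerate(result.variable_names):
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.fill_between(result.times, -result.r_crit, result.r_crit,
                        color="yellow", alpha=0.5, lw=0,
                        label=f"non-significant (alpha={result.alpha:g})")
        for j, par in enumerate(result.parameter_names):
            kwargs = {"lw": 2.0, "zorder": 3} if par in highlight else {"lw": 0.8, "alpha": 0.7}
            ax.plot(result.times, result.prcc[:, j, b], label=par, **kwargs)
        ax.set_xlabel("time")
        ax.set_ylabel("PRCC")
        ax.set_ylim(-1.05, 1.05)
        ax.set_title(f"PRCC over time — {var} (n={result.n_effective})")
        ax.legend(fontsize=6, ncol=2, loc="center left", bbox_to_anchor=(1.0, 0.5))
        fig.tight_layout()
        for fmt in formats:
            p = directory / f"prcc_{var}.{fmt}"
            fig.savefig(p, dpi=120)
            paths.append(p)
        plt.close(fig)
    return paths
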