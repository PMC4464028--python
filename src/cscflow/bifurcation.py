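"""Equilibria, stability, one-parameter branch scans, invasion boundary.

Phase 3.3 of the workflow.  For the population model the relevant structure
is a transcritical bifurcation in the symmetric-division probability: the
extinction state E0 (all compartments empty) always exists, and a positive
tumor state E1 crosses it, the two exchanging stability at

    P* = (eta_1 + delta_1) / omega_CSC,

the closed-form *invasion boundary*: below P*, stem-cell loss (first
differentiation plus death) outpaces symmetric self-renewal and the tumor
dies out; above it the tumor grows to a feedback-bounded positive
equilibrium.  The closed form is exact for gamma_PC = 0; with
de-differentiation the extinction threshold at E0 couples to the PC1
compartment and moves slightly below the printed formula, so a warning is
attached and the numerical scan reports the exact crossing.

The scan uses natural continuation on a parameter grid (polish the trivial
branch, track the nontrivial branch from the previous solution) with
bisection refinement of leading-eigenvalue sign changes — sufficient for
one-parameter transcritical structure, without pseudo-arclength machinery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._errors import DomainError
from .models import CSCParameters, ModelDefinition

__all__ = ["EquilibriumResult", "Stability", "BranchPoint", "BifurcationDiagram",
           "find_equilibrium", "classify_stability", "scan_parameter",
           "invasion_threshold"]

log = logging.getLogger(__name__)

STABILITY_TOL = 1e-9  # |max Re(lambda)| below this is labeled marginal
ROOT_TOL = 1e-10


@dataclass
class EquilibriumResult:
    state: np.ndarray | None
    converged: bool
    residual: float
    iterations: int = 0


@dataclass(frozen=True)
class Stability:
    max_real_eigenvalue: float
    stable: bool
    marginal: bool


@dataclass
class BranchPoint:
    parameter_value: float
    state: np.ndarray
    max_real_eigenvalue: float
    stable: bool
    marginal: bool


@dataclass
class TranscriticalPoint:
    parameter_value: float
    exchanging_branches: tuple[str, str]
    stability_swap_verified: bool


@dataclass
class BifurcationDiagram:
    parameter: str
    grid: np.ndarray
    branches: dict[str, list[BranchPoint]]
    transcritical_points: list[TranscriticalPoint] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for branch_id, points in self.branches.items():
            for pt in points:
                rec = {"parameter_value": pt.parameter_value, "branch": branch_id,
                       "max_real_eigenvalue": pt.max_real_eigenvalue,
                       "stable": pt.stable, "marginal": pt.marginal}
                rec.update({f"state_{i}": s for i, s in enumerate(pt.state)})
                records.append(rec)
        return pd.DataFrame.from_records(records)

    def save(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def plot(self, path, state_index: int = 0, state_label: str | None = None) -> Path:
        """Branch plot: solid = stable, dashed = unstable, dotted = marginal."""
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        colors = {"E0": "tab:gray", "E1": "tab:red"}
        for branch_id, points in self.branches.items():
            p = np.array([pt.parameter_value for pt in points])
            y = np.array([pt.state[state_index] for pt in points])
            stable = np.array([pt.stable for pt in points])
            marginal = np.array([pt.marginal for pt in points])
            color = colors.get(branch_id)
            for mask, style, tag in ((stable, "-", "stable"),
                                     (~stable & ~marginal, "--", "unstable"),
                                     (marginal, ":", "marginal")):
                if mask.any():
                    ax.plot(np.where(mask, p, np.nan), np.where(mask, y, np.nan),
                            style, color=color, label=f"{branch_id} {tag}")
        for tp in self.transcritical_points:
            ax.axvline(tp.parameter_value, color="k", lw=0.8, alpha=0.5)
        ax.set_xlabel(self.parameter)
        ax.set_ylabel(state_label or f"state[{state_index}]")
        ax.set_title(f"Branches vs {self.parameter}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = Path(path)
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path


def find_equilibrium(
    model: ModelDefinition,
    params: np.ndarray,
    guess: np.ndarray,
    tol: float = ROOT_TOL,
    max_iter: int = 60,
) -> EquilibriumResult:
    """Damped Newton root of the right-hand side from a starting guess.

    Non-convergence is reported as a not-found result, not an exception,
    so branch scans can log a gap and continue.
    """
    y = np.asarray(guess, dtype=float).copy()
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(y)):
        raise DomainError("equilibrium guess must be finite")
    scale = max(1.0, float(np.max(np.abs(y))))
    for it in range(1, max_iter + 1):
        f = np.asarray(model.rhs(y, params, 0.0), dtype=float)
        res = float(np.linalg.norm(f))
        if res <= tol * scale:
            return EquilibriumResult(state=y, converged=True, residual=res, iterations=it)
        jac = model.jacobian_or_fd(y, params)
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(jac, -f, rcond=None)
        if not np.all(np.isfinite(step)) or np.linalg.norm(step) < 1e-14 * scale:
            # singular Jacobian with zero least-squares step (a saddle of
            # the residual norm): nudge off the degenerate point instead
            step = np.full_like(y, 1e-3 * scale)
        # damped update: halve until the residual strictly decreases
        lam = 1.0
        for _ in range(40):
            y_new = y + lam * step
            f_new = np.asarray(model.rhs(y_new, params, 0.0), dtype=float)
            if np.all(np.isfinite(f_new)) and np.linalg.norm(f_new) < res:
                break
            lam *= 0.5
        else:
            return EquilibriumResult(state=None, converged=False, residual=res, iterations=it)
        y = y + lam * step
        scale = max(1.0, float(np.max(np.abs(y))))
    f = np.asarray(model.rhs(y, params, 0.0), dtype=float)
    res = float(np.linalg.norm(f))
    if res <= tol * scale:
        return EquilibriumResult(state=y, converged=True, residual=res, iterations=max_iter)
    return EquilibriumResult(state=None, converged=False, residual=res, iterations=max_iter)


def classify_stability(
    model: ModelDefinition,
    equilibrium: np.ndarray,
    params: np.ndarray,
    tol_stab: float = STABILITY_TOL,
) -> Stability:
    """Leading Jacobian eigenvalue at an equilibrium and its stability flag.

    Stable means every real part is below ``-tol_stab``; a leading real
    part within ``+-tol_stab`` of zero is labeled marginal rather than
    forced into either class.
    """
    jac = model.jacobian_or_fd(np.asarray(equilibrium, float), np.asarray(params, float))
    try:
        eig = np.linalg.eigvals(jac)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"eigendecomposition failed for Jacobian {jac!r}") from exc
    max_re = float(np.max(eig.real))
    return Stability(
        max_real_eigenvalue=max_re,
        stable=max_re < -tol_stab,
        marginal=abs(max_re) <= tol_stab,
    )


def _with_param(model: ModelDefinition, params: np.ndarray, name: str, value: float) -> np.ndarray:
    if name not in model.parameter_names:
        raise DomainError(f"{name!r} is not a parameter of model {model.name!r}")
    p = np.asarray(params, dtype=float).copy()
    p[model.parameter_names.index(name)] = value
    return p


def _transient_seed(
    model: ModelDefinition, params: np.ndarray, t_transient: float | None
) -> np.ndarray:
    """Long-time simulation from the default initial state, as a branch seed."""
    if t_transient is None:
        # for rate-based models: ten times the slowest decay scale present
        positive = [p for p in params if p > 0]
        slowest = min(positive) if positive else 1.0
        t_transient = min(10.0 / slowest, 1e4)
    y = model.default_initial_state.astype(float)
    if np.all(y == 0):
        y = y + 1e-3
    # integrate in chunks until near-stationary, so the Newton polish starts
    # inside the target equilibrium's basin even when convergence is slow
    for _ in range(64):
        sol = solve_ivp(
            lambda t, yy: model.rhs(yy, params, t),
            (0.0, t_transient), y, method="LSODA", rtol=1e-8, atol=1e-10,
            jac=(lambda t, yy: model.jacobian(yy, params)) if model.jacobian else None,
        )
        if not sol.success:
            break
        y = sol.y[:, -1]
        f = np.asarray(model.rhs(y, params, 0.0), dtype=float)
        if np.linalg.norm(f) <= 1e-9 * max(1.0, float(np.linalg.norm(y))):
            break
    return y


def _leading_eig_at_zero_branch(
    model: ModelDefinition, params: np.ndarray, name: str, value: float,
    guess: np.ndarray,
) -> tuple[float, np.ndarray] | None:
    p = _with_param(model, params, name, value)
    eq = find_equilibrium(model, p, guess)
    if not eq.converged:
        return None
    return classify_stability(model, eq.state, p).max_real_eigenvalue, eq.state


def scan_parameter(
    model: ModelDefinition,
    params: np.ndarray | CSCParameters,
    name: str,
    prange: tuple[float, float],
    n_points: int = 101,
    seed_guesses: list[np.ndarray] | None = None,
    t_transient: float | None = None,
    refine_tol: float = 1e-6,
) -> BifurcationDiagram:
    """Natural continuation of equilibrium branches along one parameter.

    At each grid value the trivial branch is polished from the zero state
    and every nontrivial branch is tracked from the previous grid point
    (the first point is seeded by a long transient simulation, or by the
    caller's ``seed_guesses``).  Sign changes of the trivial branch's
    leading eigenvalue are refined by bisection to ``refine_tol`` in the
    parameter and reported as transcritical candidates, with the
    stability swap of the two branches checked across the crossing.
    """
    if isinstance(params, CSCParameters):
        params = params.to_array()
    params = np.asarray(params, dtype=float)
    lo, hi = float(prange[0]), float(prange[1])
    if not lo < hi:
        raise DomainError(f"parameter range must satisfy lo < hi, got {prange}")
    if n_points < 3:
        raise DomainError("scan needs at least 3 grid points")
    grid = np.linspace(lo, hi, n_points)

    branches: dict[str, list[BranchPoint]] = {}

    def track(branch_id: str, first_guess: np.ndarray, values: np.ndarray) -> list[BranchPoint]:
        # natural continuation with a secant predictor, so the branch is
        # followed through a transcritical crossing onto its unstable side
        # instead of collapsing onto the branch it intersects
        points: list[BranchPoint] = []
        prev: np.ndarray | None = None
        last: np.ndarray = np.asarray(first_guess, dtype=float)
        for value in values:
            p = _with_param(model, params, name, value)
            guess = last if prev is None else 2.0 * last - prev
            eq = find_equilibrium(model, p, guess)
            if not eq.converged:
                eq = find_equilibrium(model, p, last)
            if not eq.converged:
                log.warning("branch %s lost at %s=%g; leaving a gap", branch_id, name, value)
                continue
            stab = classify_stability(model, eq.state, p)
            points.append(BranchPoint(
                parameter_value=float(value), state=eq.state,
                max_real_eigenvalue=stab.max_real_eigenvalue,
                stable=stab.stable, marginal=stab.marginal,
            ))
            prev, last = last, eq.state
        return points

    branches["E0"] = track("E0", np.zeros(model.n_states), grid)
    if seed_guesses is None:
        # seed the nontrivial branch where it is the attractor: just above
        # the trivial branch's destabilization if there is one (near its
        # birth the new branch is stable, while far from the crossing it may
        # have lost stability again, e.g. through a Hopf point, leaving a
        # transient stuck on a limit cycle), else at the top of the range
        e0_lead = [pt.max_real_eigenvalue for pt in branches["E0"]]
        unstable = [i for i, lam in enumerate(e0_lead) if lam > 0.0]
        seed_idx = min(unstable[0] + 2, n_points - 1) if unstable else n_points - 1
        p_seed = grid[seed_idx]
        seed = _transient_seed(model, _with_param(model, params, name, p_seed), t_transient)
        down = track("E1", seed, grid[: seed_idx + 1][::-1])[::-1]
        up = track("E1", seed, grid[seed_idx + 1:])
        branches["E1"] = down + up
    else:
        for b, g in enumerate(seed_guesses, start=1):
            branches[f"E{b}"] = track(f"E{b}", np.asarray(g, dtype=float), grid)

    diagram = BifurcationDiagram(parameter=name, grid=grid, branches=branches)

    # transcritical detection on the trivial branch's leading eigenvalue
    e0 = branches.get("E0", [])
    for a, b in zip(e0[:-1], e0[1:]):
        la, lb = a.max_real_eigenvalue, b.max_real_eigenvalue
        if la == 0.0 or la * lb >= 0.0:
            continue
        p_lo, p_hi, l_lo = a.parameter_value, b.parameter_value, la
        guess = a.state
        while p_hi - p_lo > refine_tol:
            mid = 0.5 * (p_lo + p_hi)
            res = _leading_eig_at_zero_branch(model, params, name, mid, guess)
            if res is None:
                break
            l_mid, state_mid = res
            guess = state_mid
            if l_lo * l_mid <= 0.0:
                p_hi = mid
            else:
                p_lo, l_lo = mid, l_mid
        crossing = 0.5 * (p_lo + p_hi)
        swap = _verify_swap(diagram, crossing)
        diagram.transcritical_points.append(TranscriticalPoint(
            parameter_value=crossing,
            exchanging_branches=("E0", "E1"),
            stability_swap_verified=swap,
        ))
    return diagram


def _verify_swap(diagram: BifurcationDiagram, crossing: float) -> bool:
    """Check that the two branches exchange stability across the crossing.

    The trivial branch must flip; the nontrivial branch must carry the
    opposite flag on each side where it is numerically distinct from the
    trivial one (near the crossing — and, for branches that turn virtual,
    on a whole side — continuation can collapse onto the trivial state, so
    coincident points are not evidence either way).
    """
    e0 = {round(p.parameter_value, 12): p for p in diagram.branches.get("E0", [])}

    def e0_flag(side: str) -> bool | None:
        pts = [p for p in diagram.branches.get("E0", [])
               if (p.parameter_value < crossing) == (side == "below") and not p.marginal]
        if not pts:
            return None
        return pts[-1].stable if side == "below" else pts[0].stable

    def e1_distinct_flag(side: str) -> bool | None:
        pts = []
        for p in diagram.branches.get("E1", []):
            if (p.parameter_value < crossing) != (side == "below") or p.marginal:
                continue
            ref = e0.get(round(p.parameter_value, 12))
            scale = max(1.0, float(np.max(np.abs(p.state))))
            if ref is None or np.linalg.norm(p.state - ref.state) > 1e-6 * scale:
                pts.append(p)
        if not pts:
            return None
        return pts[-1].stable if side == "below" else pts[0].stable

    e0_below, e0_above = e0_flag("below"), e0_flag("above")
    if e0_below is None or e0_above is None or e0_below == e0_above:
        return False
    e1_below, e1_above = e1_distinct_flag("below"), e1_distinct_flag("above")
    if e1_below is None and e1_above is None:
        return False
    ok = True
    if e1_above is not None:
        ok &= e1_above == e0_below  # nontrivial branch takes over as attractor
    if e1_below is not None:
        ok &= e1_below == e0_above
    return ok


def invasion_threshold(params: CSCParameters) -> float:
    """Closed-form invasion boundary ``P* = (eta_1 + delta_1) / omega_CSC``.

    Exact extinction threshold of the trivial state for ``gamma_PC = 0``;
    with de-differentiation active the true threshold shifts slightly (the
    stem and first progenitor compartments couple at the origin), so a
    warning is attached and the numerical scan should be consulted for the
    exact crossing.
    """
    if params.omega_CSC == 0:
        raise DomainError("invasion threshold undefined for omega_CSC = 0")
    if params.gamma_PC > 0:
        warnings.warn(
            "gamma_PC > 0: the closed-form threshold neglects de-differentiation; "
            "the numerically exact crossing differs slightly",
            stacklevel=2,
        )
    return (params.eta_1 + params.delta_1) / params.omega_CSC
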