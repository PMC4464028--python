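"""ODE model contracts, the cancer-stem-cell population model, and test fixtures.

The central object is :class:`ModelDefinition`, a small model-agnostic
contract (state names, parameter names, right-hand side, optional analytic
Jacobian) that the sampling / simulation / sensitivity machinery operates
on.  The built-in tumor-growth model describes a hierarchically organised
cancer-cell population with five compartments:

* ``N_CSC``  cancer stem cells — self-renewing apex of the hierarchy,
* ``N_PC1``, ``N_PC2`` two progenitor levels of decreasing potency,
* ``N_TC``   terminal, non-proliferating cells forming the tumor bulk,
* ``N_DC``   dead cells, cleared by lysis.

A CSC divides symmetrically (two CSCs) with probability ``P_sy`` and
asymmetrically otherwise; progenitors amplify the lineage and feed the
terminal compartment; every death flux accumulates in the dead-cell pool.
The terminal-cell mass feeds back on both proliferation rates through

    omega -> omega / (1 + h * N_TC)

which bounds growth and makes the system nonlinear: the microenvironment
(represented by the tumor bulk) throttles division as the tumor grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dataclass_fields
from typing import Callable, Mapping

import numpy as np

from ._errors import ContractError, DomainError, UnknownModelError

__all__ = [
    "CSCParameters",
    "CSCState",
    "ModelDefinition",
    "effective_rate",
    "csc_rhs",
    "csc_jacobian",
    "csc_model",
    "fixture_model",
    "get_model",
    "register_model",
    "available_models",
]


# --------------------------------------------------------------------------
# parameter / state containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CSCParameters:
    """The 13 phenotypic rates of the population model.

    Units: probabilities are dimensionless, rates are 1/time, feedback
    intensities are 1/cells.  Defaults are the shipped baselines — a
    documented package choice, not ground truth from the original study
    (whose baseline table is not reproduced in the paper body).  They are
    constructed to satisfy every stated constraint, in particular
    ``(eta_1 + delta_1) / omega_CSC == 0.025`` so that the closed-form
    invasion boundary sits at the published threshold.
    """

    P_sy: float = 0.5          # probability of symmetric CSC division
    omega_CSC: float = 1.0     # CSC proliferation rate
    omega_PC: float = 0.4      # PC1 proliferation rate
    eta_1: float = 0.015       # CSC differentiation rate
    eta_2: float = 0.05        # PC1 differentiation rate
    eta_3: float = 0.1         # PC2 differentiation rate
    gamma_PC: float = 0.005    # PC1 de-differentiation rate
    delta_1: float = 0.01      # CSC death rate
    delta_2: float = 0.01      # PC death rate (both levels)
    delta_3: float = 0.1       # TC death rate
    delta_4: float = 0.3       # DC lysis rate
    h_CSC: float = 1.0e-3      # feedback intensity on omega_CSC
    h_PC: float = 1.0e-3       # feedback intensity on omega_PC

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise DomainError(f"parameter {f.name} must be finite and >= 0, got {v!r}")
        if not 0.0 <= self.P_sy <= 1.0:
            raise DomainError(f"P_sy must lie in [0, 1], got {self.P_sy!r}")

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in dataclass_fields(cls)]

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names()], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "CSCParameters":
        values = np.asarray(values, dtype=float)
        names = cls.names()
        if values.shape != (len(names),):
            raise ContractError(
                f"expected {len(names)} parameters in order {names}, got shape {values.shape}"
            )
        return cls(**dict(zip(names, values)))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "CSCParameters":
        unknown = set(mapping) - set(cls.names())
        if unknown:
            raise ContractError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**dict(mapping))


@dataclass(frozen=True)
class CSCState:
    """Subpopulation sizes (cells, real-valued)."""

    N_CSC: float
    N_PC1: float
    N_PC2: float
    N_TC: float
    N_DC: float

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise DomainError(f"state component {f.name} must be finite and >= 0, got {v!r}")

    @property
    def N_PC(self) -> float:
        """Total progenitor count, the sum of the two PC levels."""
        return self.N_PC1 + self.N_PC2

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in dataclass_fields(cls)]

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names()], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "CSCState":
        values = np.asarray(values, dtype=float)
        if values.shape != (5,):
            raise ContractError(f"expected a length-5 state vector, got shape {values.shape}")
        return cls(*values)


@dataclass(frozen=True)
class ModelDefinition:
    """Generic autonomous ODE model contract.

    ``rhs(y, p, t)`` maps (state vector, parameter vector, time) to the
    derivative vector; ``jacobian(y, p)``, when given, returns the square
    matrix of state partials.  When absent, consumers fall back to central
    finite differences.
    """

    name: str
    state_names: tuple[str, ...]
    parameter_names: tuple[str, ...]
    rhs: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    default_parameters: np.ndarray
    default_initial_state: np.ndarray
    jacobian: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_names", tuple(self.state_names))
        object.__setattr__(self, "parameter_names", tuple(self.parameter_names))
        object.__setattr__(
            self, "default_parameters", np.asarray(self.default_parameters, dtype=float)
        )
        object.__setattr__(
            self, "default_initial_state", np.asarray(self.default_initial_state, dtype=float)
        )
        if self.default_parameters.shape != (len(self.parameter_names),):
            raise ContractError("default_parameters length does not match parameter_names")
        if self.default_initial_state.shape != (len(self.state_names),):
            raise ContractError("default_initial_state length does not match state_names")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def check_vectors(self, y: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        y = np.asarray(y, dtype=float)
        p = np.asarray(p, dtype=float)
        if y.shape != (self.n_states,):
            raise ContractError(
                f"model {self.name!r} expects a state vector of length {self.n_states}, "
                f"got shape {y.shape}"
            )
        if p.shape != (self.n_parameters,):
            raise ContractError(
                f"model {self.name!r} expects {self.n_parameters} parameters "
                f"({', '.join(self.parameter_names)}), got shape {p.shape}"
            )
        return y, p

    def parameter_vector(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        """Default parameter vector with named overrides applied."""
        p = self.default_parameters.copy()
        if overrides:
            index = {n: i for i, n in enumerate(self.parameter_names)}
            unknown = set(overrides) - set(index)
            if unknown:
                raise ContractError(
                    f"unknown parameter(s) for model {self.name!r}: {sorted(unknown)}"
                )
            for name, value in overrides.items():
                p[index[name]] = value
        return p

    def jacobian_or_fd(self, y: np.ndarray, p: np.ndarray, step: float = 1e-6) -> np.ndarray:
        if self.jacobian is not None:
            return np.asarray(self.jacobian(y, p), dtype=float)
        return finite_difference_jacobian(self.rhs, y, p, step=step)


def finite_difference_jacobian(
    rhs: Callable[[np.ndarray, np.ndarray, float], np.ndarray],
    y: np.ndarray,
    p: np.ndarray,
    step: float = 1e-6,
) -> np.ndarray:
    """Central-difference Jacobian of ``rhs`` with respect to the state."""
    y = np.asarray(y, dtype=float)
    n = y.size
    jac = np.empty((n, n))
    for j in range(n):
        h = step * max(1.0, abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        jac[:, j] = (np.asarray(rhs(yp, p, 0.0)) - np.asarray(rhs(ym, p, 0.0))) / (2 * h)
    return jac


# --------------------------------------------------------------------------
# the population model
# --------------------------------------------------------------------------

def effective_rate(omega: float, h: float, N_TC: float) -> float:
    """Feedback-limited proliferation rate ``omega / (1 + h * N_TC)``.

    The terminal-cell mass depresses the division rate; ``h`` sets the
    strength of this microenvironmental feedback (units 1/cells).  With
    ``h == 0`` the rate is unregulated.
    """
    if omega < 0 or h < 0 or N_TC < 0:
        raise DomainError(
            f"effective_rate requires omega, h, N_TC >= 0; got {(omega, h, N_TC)!r}"
        )
    return omega / (1.0 + h * N_TC)


_CSC_STATE_NAMES = tuple(CSCState.names())
_CSC_PARAM_NAMES = tuple(CSCParameters.names())

# Shipped default initial condition: 1e5 cells total, terminal cells the
# largest subpopulation and stem cells the smallest, mirroring a
# subcutaneous-injection protocol of a heterogeneous tumor-cell mix.
DEFAULT_INITIAL_STATE = np.array([100.0, 2000.0, 7900.0, 80000.0, 10000.0])


def _as_param_array(params: CSCParameters | np.ndarray) -> np.ndarray:
    if isinstance(params, CSCParameters):
        return params.to_array()
    p = np.asarray(params, dtype=float)
    if p.shape != (13,):
        raise ContractError(f"expected 13 parameters in order {_CSC_PARAM_NAMES}, got {p.shape}")
    return p


def _as_state_array(state: CSCState | np.ndarray) -> np.ndarray:
    if isinstance(state, CSCState):
        return state.to_array()
    y = np.asarray(state, dtype=float)
    if y.shape != (5,):
        raise ContractError(f"expected a length-5 state vector, got shape {y.shape}")
    return y


def csc_rhs(
    state: CSCState | np.ndarray,
    params: CSCParameters | np.ndarray,
    t: float = 0.0,
) -> np.ndarray:
    """Right-hand side of the five-compartment population model.

    The system is autonomous; ``t`` is accepted only for solver
    compatibility.  State order: (N_CSC, N_PC1, N_PC2, N_TC, N_DC).
    """
    y = _as_state_array(state)
    p = _as_param_array(params)
    (P_sy, omega_CSC, omega_PC, eta_1, eta_2, eta_3, gamma_PC,
     delta_1, delta_2, delta_3, delta_4, h_CSC, h_PC) = p
    C, P1, P2, T, D = y

    W_C = omega_CSC / (1.0 + h_CSC * T)
    W_P = omega_PC / (1.0 + h_PC * T)

    dC = P_sy * W_C * C + gamma_PC * P1 - eta_1 * C - delta_1 * C
    dP1 = ((1.0 - P_sy) * W_C * C - W_P * P1 - gamma_PC * P1
           + eta_1 * C - eta_2 * P1 - delta_2 * P1)
    dP2 = 2.0 * W_P * P1 + eta_2 * P1 - eta_3 * P2 - delta_2 * P2
    dT = eta_3 * P2 - delta_3 * T
    dD = delta_1 * C + delta_2 * (P1 + P2) + delta_3 * T - delta_4 * D
    return np.array([dC, dP1, dP2, dT, dD])


def csc_jacobian(
    state: CSCState | np.ndarray,
    params: CSCParameters | np.ndarray,
) -> np.ndarray:
    """Analytic 5x5 Jacobian of :func:`csc_rhs`, feedback terms included."""
    y = _as_state_array(state)
    p = _as_param_array(params)
    (P_sy, omega_CSC, omega_PC, eta_1, eta_2, eta_3, gamma_PC,
     delta_1, delta_2, delta_3, delta_4, h_CSC, h_PC) = p
    C, P1, P2, T, D = y

    denom_C = 1.0 + h_CSC * T
    denom_P = 1.0 + h_PC * T
    W_C = omega_CSC / denom_C
    W_P = omega_PC / denom_P
    # d/dT of the feedback-limited rates
    dWC_dT = -omega_CSC * h_CSC / denom_C**2
    dWP_dT = -omega_PC * h_PC / denom_P**2

    jac = np.zeros((5, 5))
    # dN_CSC/dt
    jac[0, 0] = P_sy * W_C - eta_1 - delta_1
    jac[0, 1] = gamma_PC
    jac[0, 3] = P_sy * C * dWC_dT
    # dN_PC1/dt
    jac[1, 0] = (1.0 - P_sy) * W_C + eta_1
    jac[1, 1] = -W_P - gamma_PC - eta_2 - delta_2
    jac[1, 3] = (1.0 - P_sy) * C * dWC_dT - P1 * dWP_dT
    # dN_PC2/dt
    jac[2, 1] = 2.0 * W_P + eta_2
    jac[2, 2] = -eta_3 - delta_2
    jac[2, 3] = 2.0 * P1 * dWP_dT
    # dN_TC/dt
    jac[3, 2] = eta_3
    jac[3, 3] = -delta_3
    # dN_DC/dt
    jac[4, 0] = delta_1
    jac[4, 1] = delta_2
    jac[4, 2] = delta_2
    jac[4, 3] = delta_3
    jac[4, 4] = -delta_4
    return jac


def csc_model(
    parameters: CSCParameters | None = None,
    initial_state: np.ndarray | None = None,
) -> ModelDefinition:
    """The population model packaged as a :class:`ModelDefinition`."""
    params = parameters if parameters is not None else CSCParameters()
    y0 = DEFAULT_INITIAL_STATE if initial_state is None else np.asarray(initial_state, float)
    return ModelDefinition(
        name="csc",
        state_names=_CSC_STATE_NAMES,
        parameter_names=_CSC_PARAM_NAMES,
        rhs=lambda y, p, t: csc_rhs(y, p, t),
        jacobian=lambda y, p: csc_jacobian(y, p),
        default_parameters=params.to_array(),
        default_initial_state=y0,
    )


# --------------------------------------------------------------------------
# fixture models
# --------------------------------------------------------------------------

def _logistic_model() -> ModelDefinition:
    # dN/dt = r N (1 - N/K); closed form available, used as an oracle
    def rhs(y, p, t):
        r, K = p
        return np.array([r * y[0] * (1.0 - y[0] / K)])

    def jac(y, p):
        r, K = p
        return np.array([[r * (1.0 - 2.0 * y[0] / K)]])

    return ModelDefinition(
        name="logistic",
        state_names=("N",),
        parameter_names=("r", "K"),
        rhs=rhs,
        jacobian=jac,
        default_parameters=np.array([1.0, 100.0]),
        default_initial_state=np.array([1.0]),
    )


def _monotone_linear_model(weights: tuple[float, ...] = (1.0, 0.1, 0.0)) -> ModelDefinition:
    """Static linear response y(t) = t * sum_j a_j x_j.

    The sampled parameters x_j enter a constant derivative, so at any t > 0
    the single output is an exact linear (hence monotone) function of the
    combination — a clean fixture for the rank-statistics path, with the
    shared zero initial state exercising the degenerate t = 0 case.
    """
    a = np.asarray(weights, dtype=float)

    def rhs(y, p, t):
        return np.array([float(a @ p)])

    def jac(y, p):
        return np.zeros((1, 1))

    return ModelDefinition(
        name="monotone_linear",
        state_names=("y",),
        parameter_names=tuple(f"x_{j + 1}" for j in range(a.size)),
        rhs=rhs,
        jacobian=jac,
        default_parameters=np.ones(a.size),
        default_initial_state=np.zeros(1),
    )


def _bistable_toy_model() -> ModelDefinition:
    # dx/dt = x (p - x)(x - 1): equilibria {0, p, 1}; for 0 < p < 1 the
    # outer equilibria are stable and x = p is unstable.
    def rhs(y, p, t):
        x = y[0]
        return np.array([x * (p[0] - x) * (x - 1.0)])

    def jac(y, p):
        x = y[0]
        return np.array([[(p[0] - x) * (x - 1.0) + x * (-(x - 1.0)) + x * (p[0] - x)]])

    return ModelDefinition(
        name="bistable_toy",
        state_names=("x",),
        parameter_names=("p",),
        rhs=rhs,
        jacobian=jac,
        default_parameters=np.array([0.5]),
        default_initial_state=np.array([1.2]),
    )


_FIXTURES: dict[str, Callable[..., ModelDefinition]] = {
    "logistic": _logistic_model,
    "monotone_linear": _monotone_linear_model,
    "bistable_toy": _bistable_toy_model,
}


def fixture_model(name: str, **kwargs) -> ModelDefinition:
    """Return one of the small built-in validation models by name."""
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise UnknownModelError(
            f"unknown fixture model {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return factory(**kwargs)


# --------------------------------------------------------------------------
# model registry (config / CLI entry point)
# --------------------------------------------------------------------------

_REGISTRY: dict[str, Callable[[], ModelDefinition]] = {
    "csc": csc_model,
    **_FIXTURES,
}


def register_model(name: str, factory: Callable[[], ModelDefinition]) -> None:
    """Register a user model so configs and the CLI can address it by name."""
    _REGISTRY[name] = factory


def available_models() -> list[str]:
    return sorted(_REGISTRY)


def get_model(name: str) -> ModelDefinition:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise UnknownModelError(
            f"unknown model {name!r}; available: {available_models()}"
        ) from None
    return factory()
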