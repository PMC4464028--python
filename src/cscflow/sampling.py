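"""Latin hypercube designs over named parameter intervals.

Phase 1.1 of the workflow: each parameter gets a sampling interval (a
baseline plus-or-minus a variation percentage, or explicit bounds) and a
distribution; the design stratifies each column into ``n``
equal-probability subintervals sampled exactly once, with columns permuted
independently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DegenerateSpecError, DomainError, FormatError

__all__ = ["ParameterSpec", "SampleDesign", "resolve_interval", "lhs_sample",
           "write_design", "read_design"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterSpec:
    """Sampling specification for one parameter.

    Either ``variation_pct`` (interval ``baseline * (1 -+ v/100)``) or
    explicit ``bounds`` must be given.  ``distribution`` is ``"uniform"``
    or ``"normal"``; a normal spec takes its standard deviation from ``sd``
    or, failing that, ``baseline * variation_pct / 100``.  Normal samples
    are truncated only when explicit bounds are supplied.  ``nonnegative``
    clips a negative resolved lower bound at zero (logged), for rate
    parameters that cannot go below zero.
    """

    name: str
    baseline: float | None = None
    distribution: str = "uniform"
    variation_pct: float | None = None
    bounds: tuple[float, float] | None = None
    sd: float | None = None
    nonnegative: bool = False

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "normal"):
            raise DomainError(
                f"{self.name}: distribution must be 'uniform' or 'normal', "
                f"got {self.distribution!r}"
            )
        if self.variation_pct is not None and self.variation_pct < 0:
            raise DomainError(f"{self.name}: variation_pct must be >= 0")
        if self.variation_pct is None and self.bounds is None and not (
            self.distribution == "normal" and self.sd is not None
        ):
            raise DomainError(
                f"{self.name}: either variation_pct (with baseline) or bounds is required"
            )
        if self.variation_pct is not None and self.bounds is None and self.baseline is None:
            raise DomainError(f"{self.name}: variation_pct requires a baseline")

    def normal_sd(self) -> float:
        if self.sd is not None:
            return float(self.sd)
        if self.variation_pct is not None and self.baseline is not None:
            return abs(self.baseline) * self.variation_pct / 100.0
        raise DomainError(f"{self.name}: normal distribution requires sd or variation_pct")


def resolve_interval(spec: ParameterSpec) -> tuple[float, float]:
    """Resolve a spec to its (min, max) sampling interval.

    Explicit bounds pass through unchanged; a variation percentage ``v``
    gives ``baseline * (1 - v/100), baseline * (1 + v/100)``.  A flagged
    non-negative parameter has a negative lower bound clipped at zero.
    """
    if spec.bounds is not None:
        lo, hi = float(spec.bounds[0]), float(spec.bounds[1])
        if lo >= hi:
            raise DomainError(f"{spec.name}: explicit bounds must satisfy min < max, got {(lo, hi)}")
    elif spec.variation_pct is None:
        raise DomainError(
            f"{spec.name}: an untruncated normal spec has no finite interval; "
            "partition by the sampled range instead"
        )
    else:
        if not np.isfinite(spec.baseline):
            raise DomainError(f"{spec.name}: baseline must be finite")
        v = spec.variation_pct / 100.0
        lo = spec.baseline * (1.0 - v)
        hi = spec.baseline * (1.0 + v)
        if lo > hi:  # negative baseline flips the endpoints
            lo, hi = hi, lo
    if spec.nonnegative and lo < 0.0:
        log.info("%s: clipping negative lower bound %g to 0", spec.name, lo)
        lo = 0.0
    if lo == hi:
        raise DegenerateSpecError(
            f"{spec.name}: interval is zero-width at {lo}; widen variation_pct or bounds"
        )
    if spec.bounds is None and not lo <= spec.baseline <= hi:
        raise DomainError(f"{spec.name}: baseline {spec.baseline} outside resolved interval")
    return lo, hi


@dataclass
class SampleDesign:
    """An n x k Latin hypercube design with named columns."""

    specs: list[ParameterSpec]
    n: int
    seed: int
    matrix: pd.DataFrame

    @property
    def k(self) -> int:
        return len(self.specs)

    @property
    def parameter_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[name].to_numpy()


def _column_sample(spec: ParameterSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """One LHS column: one draw per equal-probability stratum, permuted."""
    strata = rng.permutation(n)
    q = (strata + rng.random(n)) / n  # uniform position inside each stratum
    if spec.distribution == "uniform":
        lo, hi = resolve_interval(spec)
        return lo + q * (hi - lo)
    # normal: strata of equal probability mass via the inverse CDF
    mean = spec.baseline if spec.baseline is not None else 0.0
    sd = spec.normal_sd()
    if sd <= 0:
        raise DegenerateSpecError(f"{spec.name}: normal sd must be > 0, got {sd}")
    if spec.bounds is not None:
        lo, hi = resolve_interval(spec)
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.ppf(q, a, b, loc=mean, scale=sd)
    return stats.norm.ppf(q, loc=mean, scale=sd)


def lhs_sample(specs: list[ParameterSpec], n: int, seed: int) -> SampleDesign:
    """Generate an n x k Latin hypercube design.

    Each column occupies its n equal-probability strata exactly once, with
    independent stratum permutations per column.  One master seed spawns
    per-column substreams, so adding a parameter leaves the draws of the
    other columns unchanged.
    """
    if n < 2:
        raise DomainError(f"sample size n must be >= 2, got {n}")
    k = len(specs)
    if k == 0:
        raise DomainError("at least one ParameterSpec is required")
    names = [s.name for s in specs]
    if len(set(names)) != k:
        raise DomainError(f"duplicate parameter names in specs: {names}")
    if n <= k + 1:
        warnings.warn(
            f"sample size n={n} should exceed k+1={k + 1} for a well-posed "
            "rank-regression analysis",
            stacklevel=2,
        )
    streams = np.random.SeedSequence(seed).spawn(k)
    columns = {
        spec.name: _column_sample(spec, n, np.random.default_rng(stream))
        for spec, stream in zip(specs, streams)
    }
    matrix = pd.DataFrame(columns, columns=names)
    return SampleDesign(specs=list(specs), n=n, seed=seed, matrix=matrix)


def write_design(design: SampleDesign, path) -> None:
    """Write the design as CSV (header = parameter names, full precision)."""
    if design.n == 0 or design.matrix.shape[0] == 0:
        raise DomainError("cannot write an empty design (n = 0 rows)")
    design.matrix.to_csv(path, index=False, float_format="%.17g")


def read_design(path, specs: list[ParameterSpec]) -> SampleDesign:
    """Read a design CSV back; columns must match the specs exactly."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"could not parse design file {path}: {exc}") from exc
    expected = [s.name for s in specs]
    missing = [c for c in expected if c not in frame.columns]
    extra = [c for c in frame.columns if c not in expected]
    if missing or extra:
        raise FormatError(
            f"design file {path} does not match specs: missing columns {missing}, "
            f"unexpected columns {extra}"
        )
    if frame.shape[0] == 0:
        raise DomainError(f"design file {path} has no sample rows")
    for col in expected:
        bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
        if len(bad):
            raise FormatError(
                f"design file {path}: non-numeric value in column {col!r} at row {bad[0]}"
            )
    frame = frame[expected].astype(float)
    return SampleDesign(specs=list(specs), n=frame.shape[0], seed=-1, matrix=frame)
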