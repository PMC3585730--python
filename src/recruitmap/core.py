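"""Deterministic cohort model for recruitment of sessile organisms.

The model tracks a single closed cohort (no immigration after settlement)
through discrete time steps.  At each step a fraction lambda of individuals
survives, where lambda depends on *resource use* — the product of density
``N_t`` and mean individual body size ``phi_t``.  Body size follows
Ford–Walford (discrete von Bertalanffy) growth toward an asymptote, so
resource use can increase even while density falls.  Iterating the
recursion from a grid of initial densities produces a settler–recruit map
whose shape (monotonic, humped, or multi-humped) diagnoses the strength
and form of density dependence.

Three survival functional forms are supported, each with a
resource-independent survival ``alpha`` (survival at zero resource use)
and a resource-use-dependent mortality parameter ``beta``:

* exponential:  ``lambda = alpha * exp(-beta * u)``
* logistic:     ``lambda = 1 / (1 + alpha' * exp(beta * u))`` with
  ``alpha' = 1/alpha - 1`` so that ``lambda(0) = alpha``
* hyperbolic:   ``lambda = alpha / (1 + beta * u)``

where ``u = N * phi`` is resource use.  Note the sign convention in the
logistic form: some published statements of the model print
``exp(-beta*u)`` inside the logistic denominator, which would make
survival *increase* with crowding, contradicting beta's role as a
mortality parameter.  This module adopts the declining convention by
default and exposes ``logistic_literal_sign`` for the printed variant.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SurvivalForm",
    "MapShape",
    "SurvivalParams",
    "GrowthParams",
    "CohortState",
    "ResourceContext",
    "ResourceCheck",
    "RecruitmentMap",
    "survival_fraction",
    "grow_step",
    "step_cohort",
    "simulate_cohort",
    "resource_violation",
    "recruitment_map",
    "count_local_maxima",
    "classify_map_shape",
    "default_n0_grid",
]


class SurvivalForm(str, enum.Enum):
    """Functional form linking survival to resource use."""

    EXPONENTIAL = "exponential"
    LOGISTIC = "logistic"
    HYPERBOLIC = "hyperbolic"


class MapShape(str, enum.Enum):
    """Qualitative shape class of a settler–recruit curve."""

    MONOTONIC_INCREASING = "monotonic_increasing"
    UNIMODAL = "unimodal"
    MULTIMODAL = "multimodal"


@dataclass(frozen=True)
class SurvivalParams:
    """Parameters of one survival functional form.

    Parameters
    ----------
    form
        One of the three supported functional forms.
    alpha
        Resource-independent survival fraction per base time step,
        ``0 < alpha <= 1``.  All three forms satisfy ``lambda(0) = alpha``.
    beta
        Resource-use-dependent mortality parameter, ``beta >= 0``; units are
        the inverse of the resource-use unit.  ``1/beta`` is proportional to
        the carrying capacity of the system.
    """

    form: SurvivalForm
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", SurvivalForm(self.form))
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must satisfy 0 < alpha <= 1, got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    @property
    def alpha_prime(self) -> float:
        """Logistic auxiliary parameter ``alpha' = 1/alpha - 1`` (>= 0)."""
        return 1.0 / self.alpha - 1.0


@dataclass(frozen=True)
class GrowthParams:
    """Ford–Walford growth: ``phi_{t+1} = phi_t e^{-K} + phi_inf (1 - e^{-K})``."""

    K: float
    phi_inf: float
    phi_0: float

    def __post_init__(self) -> None:
        if self.K < 0.0:
            raise ValueError(f"growth rate K must be >= 0, got {self.K}")
        if not (0.0 < self.phi_0 <= self.phi_inf):
            raise ValueError(
                f"initial size must satisfy 0 < phi_0 <= phi_inf, "
                f"got phi_0={self.phi_0}, phi_inf={self.phi_inf}"
            )


@dataclass(frozen=True)
class CohortState:
    """Snapshot of a cohort: step index ``t``, density ``N``, mean size ``phi``."""

    t: int
    N: float
    phi: float

    def __post_init__(self) -> None:
        if self.N < 0.0:
            raise ValueError(f"density N must be >= 0, got {self.N}")
        if self.phi <= 0.0:
            raise ValueError(f"body size phi must be > 0, got {self.phi}")

    @property
    def resource_use(self) -> float:
        """Resource use ``u = N * phi``."""
        return self.N * self.phi


@dataclass(frozen=True)
class ResourceContext:
    """Total available resource ``A`` (same units as ``N * phi``)."""

    A: float

    def __post_init__(self) -> None:
        if self.A <= 0.0:
            raise ValueError(f"available resource A must be > 0, got {self.A}")


@dataclass(frozen=True)
class ResourceCheck:
    """Result of the resource-budget diagnostic ``A >= N * phi``."""

    violated: bool
    excess: float


@dataclass(frozen=True)
class RecruitmentMap:
    """Settler–recruit map: density at requested steps for each initial density.

    ``values[i, j]`` is the density after ``steps[j]`` time steps of a cohort
    started at ``N0_grid[i]``.  Column ``j`` as a function of ``N0`` is one
    settler–recruit curve.
    """

    N0_grid: np.ndarray
    steps: tuple[int, ...]
    values: np.ndarray
    phi: np.ndarray = field(repr=False, default=None)  # mean size at each step

    def column(self, step: int) -> np.ndarray:
        """Return the settler–recruit curve at one time step."""
        try:
            j = self.steps.index(step)
        except ValueError:
            raise KeyError(f"step {step} not in recorded steps {self.steps}") from None
        return self.values[:, j]


def survival_fraction(
    params: SurvivalParams,
    u: float | np.ndarray,
    *,
    logistic_literal_sign: bool = False,
) -> float | np.ndarray:
    """Fraction of individuals surviving one base time step at resource use ``u``.

    All three forms return ``alpha`` at ``u = 0`` and, for ``beta > 0``,
    decline strictly with ``u`` (unless ``logistic_literal_sign`` selects the
    increasing printed variant of the logistic form; see the module docstring).

    Accepts a scalar or array ``u``; every element must be >= 0.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0.0):
        raise ValueError(f"resource use u must be >= 0, got minimum {u_arr.min()}")
    if params.form is SurvivalForm.EXPONENTIAL:
        lam = params.alpha * np.exp(-params.beta * u_arr)
    elif params.form is SurvivalForm.LOGISTIC:
        sign = -1.0 if logistic_literal_sign else 1.0
        lam = 1.0 / (1.0 + params.alpha_prime * np.exp(sign * params.beta * u_arr))
    else:  # hyperbolic
        lam = params.alpha / (1.0 + params.beta * u_arr)
    if np.isscalar(u) or u_arr.ndim == 0:
        return float(lam)
    return lam


def grow_step(
    phi: float | np.ndarray, g: GrowthParams, n_steps: float = 1.0
) -> float | np.ndarray:
    """Advance body size by ``n_steps`` Ford–Walford steps (fractional allowed).

    The closed form ``phi_inf - (phi_inf - phi) * exp(-K * n_steps)`` reduces
    to the one-step recursion at ``n_steps = 1``; ``phi_inf`` is a fixed point
    and the approach to it is monotone.
    """
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr <= 0.0):
        raise ValueError(f"body size phi must be > 0, got minimum {phi_arr.min()}")
    if n_steps < 0:
        raise ValueError(f"n_steps must be >= 0, got {n_steps}")
    decay = math.exp(-g.K * n_steps)
    out = g.phi_inf - (g.phi_inf - phi_arr) * decay
    if np.isscalar(phi) or phi_arr.ndim == 0:
        return float(out)
    return out


def step_cohort(
    state: CohortState, sp: SurvivalParams, g: GrowthParams
) -> CohortState:
    """One iteration of the cohort recursion.

    Density is multiplied by the survival fraction evaluated at the current
    resource use ``N * phi``; size advances one growth step.  Density never
    increases because ``lambda <= 1``.
    """
    lam = survival_fraction(sp, state.N * state.phi)
    return CohortState(t=state.t + 1, N=state.N * lam, phi=grow_step(state.phi, g))


def simulate_cohort(
    N0: float,
    phi0: float,
    sp: SurvivalParams,
    g: GrowthParams,
    n_steps: int,
) -> list[CohortState]:
    """Iterate the cohort model for ``n_steps`` steps from ``(N0, phi0)``.

    Returns the full trajectory of length ``n_steps + 1`` including the
    initial state at ``t = 0``.
    """
    if n_steps < 0:
        raise ValueError(f"n_steps must be >= 0, got {n_steps}")
    traj = [CohortState(t=0, N=N0, phi=phi0)]
    for _ in range(n_steps):
        traj.append(step_cohort(traj[-1], sp, g))
    return traj


def resource_violation(state: CohortState, ctx: ResourceContext) -> ResourceCheck:
    """Diagnostic check of the resource budget ``A >= N * phi``.

    Purely diagnostic: the cohort recursion is never clipped by the budget,
    since clipping would alter the published map shapes.  The boundary
    ``N * phi == A`` does not count as a violation.
    """
    use = state.N * state.phi
    excess = max(0.0, use - ctx.A)
    return ResourceCheck(violated=use > ctx.A, excess=excess)


def default_n0_grid(
    n0_min: float = 1.0, n0_max: float = 1.0e4, n_points: int = 400
) -> np.ndarray:
    """Log-spaced grid of initial densities for recruitment maps."""
    if not (0.0 < n0_min < n0_max):
        raise ValueError("need 0 < n0_min < n0_max")
    return np.logspace(math.log10(n0_min), math.log10(n0_max), n_points)


def recruitment_map(
    sp: SurvivalParams,
    g: GrowthParams,
    N0_grid: Sequence[float] | np.ndarray | None = None,
    steps: Sequence[int] | None = None,
    *,
    logistic_literal_sign: bool = False,
) -> RecruitmentMap:
    """Build a settler–recruit map over a grid of initial densities.

    Each row of the grid is iterated with the shared growth trajectory
    (all cohorts start at ``g.phi_0``), and the density is recorded at the
    requested step indices.  Defaults: 400 log-spaced initial densities on
    [1, 1e4] and steps 0..500 (growth saturates on a ``1/K`` time scale, so
    500 steps at the default ``K = 0.01`` spans the full size trajectory).
    """
    grid = default_n0_grid() if N0_grid is None else np.asarray(N0_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("N0_grid must be a nonempty 1-D sequence")
    if np.any(grid <= 0.0):
        raise ValueError("N0_grid values must be > 0")
    if np.any(np.diff(grid) <= 0.0):
        raise ValueError("N0_grid must be strictly increasing")
    step_list = list(range(501)) if steps is None else sorted(set(int(s) for s in steps))
    if not step_list:
        raise ValueError("steps must be nonempty")
    if step_list[0] < 0:
        raise ValueError("steps must be >= 0")

    wanted = set(step_list)
    values = np.empty((grid.size, len(step_list)))
    phis = np.empty(len(step_list))
    N = grid.copy()
    phi = g.phi_0
    col = 0
    for t in range(step_list[-1] + 1):
        if t in wanted:
            values[:, col] = N
            phis[col] = phi
            col += 1
        N = N * survival_fraction(sp, N * phi, logistic_literal_sign=logistic_literal_sign)
        phi = grow_step(phi, g)
    return RecruitmentMap(
        N0_grid=grid, steps=tuple(step_list), values=values, phi=phis
    )


def _merge_plateaus(curve: np.ndarray, eps: float) -> np.ndarray:
    """Collapse runs of near-equal consecutive values to single representatives."""
    reps = [curve[0]]
    for v in curve[1:]:
        if abs(v - reps[-1]) > eps:
            reps.append(v)
    return np.asarray(reps)


def count_local_maxima(curve: Sequence[float], tol: float = 1e-9) -> int:
    """Count strict interior local maxima of a curve, merging plateaus.

    Consecutive values within ``tol`` (relative to the curve's maximum
    absolute value) are treated as a single plateau; a plateau flanked by a
    rise and a fall counts as one maximum.  Endpoints never count.
    """
    c = np.asarray(curve, dtype=float)
    if c.size < 3:
        raise ValueError(f"curve must have at least 3 points, got {c.size}")
    scale = float(np.max(np.abs(c)))
    eps = tol * (scale if scale > 0.0 else 1.0)
    reps = _merge_plateaus(c, eps)
    if reps.size < 3:
        return 0
    interior = reps[1:-1]
    left = reps[:-2]
    right = reps[2:]
    return int(np.sum((interior - left > eps) & (interior - right > eps)))


def classify_map_shape(curve: Sequence[float], tol: float = 1e-9) -> MapShape:
    """Classify a settler–recruit curve as monotonic, unimodal or multimodal.

    ``monotonic_increasing``: no interior maxima and nondecreasing within
    tolerance.  ``unimodal``: exactly one interior maximum, or no interior
    maximum with the peak at a boundary (a curve that only falls within the
    observed window is the tail of a single hump).  ``multimodal``: two or
    more interior maxima.
    """
    m = count_local_maxima(curve, tol=tol)
    if m >= 2:
        return MapShape.MULTIMODAL
    if m == 1:
        return MapShape.UNIMODAL
    c = np.asarray(curve, dtype=float)
    scale = float(np.max(np.abs(c)))
    eps = tol * (scale if scale > 0.0 else 1.0)
    if np.all(np.diff(c) >= -eps):
        return MapShape.MONOTONIC_INCREASING
    return MapShape.UNIMODAL
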