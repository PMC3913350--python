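"""Mechanistic kinetics of lipase-catalysed triolein ethanolysis.

The rate law is the lumped Ping-Pong Bi-Bi expression (with ethanol
inhibition) for the disappearance of triolein in a well-mixed batch
reactor,

    -d[T]/dt = e0 * (K1[T][Et] - K2[P][EO]) / D([T],[Et],[P],[EO])

with a ten-term denominator ``D`` built from the King-Altman enumeration
of the enzyme complexes.  ``[T]`` is triolein, ``[Et]`` ethanol, ``[EO]``
ethyl oleate and ``[P]`` the pooled glycerol + monolein + diolein
concentration (all mol/L); ``e0`` is the lipase loading (g/L).  The twelve
lumped constants K1..K12 absorb the elementary rate constants and any
residual unit conversions; the rate is invariant to a common rescaling of
all twelve, so a fit is only identifiable once one of them is pinned
(``norm_index``, default K3 = 1).

Because the three consecutive transesterification steps share a single
ester product, the remaining species are closed algebraically as a
function of triolein: the baseline linear closure uses the empirical
2.25 slope between ethanol consumption / ester formation and triolein
consumption, plus exact pool stoichiometry P = T0 - T.  A trained network
closure may be substituted (see :mod:`biohybrid.hybrid_model`).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "ESTER_SLOPE",
    "DegenerateStateError",
    "SolverError",
    "KineticParams",
    "SpeciesState",
    "BatchConditions",
    "Trajectory",
    "ClosureValues",
    "rate_triolein",
    "linear_closures",
    "make_linear_closure",
    "integrate_batch",
    "fit_kinetic_params",
    "KineticFit",
]

#: empirical slope of the ethanol/ester vs. triolein-consumption correlation
ESTER_SLOPE = 2.25


class DegenerateStateError(ValueError):
    """Rate-law denominator is non-positive (state or parameters degenerate)."""


class SolverError(RuntimeError):
    """ODE step control failed; carries solver diagnostics."""


@dataclasses.dataclass(frozen=True)
class KineticParams:
    """The 12 lumped rate-law constants plus the normalization gauge.

    Parameters
    ----------
    k : array-like of 12 nonnegative floats
        K1..K12, in order.
    norm_index : int
        1-based index of the constant pinned to 1 during fitting
        (scale gauge; default K3).
    """

    k: np.ndarray
    norm_index: int = 3

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        if k.shape != (12,):
            raise ValueError(f"expected 12 kinetic constants, got shape {k.shape}")
        if np.any(k < 0) or not np.all(np.isfinite(k)):
            raise ValueError("kinetic constants must be finite and nonnegative")
        if not 1 <= self.norm_index <= 12:
            raise ValueError("norm_index must be in 1..12")
        object.__setattr__(self, "k", k)

    @property
    def is_gauged(self) -> bool:
        return abs(self.k[self.norm_index - 1] - 1.0) < 1e-12

    def with_gauge(self) -> "KineticParams":
        """Rescale all constants so the gauge parameter equals exactly 1.

        Valid because the rate is invariant under common rescaling.
        """
        pivot = self.k[self.norm_index - 1]
        if pivot <= 0:
            raise ValueError("gauge parameter is zero; cannot normalize")
        return KineticParams(self.k / pivot, self.norm_index)

    def to_dict(self) -> dict:
        return {f"K{i + 1}": float(v) for i, v in enumerate(self.k)} | {
            "norm_index": self.norm_index
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        k = [float(d[f"K{i + 1}"]) for i in range(12)]
        return cls(np.array(k), int(d.get("norm_index", 3)))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "KineticParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclasses.dataclass(frozen=True)
class SpeciesState:
    """Concentrations (mol/L) of the four tracked species at time ``t`` (h)."""

    T: float
    Et: float
    EO: float
    P: float
    t: float

    def __post_init__(self) -> None:
        for name in ("T", "Et", "EO", "P"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < -1e-12:
                raise ValueError(f"concentration {name}={v} must be nonnegative")
            if v < 0:  # clip float dust
                object.__setattr__(self, name, 0.0)


@dataclasses.dataclass(frozen=True)
class BatchConditions:
    """Operating conditions of one transesterification batch run.

    The first five fields are the designed factors (ratios / levels); the
    last three are the absolute initial concentrations they imply for the
    charged reactor.
    """

    e0_t0: float  # enzyme/triolein mass ratio (g/g)
    Et0_T0: float  # ethanol/triolein molar ratio (mol/mol)
    W0: float  # water fed (g/L)
    omega: int  # agitation level, 0/1/2
    T0_Hex0: float  # triolein/hexane mass ratio (g/g)
    T0: float  # initial triolein (mol/L)
    Et0: float  # initial ethanol (mol/L)
    e0: float  # lipase loading (g/L)
    run_id: int = 0

    def __post_init__(self) -> None:
        if self.omega not in (0, 1, 2):
            raise ValueError(f"omega must be 0, 1 or 2, got {self.omega}")
        if self.T0 <= 0 or self.Et0 < 0 or self.e0 < 0:
            raise ValueError("initial concentrations must be positive")
        if abs(self.Et0 / self.T0 - self.Et0_T0) > 1e-9 * max(1.0, self.Et0_T0):
            raise ValueError("Et0/T0 inconsistent with the stated molar ratio")


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """An ordered batch time course for one run."""

    conditions: BatchConditions
    states: tuple

    def __post_init__(self) -> None:
        states = tuple(self.states)
        if not states:
            raise ValueError("trajectory must contain at least one state")
        t = np.array([s.t for s in states])
        if np.any(np.diff(t) <= 0):
            raise ValueError("state times must be strictly increasing")
        s0 = states[0]
        if abs(s0.T - self.conditions.T0) > 1e-9 * self.conditions.T0:
            raise ValueError("trajectory must start at T = T0")
        if s0.EO > 1e-9 or s0.P > 1e-9:
            raise ValueError("trajectory must start with EO = P = 0")
        object.__setattr__(self, "states", states)

    @property
    def t(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def species(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.states])


class ClosureValues(NamedTuple):
    Et: float
    EO: float
    P: float
    clamped: bool = False


def rate_triolein(state: SpeciesState, params: KineticParams, e0: float) -> float:
    """d[T]/dt (mol/L/h); negative while the forward reaction dominates."""
    T, Et, EO, P = state.T, state.Et, state.EO, state.P
    k = params.k
    num = k[0] * T * Et - k[1] * P * EO
    den = (
        k[2] * T
        + k[3] * Et
        + k[4] * T * Et
        + k[5] * P
        + k[6] * EO
        + k[7] * P * EO
        + k[8] * T * P
        + k[9] * Et * EO
        + k[10] * Et * Et
        + k[11] * Et * P
    )
    if den <= 0:
        raise DegenerateStateError(
            f"rate-law denominator {den} <= 0 at T={T}, Et={Et}, EO={EO}, P={P}"
        )
    return -e0 * num / den


def linear_closures(T: float, conditions: BatchConditions) -> ClosureValues:
    """Baseline algebraic closure: Et/EO linear in triolein consumption, exact pool.

    Et = 2.25 (T - T0) + Et0, EO = -2.25 (T - T0), P = T0 - T.  Ethanol is
    clamped at zero (and the event flagged) when the 2.25 slope overshoots
    the charged ethanol at high conversion.
    """
    T0, Et0 = conditions.T0, conditions.Et0
    if T > T0 * (1 + 1e-9):
        raise ValueError(f"T={T} exceeds T0={T0}: nonphysical for this batch")
    if T < -1e-12:
        raise ValueError(f"negative triolein concentration T={T}")
    T = min(max(T, 0.0), T0)
    dT = T0 - T
    Et = Et0 - ESTER_SLOPE * dT
    clamped = Et < 0
    return ClosureValues(max(Et, 0.0), ESTER_SLOPE * dT, dT, clamped)


def make_linear_closure(conditions: BatchConditions) -> Callable[[float], ClosureValues]:
    """Bind :func:`linear_closures` to one run's conditions."""

    def closure(T: float) -> ClosureValues:
        return linear_closures(T, conditions)

    return closure


def integrate_batch(
    conditions: BatchConditions,
    params: KineticParams,
    closure: Callable[[float], tuple],
    t_grid: Sequence[float],
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the scalar triolein ODE with algebraically closed co-species.

    ``closure`` maps T -> (Et, EO, P); the solver is adaptive and
    stiffness-switching (LSODA), with species clipped at zero.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValueError("t_grid must contain at least two times")
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")

    T0, e0 = conditions.T0, conditions.e0
    c0 = closure(T0)
    if abs(c0[2]) > 1e-9 * max(T0, 1.0):
        raise ValueError("closure inconsistent at T = T0: P(T0) != 0")
    if c0[1] > 1e-3 * max(ESTER_SLOPE * T0, 1.0):
        warnings.warn(
            f"closure EO(T0)={c0[1]:.3g} is not ~0; trajectory will be shifted",
            stacklevel=2,
        )

    def rhs(t: float, y: np.ndarray) -> list:
        T = min(max(y[0], 0.0), T0)
        Et, EO, P = (max(v, 0.0) for v in closure(T)[:3])
        r = rate_triolein(SpeciesState(T, Et, EO, P, t), params, e0)
        if (y[0] <= 0.0 and r < 0.0) or (y[0] >= T0 and r > 0.0):
            return [0.0]
        return [r]

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        [T0],
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"ODE integration failed: {sol.message}")

    T_vals = np.clip(sol.y[0], 0.0, T0)
    states = []
    for ti, Ti in zip(t_grid, T_vals):
        if ti == 0.0:
            states.append(SpeciesState(T0, conditions.Et0, 0.0, 0.0, 0.0))
            continue
        Et, EO, P = (max(v, 0.0) for v in closure(Ti)[:3])
        states.append(SpeciesState(Ti, Et, EO, P, ti))
    return Trajectory(conditions, tuple(states))


@dataclasses.dataclass
class KineticFit:
    """Result of a least-squares kinetic parameter estimation."""

    params: KineticParams
    rss: float
    per_run_rmse: dict
    success: bool
    message: str
    nfev: int


def fit_kinetic_params(
    trajectories: Sequence[Trajectory],
    init: KineticParams,
    closure_factory: Callable[[BatchConditions], Callable] = make_linear_closure,
    max_nfev: int | None = None,
) -> KineticFit:
    """Estimate the gauged K1..K12 from triolein time courses.

    Minimizes the squared residuals in [T] between the data and the batch
    integration, with the gauge parameter pinned to 1 throughout and all
    constants bounded below by zero.  Non-convergence is reported through
    ``success``/``message`` with the best parameters found, never silently.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory to fit")
    for traj in trajectories:
        if len(traj.states) < 5:
            raise ValueError("each trajectory must have at least 5 time points")
    if not init.is_gauged:
        raise ValueError("initial parameters must satisfy the gauge (pinned = 1)")

    pin = init.norm_index - 1
    free = [i for i in range(12) if i != pin]
    x0 = init.k[free]

    data = [
        (traj.conditions, closure_factory(traj.conditions), traj.t, traj.species("T"))
        for traj in trajectories
    ]

    def assemble(x: np.ndarray) -> KineticParams:
        k = np.empty(12)
        k[pin] = 1.0
        k[free] = np.clip(x, 0.0, None)
        return KineticParams(k, init.norm_index)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = assemble(x)
        res = []
        for conds, closure, t, T_obs in data:
            try:
                traj = integrate_batch(conds, p, closure, t)
            except (SolverError, DegenerateStateError):
                return np.full(sum(len(d[2]) for d in data), 1e3)
            res.append(traj.species("T") - T_obs)
        return np.concatenate(res)

    result = least_squares(
        residuals,
        x0,
        bounds=(0.0, np.inf),
        method="trf",
        x_scale="jac",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    fitted = assemble(result.x)
    per_run = {}
    for conds, closure, t, T_obs in data:
        traj = integrate_batch(conds, fitted, closure, t)
        per_run[conds.run_id] = float(
            np.sqrt(np.mean((traj.species("T") - T_obs) ** 2))
        )
    return KineticFit(
        params=fitted,
        rss=float(2 * result.cost),
        per_run_rmse=per_run,
        success=bool(result.success),
        message=str(result.message),
        nfev=int(result.nfev),
    )
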