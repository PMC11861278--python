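"""Compartmental model of depression dynamics with a saboteur population.

The population is divided into seven compartments:

=====  =======================================================================
``S``  susceptible individuals, at risk but not yet depressed
``B``  saboteurs (detractors) who actively undermine others' mental health
``P``  primary (early-stage, milder) depression
``D``  secondary (severe, chronic) depression
``M``  non-pharmacological treatment (exercise, diet, sleep, yoga/CBT)
``C``  pharmacological treatment (counselling, antidepressants)
``R``  recovered
=====  =======================================================================

Saboteurs recruit susceptibles by contact (rate ``beta1``) and push
primary-depressed individuals into the secondary stage (rate ``lambda1``);
susceptibles become primary depressed through contact with the
secondary-depressed (rate ``beta2``).  Both contact processes are
frequency-dependent (scaled by the total population ``N``).  The total
population obeys ``dN/dt = Lambda - mu*N - sigma*D``, so every solution
started inside the region ``0 <= x_i``, ``N <= Lambda/mu`` stays there.

The controlled variant adds three bounded, time-dependent intervention
rates: ``u1`` boosts uptake of non-pharmacological treatment (P -> M),
``u2`` boosts uptake of pharmacological treatment (D -> C) and ``u3``
boosts recovery from pharmacological treatment (C -> R).  With all three
controls at zero the controlled system coincides exactly with the base
model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "COMPARTMENTS",
    "PARAM_ALIASES",
    "ModelParameters",
    "StateVector",
    "ControlVector",
    "Trajectory",
    "IntegrationError",
    "rhs",
    "rhs_controlled",
    "simulate",
    "resolve_param_name",
]

COMPARTMENTS: tuple[str, ...] = ("S", "B", "P", "D", "M", "C", "R")

#: Conventional (Greek-letter) spellings accepted anywhere a parameter is
#: named, mapped to the descriptive field names of :class:`ModelParameters`.
PARAM_ALIASES: dict[str, str] = {
    "Lambda": "recruitment",
    "beta1": "saboteur_contact",
    "beta2": "depression_contact",
    "lambda1": "saboteur_aggravation",
    "lambda2": "progression",
    "psi1": "primary_uptake",
    "psi2": "secondary_uptake",
    "gamma1": "recovery_nonpharm",
    "gamma2": "recovery_pharm",
    "sigma": "depression_death",
    "omega": "relapse",
    "mu": "natural_death",
}

_FIELD_TO_GREEK = {v: k for k, v in PARAM_ALIASES.items()}


def resolve_param_name(name: str) -> str:
    """Return the :class:`ModelParameters` field for ``name``.

    Accepts either the descriptive field name (``"depression_contact"``)
    or the conventional short spelling (``"beta2"``).
    """
    if name in PARAM_ALIASES:
        return PARAM_ALIASES[name]
    if name in _FIELD_TO_GREEK:
        return name
    raise KeyError(f"unknown model parameter {name!r}")


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails to meet its tolerances."""


@dataclass(frozen=True)
class ModelParameters:
    """The twelve non-negative rate constants of the model (units: 1/year,
    except ``recruitment`` which is individuals/year on the chosen
    population scale)."""

    recruitment: float          # Lambda, inflow of susceptibles
    saboteur_contact: float     # beta1, S -> B by contact with B
    depression_contact: float   # beta2, S -> P by contact with D
    saboteur_aggravation: float  # lambda1, P -> D by contact with B
    progression: float          # lambda2, spontaneous P -> D
    primary_uptake: float       # psi1, P -> M
    secondary_uptake: float     # psi2, D -> C
    recovery_nonpharm: float    # gamma1, M -> R
    recovery_pharm: float       # gamma2, C -> R
    depression_death: float     # sigma, excess mortality in D
    relapse: float              # omega, R -> D
    natural_death: float        # mu, background mortality

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"{field.name} must be finite and >= 0, got {value}"
                )
        if self.natural_death <= 0:
            raise ValueError("natural_death (mu) must be strictly positive")

    @property
    def saboteurs_viable(self) -> bool:
        """Whether beta1 > mu, i.e. a saboteur population can establish.

        The saboteur-present depression-free equilibrium and the
        next-generation matrix both require this.
        """
        return self.saboteur_contact > self.natural_death

    @property
    def carrying_capacity(self) -> float:
        """Asymptotic population bound Lambda/mu."""
        return self.recruitment / self.natural_death

    def as_dict(self, greek: bool = False) -> dict[str, float]:
        d = dataclasses.asdict(self)
        if greek:
            return {_FIELD_TO_GREEK[k]: v for k, v in d.items()}
        return d

    def with_updates(self, **updates: float) -> "ModelParameters":
        """Return a copy with the given parameters replaced; keys may use
        either naming convention."""
        resolved = {resolve_param_name(k): v for k, v in updates.items()}
        return dataclasses.replace(self, **resolved)

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "ModelParameters":
        resolved = {resolve_param_name(k): float(v) for k, v in values.items()}
        missing = {f.name for f in dataclasses.fields(cls)} - set(resolved)
        if missing:
            raise ValueError(f"missing model parameters: {sorted(missing)}")
        return cls(**resolved)

    @classmethod
    def spain_baseline(cls, reference_population: float = 47_400_000.0) -> "ModelParameters":
        """Published Spain calibration: literature/assumed rates plus the
        fitted contact and recovery rates (beta1=0.5665, beta2=0.1567,
        gamma2=0.9219).  Recruitment is the per-capita birth rate
        7.816/10,000 per year times ``reference_population``."""
        return cls(
            recruitment=7.816e-4 * reference_population,
            saboteur_contact=0.5665,
            depression_contact=0.1567,
            saboteur_aggravation=0.2145,
            progression=0.7,
            primary_uptake=0.0045,
            secondary_uptake=0.02,
            recovery_nonpharm=0.6,
            recovery_pharm=0.9219,
            depression_death=0.01,
            relapse=0.005,
            natural_death=0.0125,
        )


@dataclass(frozen=True)
class StateVector:
    """Compartment occupancies; ``total`` is always the exact sum."""

    S: float
    B: float
    P: float
    D: float
    M: float
    C: float
    R: float

    @property
    def total(self) -> float:
        return self.S + self.B + self.P + self.D + self.M + self.C + self.R

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.B, self.P, self.D, self.M, self.C, self.R])

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "StateVector":
        arr = np.asarray(values, dtype=float)
        if arr.shape != (7,):
            raise ValueError(f"state must have 7 components, got shape {arr.shape}")
        return cls(*arr.tolist())


@dataclass(frozen=True)
class ControlVector:
    """The three intervention rates (dimensionless additions to psi1, psi2,
    gamma2)."""

    u1: float = 0.0
    u2: float = 0.0
    u3: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.u1, self.u2, self.u3])

    def clipped(self, lower: Sequence[float], upper: Sequence[float]) -> "ControlVector":
        u = np.clip(self.as_array(), lower, upper)
        return ControlVector(*u.tolist())


def _param_tuple(params: ModelParameters) -> tuple[float, ...]:
    return (
        params.recruitment,
        params.saboteur_contact,
        params.depression_contact,
        params.saboteur_aggravation,
        params.progression,
        params.primary_uptake,
        params.secondary_uptake,
        params.recovery_nonpharm,
        params.recovery_pharm,
        params.depression_death,
        params.relapse,
        params.natural_death,
    )


def _rhs_core(y, p, u1=0.0, u2=0.0, u3=0.0):
    """Hot-path right-hand side on plain floats; no validation."""
    S, B, P, D, M, C, R = y
    Lam, b1, b2, l1, l2, p1, p2, g1, g2, sg, om, mu = p
    N = S + B + P + D + M + C + R
    sab = b1 * B * S / N       # S -> B
    dep = b2 * D * S / N       # S -> P
    agg = l1 * B * P / N       # P -> D (saboteur aggravation)
    dS = Lam - sab - dep - mu * S
    dB = sab - mu * B
    dP = dep - agg - (l2 + mu + p1 + u1) * P
    dD = agg + l2 * P + om * R - (p2 + u2 + mu + sg) * D
    dM = (p1 + u1) * P - (g1 + mu) * M
    dC = (p2 + u2) * D - (g2 + u3 + mu) * C
    dR = g1 * M + (g2 + u3) * C - (mu + om) * R
    return (dS, dB, dP, dD, dM, dC, dR)


def _coerce_state(state) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.as_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (7,):
        raise ValueError(f"state must have 7 components, got shape {arr.shape}")
    return arr


def rhs_controlled(state, params: ModelParameters, controls) -> np.ndarray:
    """Right-hand side of the controlled model.

    ``controls`` may be a :class:`ControlVector` or any 3-sequence
    ``(u1, u2, u3)``.  With all controls zero this is exactly :func:`rhs`.
    """
    y = _coerce_state(state)
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    if y.sum() <= 0:
        raise ValueError(
            "total population is zero: frequency-dependent contact terms "
            "are undefined"
        )
    if isinstance(controls, ControlVector):
        u = controls.as_array()
    else:
        u = np.asarray(controls, dtype=float)
        if u.shape != (3,):
            raise ValueError("controls must have 3 components (u1, u2, u3)")
    return np.array(_rhs_core(tuple(y), _param_tuple(params), *u))


def rhs(state, params: ModelParameters) -> np.ndarray:
    """Right-hand side of the base (uncontrolled) model.

    The component sum always equals ``Lambda - mu*N - sigma*D``: the
    contact and progression terms are internal transfers.
    """
    return rhs_controlled(state, params, (0.0, 0.0, 0.0))


def _as_control_fn(controls) -> Callable[[float], tuple[float, float, float]]:
    """Normalise the ``controls`` argument of :func:`simulate` to a callable
    ``t -> (u1, u2, u3)``.  Accepts None, a constant 3-sequence or
    ControlVector, a callable, or a pair ``(times, values)`` with values of
    shape (len(times), 3) interpolated linearly."""
    if controls is None:
        return lambda t: (0.0, 0.0, 0.0)
    if isinstance(controls, ControlVector):
        const = tuple(controls.as_array())
        return lambda t: const
    if callable(controls):
        return controls
    if (
        isinstance(controls, tuple)
        and len(controls) == 2
        and np.ndim(controls[1]) == 2
    ):
        ctimes = np.asarray(controls[0], dtype=float)
        cvals = np.asarray(controls[1], dtype=float)
        if cvals.shape != (ctimes.size, 3):
            raise ValueError("control values must have shape (len(times), 3)")

        def interp(t: float):
            return tuple(
                float(np.interp(t, ctimes, cvals[:, j])) for j in range(3)
            )

        return interp
    const = tuple(np.asarray(controls, dtype=float))
    if len(const) != 3:
        raise ValueError("constant controls must have 3 components")
    return lambda t: const


@dataclass
class Trajectory:
    """A solved path of the model: ``states[i]`` is the 7-component state at
    ``times[i]``.  When produced by :func:`simulate`, a dense interpolant is
    attached so the solution can be evaluated at arbitrary times."""

    times: np.ndarray
    states: np.ndarray
    dense: Callable[[float], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 7):
            raise ValueError("states must have shape (len(times), 7)")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def totals(self) -> np.ndarray:
        """Total population N at every grid time."""
        return self.states.sum(axis=1)

    def state_at(self, t) -> np.ndarray:
        """Evaluate the trajectory at arbitrary time(s) via the dense
        interpolant (or linear interpolation on the grid as a fallback)."""
        if self.dense is not None:
            out = np.atleast_2d(np.asarray(self.dense(t)).T.reshape(-1, 7))
            out = np.clip(out, 0.0, None)
            return out[0] if np.ndim(t) == 0 else out
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.column_stack(
            [np.interp(t_arr, self.times, self.states[:, j]) for j in range(7)]
        )
        return out[0] if np.ndim(t) == 0 else out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, **{c: self.states[:, j] for j, c in enumerate(COMPARTMENTS)}}
        )


def simulate(
    params: ModelParameters,
    init,
    time_grid,
    controls=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the (optionally controlled) model over ``time_grid``.

    Uses an adaptive explicit Runge-Kutta pair with dense output.  Negative
    undershoots larger than ``1e-8 * max(1, Lambda/mu)`` raise
    :class:`IntegrationError`; smaller ones are clamped to zero in the
    reported states (the dense interpolant is clamped on evaluation too).
    """
    y0 = _coerce_state(init)
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("time grid must be a 1-D array with >= 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be strictly increasing")

    p = _param_tuple(params)
    control_fn = _as_control_fn(controls)

    def fun(t, y):
        return _rhs_core(tuple(y), p, *control_fn(t))

    sol = solve_ivp(
        fun,
        (grid[0], grid[-1]),
        y0,
        method="RK45",
        t_eval=grid,
        dense_output=True,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")

    states = sol.y.T
    undershoot_tol = 1e-8 * max(1.0, params.carrying_capacity)
    worst = states.min()
    if worst < -undershoot_tol:
        raise IntegrationError(
            f"negative compartment {worst:.3e} exceeds the undershoot "
            f"tolerance {-undershoot_tol:.3e}"
        )
    return Trajectory(times=grid, states=np.clip(states, 0.0, None), dense=sol.sol)


def jacobian_analytic(state, params: ModelParameters, controls=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Exact Jacobian of the (controlled) right-hand side.

    The three frequency-dependent bilinear terms c*X*Y/N have partial
    derivatives Y(N-X)/N^2 and X(N-Y)/N^2 in their own factors and
    -XY/N^2 in every other compartment (because N is the component sum).
    """
    y = _coerce_state(state)
    S, B, P, D, M, C, R = y
    N = y.sum()
    if N <= 0:
        raise ValueError("total population must be positive")
    _, b1, b2, l1, l2, p1, p2, g1, g2, sg, om, mu = _param_tuple(params)
    u1, u2, u3 = (float(v) for v in np.asarray(controls, dtype=float))
    n2 = N * N

    def bilinear_grad(c, X, Y, ix, iy):
        g = np.full(7, -c * X * Y / n2)
        g[ix] = c * Y * (N - X) / n2
        g[iy] = c * X * (N - Y) / n2
        return g

    d_sab = bilinear_grad(b1, S, B, 0, 1)   # beta1*B*S/N, factors S (0), B (1)
    d_dep = bilinear_grad(b2, S, D, 0, 3)   # beta2*D*S/N
    d_agg = bilinear_grad(l1, P, B, 2, 1)   # lambda1*B*P/N

    J = np.zeros((7, 7))
    J[0] = -d_sab - d_dep
    J[0, 0] -= mu
    J[1] = d_sab
    J[1, 1] -= mu
    J[2] = d_dep - d_agg
    J[2, 2] -= l2 + mu + p1 + u1
    J[3] = d_agg
    J[3, 2] += l2
    J[3, 6] += om
    J[3, 3] -= p2 + u2 + mu + sg
    J[4, 2] = p1 + u1
    J[4, 4] = -(g1 + mu)
    J[5, 3] = p2 + u2
    J[5, 5] = -(g2 + u3 + mu)
    J[6, 4] = g1
    J[6, 5] = g2 + u3
    J[6, 6] = -(mu + om)
    return J


def integrate_fixed_step(
    params: ModelParameters,
    init,
    time_grid,
    controls: np.ndarray | None = None,
    max_step: float = 0.05,
) -> np.ndarray:
    """Classical fixed-step RK4 integration returning states on ``time_grid``.

    ``controls``, if given, is an array of shape (len(time_grid), 3) holding
    the control values at the grid times, interpolated linearly within each
    step.  This is the fast inner loop used by the calibrator and the
    forward-backward sweep; accuracy against the adaptive integrator is
    checked in the test suite.
    """
    grid = np.asarray(time_grid, dtype=float)
    y = tuple(_coerce_state(init).tolist())
    p = _param_tuple(params)
    out = np.empty((grid.size, 7))
    out[0] = y
    have_u = controls is not None
    for i in range(grid.size - 1):
        t0, t1 = grid[i], grid[i + 1]
        nsub = max(1, int(np.ceil((t1 - t0) / max_step)))
        h = (t1 - t0) / nsub
        if have_u:
            u0 = controls[i]
            u1 = controls[i + 1]
        for k in range(nsub):
            if have_u:
                f0 = (k + 0.0) / nsub
                f1 = (k + 0.5) / nsub
                f2 = (k + 1.0) / nsub
                ua = tuple(u0 + f0 * (u1 - u0))
                um = tuple(u0 + f1 * (u1 - u0))
                ub = tuple(u0 + f2 * (u1 - u0))
            else:
                ua = um = ub = (0.0, 0.0, 0.0)
            k1 = _rhs_core(y, p, *ua)
            y2 = tuple(y[j] + 0.5 * h * k1[j] for j in range(7))
            k2 = _rhs_core(y2, p, *um)
            y3 = tuple(y[j] + 0.5 * h * k2[j] for j in range(7))
            k3 = _rhs_core(y3, p, *um)
            y4 = tuple(y[j] + h * k3[j] for j in range(7))
            k4 = _rhs_core(y4, p, *ub)
            y = tuple(
                y[j] + h / 6.0 * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j])
                for j in range(7)
            )
        out[i + 1] = y
    return out
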