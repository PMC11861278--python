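"""Equilibria of the depression model and their local stability.

Four families of steady states exist:

* ``E0`` — extinction of both contagion processes: only susceptibles,
  S* = Lambda/mu.
* ``E1`` — saboteur-present, depression-free: S* = Lambda/beta1,
  B* = (beta1/mu - 1) Lambda/beta1; requires beta1 > mu.
* ``E2`` — saboteur-free endemic depression (B = 0, D > 0).
* ``E3`` — fully endemic (B > 0, D > 0); its total population is a
  positive root of a quintic polynomial in N.

The closed-form constant chains published for E2 and the quintic
coefficients are ill-conditioned and contain grouping ambiguities, so this
module treats them strictly as cross-check material: the authoritative
path is numerical root-finding on the right-hand side restricted to the
non-negative orthant, with every candidate verified by its residual and
classified by the sign pattern of its eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .model import (
    ModelParameters,
    StateVector,
    _coerce_state,
    jacobian_analytic,
    rhs,
    simulate,
)

__all__ = [
    "EquilibriumReport",
    "QuinticCoefficients",
    "closed_form_equilibria",
    "quintic_coefficients",
    "descartes_bounds",
    "solve_equilibria_numeric",
    "jacobian",
    "classify_stability",
]


@dataclass
class EquilibriumReport:
    label: str
    state: StateVector
    residual_norm: float
    eigenvalues: np.ndarray | None = None
    stability: str | None = None
    notes: str = ""


def _report(label: str, y: np.ndarray, params: ModelParameters, notes: str = "") -> EquilibriumReport:
    res = float(np.max(np.abs(rhs(np.clip(y, 0, None) + 0.0, params)))) if y.sum() > 0 else float(
        np.max(np.abs(np.array([params.recruitment, 0, 0, 0, 0, 0, 0])))
    )
    rep = EquilibriumReport(
        label=label,
        state=StateVector.from_array(y),
        residual_norm=res,
        notes=notes,
    )
    if y.sum() > 0:
        J = jacobian_analytic(y, params)
        rep.eigenvalues = np.linalg.eigvals(J)
        rep.stability = classify_stability(rep, params)
    return rep


def closed_form_equilibria(params: ModelParameters) -> list[EquilibriumReport]:
    """E0 and E1 exactly; the E2 closed-form chain as a checked candidate.

    E1 is omitted (with a note in no report) when beta1 <= mu.  The E2
    constants are evaluated verbatim from the published chain but their
    residual is reported honestly — the chain does not dimension-check and
    is labelled a candidate whenever the residual is not small.
    """
    Lam = params.recruitment
    mu = params.natural_death
    b1 = params.saboteur_contact
    out = []
    e0 = np.zeros(7)
    e0[0] = Lam / mu if mu > 0 else 0.0
    out.append(_report("E0", e0, params))
    if params.saboteurs_viable:
        e1 = np.zeros(7)
        e1[0] = Lam / b1
        e1[1] = (b1 / mu - 1.0) * Lam / b1
        out.append(_report("E1", e1, params))
    elif b1 == mu:
        # degenerate limit: E1 coincides with E0
        out.append(_report("E1", e0.copy(), params, notes="beta1 == mu: E1 coincides with E0"))

    e2 = _e2_closed_form_candidate(params)
    if e2 is not None:
        rep = _report("E2", e2, params)
        scale = max(1.0, float(np.sum(e2)))
        if rep.residual_norm > 1e-9 * scale:
            rep.label = "E2-closed-form-candidate"
            rep.notes = (
                "closed-form constant chain does not satisfy the steady-state "
                "equations; use solve_equilibria_numeric for E2"
            )
        out.append(rep)
    return out


def _e2_closed_form_candidate(params: ModelParameters) -> np.ndarray | None:
    """Verbatim evaluation of the published saboteur-free constant chain."""
    Lam = params.recruitment
    mu = params.natural_death
    l2 = params.progression
    p1 = params.primary_uptake
    p2 = params.secondary_uptake
    g1 = params.recovery_nonpharm
    g2 = params.recovery_pharm
    sg = params.depression_death
    om = params.relapse
    a1 = p1 / (g1 + mu)
    a2 = p2 / (mu + g2)
    a3 = p2 + mu + sg
    denom4 = a3 * (mu + om) - a2
    if denom4 == 0:
        return None
    a4 = (l2 * (mu + om) + a1) / denom4
    a5 = l2 + mu + p1
    if l2 == 0:
        return None
    a6 = (
        a3 * a4 / l2
        + a4
        + a1
        + a2 * a4
        + (l2 - om) * (g1 * a1 + a2 * a4 * g2) / (l2 * (mu + om))
    )
    denomP = sg * a4 - a5 * a4 + a6 * mu
    if denomP == 0:
        return None
    P = Lam * (1.0 - a4) / denomP
    S = (Lam * a4 - a5 * a4) / mu * P
    D = a4 * P
    M = a1 * P
    C = a2 * D
    R = (g1 * a1 * P + g2 * a2 * D) / (mu + om)
    y = np.array([S, 0.0, P, D, M, C, R])
    if not np.all(np.isfinite(y)):
        return None
    return y


@dataclass(frozen=True)
class QuinticCoefficients:
    """Coefficients Q1..Q6 of the endemic total-population polynomial
    Q1 N^5 + Q2 N^4 + Q3 N^3 + Q4 N^2 + Q5 N + Q6, together with the
    auxiliary constants used to build them.

    The published coefficient expressions contain grouping ambiguities and
    apparent transcription slips; they are retained here verbatim (with the
    most plausible balanced reading) for cross-checking only.  Numerical
    root-finding is the authoritative path to the endemic equilibrium.
    """

    Q1: float
    Q2: float
    Q3: float
    Q4: float
    Q5: float
    Q6: float
    constants: dict = field(default_factory=dict)

    def as_list(self) -> list[float]:
        return [self.Q1, self.Q2, self.Q3, self.Q4, self.Q5, self.Q6]

    def evaluate(self, N) -> np.ndarray:
        return np.polyval(self.as_list(), N)


def quintic_coefficients(params: ModelParameters) -> QuinticCoefficients:
    Lam = params.recruitment
    mu = params.natural_death
    b1 = params.saboteur_contact
    b2 = params.depression_contact
    l1 = params.saboteur_aggravation
    l2 = params.progression
    p1 = params.primary_uptake
    p2 = params.secondary_uptake
    g1 = params.recovery_nonpharm
    g2 = params.recovery_pharm
    sg = params.depression_death
    om = params.relapse
    if b1 == 0:
        raise ValueError("quintic constants require beta1 > 0")

    a1 = p1 / (g1 + mu)
    a2 = p2 / (mu + g2)
    a3 = p2 + mu + sg
    a4 = l2 + mu + p1
    a5 = l2 + mu + p1          # alias used by the Q6 expression
    bb1 = g1 * a1 / (mu + om)
    bb2 = g2 * a2 / (mu + om)
    bb3 = mu * b2 / b1
    A1 = a4 * a3 * b1 * (a3 - bb2) - (l2 + bb1) * mu * b2
    A2 = l1 * a3 * (a3 - bb2)
    A3 = mu * b2 * l1 / b1
    C1 = Lam * A2 * b1 - mu * A1 * b1
    C2 = b1 * A3 * Lam + mu**2 * A2
    C3 = mu**2 * A3
    C4 = b1 * A2
    C5 = b1 * A3

    s1 = 1 + a1 + bb1
    s2 = 1 + a2 + bb2
    Q1 = s1 * bb3 * b1 * A3**2 * C3
    Q2 = (2 + a2 + bb2 + mu) * A3**2 * C5 * a4 - s1 * bb3 * b1 * (
        2 * A2 * A3 * C3 + A3**2 * C2
    )
    Q3 = (
        a4 * A3 * (mu * (A3 * C4 + A2 * C5) - (a3 + C5))
        + (mu - 1) * (l1 * A1 + a4 * A2) * A3 * C5
        + s1 * bb3 * b1 * (C1 * A3**2 + A2**2 * C3 + 2 * A2 * A3 * C2)
        - s2 * (C3 * A3 * (l1 * A1 + a4 * A2) + A2 * A3 * a4 + C2 * a4 * A3**2)
    )
    Q4 = (
        (l1 * A1 - 1 + a4)
        * (A3 + C5 - mu * (A3 * C4 + A2 * C5) + 3 * s2 * C3 * A2)
        + a4 * A3 * (A2 * C4 - mu * A2 * C4 + A1 * b1 * C5 + A2 * s2 + C1 * A3)
        - bb3 * b1 * s1 * (2 * A2 * A3 * C1 + C2 * A2**2)
    )
    Q5 = (
        (l1 * A1 + a4 * A2)
        * (mu * A2 * C4 - A2 * C4 - A1 * b1 * C5 - s2 * (C2 * A2 + C1 * A3))
        - A1 * b1 * a4 * A3 * C4
        + s1 * bb3 * b1 * A2**2 * C1
        - s2 * C1 * A2 * A3 * a4
    )
    Q6 = A1 * b1 * C4 * (l1 * A1 + a5 * A2) + s2 * A2 * C1 * (l1 * A1 + a5 * A2)

    constants = dict(
        a1=a1, a2=a2, a3=a3, a4=a4, a5=a5, b1=bb1, b2=bb2, b3=bb3,
        A1=A1, A2=A2, A3=A3, C1=C1, C2=C2, C3=C3, C4=C4, C5=C5,
    )
    return QuinticCoefficients(Q1, Q2, Q3, Q4, Q5, Q6, constants)


def descartes_bounds(coefficients) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Descartes' rule of signs for an ordered (highest degree first) real
    coefficient list.

    Returns the possible counts of positive and of negative real roots,
    each as a descending tuple {v, v-2, ...} where v is the number of sign
    changes of p(x) and of p(-x) respectively.  Zero coefficients are
    skipped when counting changes; an all-zero list is an error.
    """
    coeffs = np.asarray(coefficients, dtype=float)
    nz = np.nonzero(coeffs)[0]
    if nz.size == 0:
        raise ValueError("all coefficients are zero")
    coeffs = coeffs[nz[0]:]
    degree_parity = (np.arange(coeffs.size - 1, -1, -1)) % 2

    def changes(signs):
        signs = [s for s in signs if s != 0]
        return sum(1 for a, b in zip(signs, signs[1:]) if a * b < 0)

    pos_changes = changes(np.sign(coeffs))
    neg_signs = np.sign(coeffs) * np.where(degree_parity == 1, -1, 1)
    neg_changes = changes(neg_signs)

    def possible(v):
        return tuple(range(v, -1, -2))

    return possible(pos_changes), possible(neg_changes)


def jacobian(state, params: ModelParameters, method: str = "fd") -> np.ndarray:
    """Jacobian of :func:`depdyn.model.rhs` at ``state``.

    ``method="fd"`` uses central finite differences with relative step
    1e-7; ``method="analytic"`` evaluates the exact derivative.  The two
    agree to about 1e-5 relative and are cross-checked in the test suite.
    """
    y = _coerce_state(state)
    N = y.sum()
    if N <= 0:
        raise ValueError("total population must be positive")
    if method == "analytic":
        return jacobian_analytic(y, params)
    if method != "fd":
        raise ValueError(f"unknown jacobian method {method!r}")
    J = np.zeros((7, 7))
    for k in range(7):
        h = 1e-7 * max(abs(y[k]), 1e-3 * N)
        yp = y.copy()
        ym = y.copy()
        yp[k] += h
        ym[k] = max(ym[k] - h, 0.0)
        step = yp[k] - ym[k]
        J[:, k] = (rhs(yp, params) - rhs(ym, params)) / step
    return J


def classify_stability(report: EquilibriumReport, params: ModelParameters) -> str:
    """Label an equilibrium stable/unstable/marginal from its eigenvalues.

    The threshold is eps = 1e-8 times the spectral scale (largest
    eigenvalue magnitude, floored at 1): strictly negative real parts below
    -eps mean stable, any real part above +eps means unstable, anything
    else is marginal and never silently promoted.
    """
    eig = report.eigenvalues
    if eig is None:
        J = jacobian_analytic(report.state.as_array(), params)
        eig = np.linalg.eigvals(J)
        report.eigenvalues = eig
    scale = max(1.0, float(np.max(np.abs(eig))))
    eps = 1e-8 * scale
    re = eig.real
    if np.all(re < -eps):
        return "stable"
    if np.any(re > eps):
        return "unstable"
    return "marginal"


def _label_pattern(y: np.ndarray, tol: float) -> str:
    has_b = y[1] > tol
    has_d = max(y[2], y[3]) > tol
    if not has_b and not has_d:
        return "E0"
    if has_b and not has_d:
        return "E1"
    if not has_b and has_d:
        return "E2"
    return "E3"


def solve_equilibria_numeric(
    params: ModelParameters,
    n_starts: int = 64,
    seed: int = 0,
) -> list[EquilibriumReport]:
    """Multi-start root-finding on the steady-state equations.

    Starts are a seeded low-discrepancy (Halton) scatter in [0, Lambda/mu]^7,
    the closed-form E0/E1 points, and the 200-year attractor of a generic
    interior simulation (which seeds the endemic branch when R0 > 1).
    Roots outside the non-negative orthant are discarded, duplicates are
    merged at 1e-6 relative tolerance, and every retained root carries its
    verified residual — an empty list (never a fabricated root) is returned
    if no start converges.
    """
    cap = params.carrying_capacity
    sampler = qmc.Halton(d=7, scramble=True, seed=seed)
    starts = [cap * row for row in sampler.random(n_starts)]
    e0 = np.zeros(7)
    e0[0] = cap
    starts.append(e0 + 1e-6 * cap)
    if params.saboteurs_viable:
        e1 = np.zeros(7)
        e1[0] = params.recruitment / params.saboteur_contact
        e1[1] = cap - e1[0]
        starts.append(e1)
    interior = np.full(7, cap / 7.0)
    try:
        traj = simulate(params, interior, np.linspace(0.0, 200.0, 21), rtol=1e-9)
        starts.append(traj.states[-1])
    except Exception:
        pass

    scale = max(1.0, cap)

    def steady_state_fun(y):
        ya = np.abs(y)
        if ya.sum() <= 0:
            return np.full(7, scale)
        return rhs(ya, params)

    roots: list[np.ndarray] = []
    for y0 in starts:
        y0 = np.clip(np.asarray(y0, dtype=float), 1e-12 * scale, None)
        sol = optimize.root(steady_state_fun, y0, method="hybr")
        if not sol.success:
            continue
        y = np.abs(sol.x)
        res = float(np.max(np.abs(rhs(y, params)))) if y.sum() > 0 else np.inf
        if res > 1e-9 * scale:
            continue
        y[y < 1e-12 * scale] = 0.0
        if any(np.max(np.abs(y - r)) <= 1e-6 * scale for r in roots):
            continue
        roots.append(y)

    reports = []
    for y in roots:
        label = _label_pattern(y, 1e-8 * scale)
        reports.append(_report(label, y, params))
    reports.sort(key=lambda r: r.state.total)
    return reports
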