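"""Basic reproduction number, next-generation matrix and sensitivity.

The infected subsystem is ordered (P, D, M, C).  New "infections" (new
primary-depression cases) arise only through the beta2*D*S/N contact term,
so the new-infection matrix F has a single nonzero entry.  Transitions are
linearised at the saboteur-present depression-free equilibrium E1, where
the saboteur fraction is B*/N* = (beta1 - mu)/beta1 — hence the requirement
beta1 > mu.  The spectral radius of F V^-1 has the closed form::

    R0 = beta2 (beta1 lambda1 + beta1 lambda2 - lambda1 mu)
         -----------------------------------------------------------------
         (mu + psi2 + sigma)
         (beta1 lambda1 + beta1 lambda2 + beta1 mu + beta1 psi1 - lambda1 mu)

Only eight parameters enter R0; the recruitment, relapse and the two
recovery rates drop out.  Sensitivity is reported as the elasticity
(normalised forward sensitivity index) (dR0/dp) * (p/R0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _replace

import numpy as np
import pandas as pd

from .model import ModelParameters, resolve_param_name

__all__ = [
    "R0_PARAMETERS",
    "NGMResult",
    "SensitivityIndex",
    "r0_closed_form",
    "next_generation_matrices",
    "elasticity",
    "elasticity_profile",
    "r0_grid",
]

#: Parameters R0 depends on, in the conventional reporting order.
R0_PARAMETERS: tuple[str, ...] = (
    "beta1", "beta2", "lambda1", "lambda2", "psi1", "psi2", "sigma", "mu",
)


@dataclass(frozen=True)
class NGMResult:
    F: np.ndarray
    V: np.ndarray
    K: np.ndarray                  # F V^-1
    spectral_radius: float
    r0_closed_form: float
    infected_ordering: tuple[str, ...] = ("P", "D", "M", "C")


@dataclass(frozen=True)
class SensitivityIndex:
    parameter_name: str
    elasticity: float


def _require_viable(params: ModelParameters) -> None:
    if not params.saboteurs_viable:
        raise ValueError(
            "saboteur_contact (beta1) must exceed natural_death (mu): the "
            "next-generation linearisation at the saboteur-present "
            "equilibrium needs B*/N* = (beta1 - mu)/beta1 >= 0"
        )


def r0_closed_form(params: ModelParameters) -> float:
    """Closed-form basic reproduction number.

    R0 is linear in beta2, so beta2 = 0 gives R0 = 0 regardless of the
    other rates.  Raises if the bracketed factors are not positive, which
    is guaranteed not to happen when beta1 > mu.
    """
    b1 = params.saboteur_contact
    b2 = params.depression_contact
    l1 = params.saboteur_aggravation
    l2 = params.progression
    p1 = params.primary_uptake
    p2 = params.secondary_uptake
    sg = params.depression_death
    mu = params.natural_death
    if b1 <= 0:
        raise ValueError("saboteur_contact (beta1) must be positive")
    bracket = b1 * l1 + b1 * l2 - l1 * mu
    denom = (mu + p2 + sg) * (bracket + b1 * mu + b1 * p1)
    if b2 == 0:
        return 0.0
    if bracket <= 0 or denom <= 0:
        raise ValueError(
            "R0 closed form undefined: beta1*lambda1 + beta1*lambda2 - "
            "lambda1*mu must be positive (holds whenever beta1 > mu)"
        )
    return b2 * bracket / denom


def next_generation_matrices(params: ModelParameters) -> NGMResult:
    """F, V and K = F V^-1 for the infected subsystem (P, D, M, C).

    F carries the single new-case term beta2 (row P, column D).  V is the
    linearised outflow: its (P, P) entry includes the saboteur aggravation
    lambda1 * (beta1 - mu)/beta1 evaluated at E1.  Relapse from R is not
    part of the infected subsystem and does not appear.
    """
    _require_viable(params)
    b1 = params.saboteur_contact
    b2 = params.depression_contact
    l1 = params.saboteur_aggravation
    l2 = params.progression
    p1 = params.primary_uptake
    p2 = params.secondary_uptake
    g1 = params.recovery_nonpharm
    g2 = params.recovery_pharm
    sg = params.depression_death
    mu = params.natural_death

    sab_frac = l1 * (b1 - mu) / b1
    F = np.zeros((4, 4))
    F[0, 1] = b2
    V = np.array(
        [
            [l2 + mu + p1 + sab_frac, 0.0, 0.0, 0.0],
            [-l2 - sab_frac, mu + p2 + sg, 0.0, 0.0],
            [-p1, 0.0, g1 + mu, 0.0],
            [0.0, -p2, 0.0, g2 + mu],
        ]
    )
    K = F @ np.linalg.solve(V, np.eye(4))
    rho = float(np.max(np.abs(np.linalg.eigvals(K))))
    return NGMResult(
        F=F,
        V=V,
        K=K,
        spectral_radius=rho,
        r0_closed_form=r0_closed_form(params),
    )


def elasticity(
    params: ModelParameters, parameter_name: str, rel_step: float = 1e-6
) -> SensitivityIndex:
    """Elasticity of R0 with respect to one parameter.

    Computed by a central finite difference with relative step ``rel_step``
    on the closed form; exact up to rounding for parameters R0 depends on
    polynomially.  Only the eight parameters entering R0 are accepted.
    """
    field = resolve_param_name(parameter_name)
    greek = {resolve_param_name(g): g for g in R0_PARAMETERS}
    if field not in greek:
        raise ValueError(
            f"R0 does not depend on {parameter_name!r}; supported: "
            f"{', '.join(R0_PARAMETERS)}"
        )
    value = getattr(params, field)
    if value <= 0:
        raise ValueError(f"elasticity undefined at {parameter_name} = {value}")
    r0 = r0_closed_form(params)
    if r0 <= 0:
        raise ValueError("elasticity undefined where R0 <= 0")
    hi = _replace(params, **{field: value * (1 + rel_step)})
    lo = _replace(params, **{field: value * (1 - rel_step)})
    deriv = (r0_closed_form(hi) - r0_closed_form(lo)) / (2 * rel_step * value)
    return SensitivityIndex(greek[field], float(deriv * value / r0))


def elasticity_profile(params: ModelParameters) -> list[SensitivityIndex]:
    """Elasticities of all eight R0 parameters, in reporting order."""
    return [elasticity(params, name) for name in R0_PARAMETERS]


def r0_grid(
    params: ModelParameters,
    param_a: str,
    range_a,
    param_b: str,
    range_b,
    resolution: int = 50,
) -> pd.DataFrame:
    """R0 over a 2-D parameter grid (rows: ``param_a``; columns: ``param_b``).

    ``range_a``/``range_b`` are (low, high) pairs or explicit value arrays.
    Cells where the parameter combination leaves the model's validity
    region (beta1 <= mu, or a non-positive closed-form bracket) are set to
    NaN rather than evaluated or dropped.
    """

    def axis(rng):
        arr = np.asarray(rng, dtype=float)
        if arr.shape == (2,):
            return np.linspace(arr[0], arr[1], resolution)
        return arr

    a_vals = axis(range_a)
    b_vals = axis(range_b)
    field_a = resolve_param_name(param_a)
    field_b = resolve_param_name(param_b)
    out = np.full((a_vals.size, b_vals.size), np.nan)
    for i, a in enumerate(a_vals):
        for j, b in enumerate(b_vals):
            try:
                p = _replace(params, **{field_a: a, field_b: b})
            except ValueError:
                continue
            if not p.saboteurs_viable:
                continue
            try:
                out[i, j] = r0_closed_form(p)
            except ValueError:
                continue
    frame = pd.DataFrame(out, index=a_vals, columns=b_vals)
    frame.index.name = param_a
    frame.columns.name = param_b
    return frame
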