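"""Synthetic prevalence data with the structure the calibrator assumes.

A generator configuration fixes the true rate constants, an initial
compartment split, an observable map (which compartments count as a
reported "case") and an observation-noise model.  The series is produced
by integrating the model at the true parameters, reading the observable
off at yearly grid points and adding seeded noise.  All randomness flows
through the single explicit ``seed``.

The default scenario is loosely Spain-shaped but deliberately synthetic:
the published rate baseline, a total population at the model's carrying
capacity Lambda/mu, 12 yearly observations, and an initial split that
mirrors the calibrator's initial-state rule (saboteurs 1% of the
population, the depressed mass split evenly between the primary and
secondary stages, nobody yet in treatment or recovered).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import PrevalenceSeries
from .model import ModelParameters, StateVector, simulate

__all__ = ["GeneratorConfig", "generate_initial_state", "generate_prevalence_series"]

#: Initial compartment fractions (S, B, P, D, M, C, R) of the default
#: synthetic scenario.
DEFAULT_FRACTIONS: tuple[float, ...] = (0.94, 0.01, 0.025, 0.025, 0.0, 0.0, 0.0)


@dataclass
class GeneratorConfig:
    params: ModelParameters = field(default_factory=ModelParameters.spain_baseline)
    population: float | None = None   # N0; defaults to Lambda/mu
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    n_years: int = 12
    start_year: int = 2011
    observable: str = "P+D"           # or "D"
    noise_model: str = "gaussian"     # or "poisson"
    cv: float = 0.02                  # coefficient of variation (gaussian)
    scale: float = 1.0                # persons per model unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("need at least 2 years of observations")
        if self.cv < 0:
            raise ValueError("noise level must be >= 0")
        if self.observable not in ("P+D", "D"):
            raise ValueError("observable must be 'P+D' or 'D'")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")

    @property
    def total_population(self) -> float:
        return (
            self.params.carrying_capacity
            if self.population is None
            else float(self.population)
        )


def generate_initial_state(config: GeneratorConfig) -> StateVector:
    """Deterministic split of the target population into compartments."""
    fractions = np.asarray(config.fractions, dtype=float)
    if fractions.shape != (7,) or np.any(fractions < 0):
        raise ValueError("fractions must be 7 non-negative numbers")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions.sum()!r}")
    n0 = config.total_population
    if n0 < 0:
        raise ValueError("total population must be >= 0")
    return StateVector.from_array(n0 * fractions)


def _observable(states: np.ndarray, which: str) -> np.ndarray:
    return states[:, 2] + states[:, 3] if which == "P+D" else states[:, 3]


def generate_prevalence_series(config: GeneratorConfig) -> PrevalenceSeries:
    """Simulate the true model and emit a noisy yearly case series.

    Gaussian noise has standard deviation cv * signal, truncated at zero
    (counts cannot be negative; at the default cv the truncation bias is
    negligible, see the package methods note).  Poisson noise draws counts
    with mean equal to the signal.
    """
    init = generate_initial_state(config)
    times = np.arange(config.n_years, dtype=float)
    traj = simulate(config.params, init, times)
    signal = _observable(traj.states, config.observable) * config.scale
    rng = np.random.default_rng(config.seed)
    if config.noise_model == "gaussian":
        observed = signal * (1.0 + config.cv * rng.standard_normal(signal.size))
        observed = np.clip(observed, 0.0, None)
    else:
        observed = rng.poisson(np.clip(signal, 0.0, None)).astype(float)
    years = config.start_year + np.arange(config.n_years)
    return PrevalenceSeries(years=years, observed=observed, scale=config.scale)
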