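"""Maximum-likelihood calibration of the model to yearly case counts.

The observed series is a yearly count of reported depression cases.  The
model is integrated from a reconstructed initial state and mapped to
predicted counts through an observable map (by default the total currently
depressed, P + D, times the population scale).  Three rates are free by
default — the saboteur contact rate beta1, the depression contact rate
beta2 and the pharmacological recovery rate gamma2 — with everything else
held at its configured value.

The default noise model is Gaussian with a standard deviation
proportional to the reported count (an unknown coefficient of variation,
profiled out analytically): case counts on a growing series scatter in
proportion to their size, and under this model the profiled negative
log-likelihood is minimised exactly by weighted least squares on the
relative residuals.  A constant-variance Gaussian (profiled sigma,
equivalent to ordinary least squares) and a Poisson model are available
behind a config switch.  The implementation runs a bounded trust-region
least-squares solver from a seeded Latin-hypercube multi-start.  Wald 95%
confidence intervals come from the numerical Hessian of the NLL at the
optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .model import ModelParameters, integrate_fixed_step, resolve_param_name
from .reproduction import r0_closed_form

__all__ = [
    "PrevalenceSeries",
    "FitConfig",
    "FitResult",
    "negative_log_likelihood",
    "fit_mle",
    "wald_confidence_intervals",
    "wald_from_nll",
]

logger = logging.getLogger(__name__)

_PENALTY = 1e12  # large-but-finite NLL returned on integration failure


@dataclass
class PrevalenceSeries:
    """Observed yearly case counts; ``scale`` is persons per model unit."""

    years: np.ndarray
    observed: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.years.size != self.observed.size:
            raise ValueError("years and observed must have equal length")
        if self.years.size and np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.observed < 0):
            raise ValueError("observed counts must be non-negative")

    def __len__(self) -> int:
        return self.years.size


@dataclass
class FitConfig:
    free_parameters: tuple[str, ...] = ("beta1", "beta2", "gamma2")
    base_params: ModelParameters = field(default_factory=ModelParameters.spain_baseline)
    population: float | None = None        # total N0 in persons; default Lambda/mu * scale
    depressed_split: float = 0.5           # first-year cases fraction assigned to P
    saboteur_fraction: float = 0.01        # B(0) as a fraction of N0
    observable: str = "P+D"                # or "D"
    noise_model: str = "gaussian"          # "gaussian" (sd ∝ count),
                                           # "gaussian_constant", or "poisson"
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    estimate_initial: bool = True          # treat initial depressed mass as a
                                           # nuisance parameter (multiplier on
                                           # the first observation)
    initial_multiplier_bounds: tuple[float, float] = (0.5, 2.0)
    n_starts: int = 8
    seed: int = 0
    max_nfev: int | None = None            # optimizer budget per start
    integration_step: float = 0.05         # RK4 sub-step, years

    def __post_init__(self) -> None:
        self.free_parameters = tuple(self.free_parameters)
        for name in self.free_parameters:
            resolve_param_name(name)
        if self.observable not in ("P+D", "D"):
            raise ValueError("observable must be 'P+D' or 'D'")
        if self.noise_model not in ("gaussian", "gaussian_constant", "poisson"):
            raise ValueError(
                "noise_model must be 'gaussian', 'gaussian_constant' or 'poisson'"
            )
        if not 0.0 <= self.depressed_split <= 1.0:
            raise ValueError("depressed_split must be in [0, 1]")

    def bounds_for(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        return (1e-6, 1.0)

    def params_with(self, free_values) -> ModelParameters:
        updates = dict(zip(self.free_parameters, free_values))
        return self.base_params.with_updates(**updates)


@dataclass
class FitResult:
    estimates: dict[str, float]
    nll: float
    converged: bool
    standard_errors: dict[str, float] = field(default_factory=dict)
    ci95_lower: dict[str, float] = field(default_factory=dict)
    ci95_upper: dict[str, float] = field(default_factory=dict)
    r0: float | None = None
    n_starts_converged: int = 0
    provenance: dict = field(default_factory=dict)


def _initial_state(
    series: PrevalenceSeries, config: FitConfig, multiplier: float = 1.0
) -> np.ndarray:
    """Reconstruct the model initial state from the first observation.

    The first-year cases (in model units, optionally rescaled by a fitted
    ``multiplier`` because the first observation is itself noisy) are split
    between P and D by the configured fraction; saboteurs start as a fixed
    fraction of the total; nobody starts in treatment or recovered.
    """
    scale = series.scale
    n0_persons = (
        config.base_params.carrying_capacity * scale
        if config.population is None
        else config.population
    )
    n0 = n0_persons / scale
    cases0 = multiplier * series.observed[0] / scale
    p0 = config.depressed_split * cases0
    d0 = (1.0 - config.depressed_split) * cases0
    b0 = config.saboteur_fraction * n0
    s0 = n0 - p0 - d0 - b0
    if s0 < 0:
        raise ValueError(
            "initial depressed + saboteur mass exceeds the configured total "
            "population"
        )
    return np.array([s0, b0, p0, d0, 0.0, 0.0, 0.0])


def _split_free(free_values, config: FitConfig) -> tuple[np.ndarray, float]:
    """Separate the named free parameters from the optional trailing
    initial-mass multiplier."""
    x = np.atleast_1d(np.asarray(free_values, dtype=float))
    k = len(config.free_parameters)
    if config.estimate_initial and x.size == k + 1:
        return x[:k], float(x[k])
    if x.size != k:
        raise ValueError(
            f"expected {k} free values (plus an optional initial-mass "
            f"multiplier), got {x.size}"
        )
    return x, 1.0


def _predicted_counts(free_values, series: PrevalenceSeries, config: FitConfig) -> np.ndarray:
    values, multiplier = _split_free(free_values, config)
    params = config.params_with(values)
    init = _initial_state(series, config, multiplier)
    times = (series.years - series.years[0]).astype(float)
    states = integrate_fixed_step(
        params, init, times, max_step=config.integration_step
    )
    if config.observable == "P+D":
        obs = states[:, 2] + states[:, 3]
    else:
        obs = states[:, 3]
    return obs * series.scale


def _weights(series: PrevalenceSeries, config: FitConfig) -> np.ndarray:
    """Per-observation residual weights implied by the noise model."""
    if config.noise_model == "gaussian":
        # sd proportional to the reported count: weight by 1/obs
        floor = 1e-9 * max(1.0, float(np.mean(series.observed)))
        return 1.0 / np.maximum(series.observed, floor)
    return np.ones(len(series))


def negative_log_likelihood(free_values, series: PrevalenceSeries, config: FitConfig) -> float:
    """Profiled Gaussian (or Poisson) NLL of the free parameters.

    ``"gaussian"`` takes the observation sd proportional to the reported
    count with the coefficient of variation profiled out in closed form
    (cv^2_hat = mean squared relative residual); ``"gaussian_constant"``
    profiles a constant variance (sigma^2_hat = SSR/n).  Profiling needs at
    least two observations, and the profiled NLL is floored for numerically
    perfect fits so that noise-free data evaluated at the truth returns a
    finite degenerate-fit value.  Integration failures yield a
    large-but-finite penalty and a log record rather than an exception.
    """
    n = len(series)
    if n < 2:
        raise ValueError("profiling the observation variance needs >= 2 points")
    try:
        pred = _predicted_counts(free_values, series, config)
    except (ValueError, FloatingPointError, OverflowError) as exc:
        logger.warning("model evaluation failed at %s: %s", free_values, exc)
        return _PENALTY
    if not np.all(np.isfinite(pred)):
        logger.warning("non-finite prediction at %s", free_values)
        return _PENALTY
    if config.noise_model in ("gaussian", "gaussian_constant"):
        w = _weights(series, config)
        ssr = float(np.sum((w * (series.observed - pred)) ** 2))
        rel_floor = 1e-9 if config.noise_model == "gaussian" else (
            1e-9 * max(1.0, float(np.mean(series.observed)))
        )
        sigma2 = max(ssr, n * rel_floor**2) / n
        extra = -float(np.sum(np.log(w)))  # sum of log sd_i / sigma
        return 0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + extra
    pred = np.clip(pred, 1e-12, None)
    return float(np.sum(pred - series.observed * np.log(pred)))


def _optimization_bounds(config: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    lo = [config.bounds_for(p)[0] for p in config.free_parameters]
    hi = [config.bounds_for(p)[1] for p in config.free_parameters]
    if config.estimate_initial:
        lo.append(config.initial_multiplier_bounds[0])
        hi.append(config.initial_multiplier_bounds[1])
    return np.array(lo), np.array(hi)


def _multistart_points(config: FitConfig) -> np.ndarray:
    lo, hi = _optimization_bounds(config)
    sampler = qmc.LatinHypercube(d=lo.size, seed=config.seed)
    pts = lo + sampler.random(config.n_starts) * (hi - lo)
    if config.estimate_initial:
        pts[:, -1] = 1.0  # start the initial-mass multiplier at neutral
    return pts


def fit_mle(series: PrevalenceSeries, config: FitConfig) -> FitResult:
    """Bounded multi-start maximum-likelihood fit of the free parameters.

    Gaussian noise: the profiled NLL is minimised by least squares on the
    counts, solved with a bounded trust-region-reflective solver.  Poisson
    noise: Nelder-Mead-free bounded minimisation (L-BFGS-B) of the NLL.
    Returns the best converged start with diagnostics and R0 at the
    optimum; freeing zero parameters returns the fixed values with their
    NLL only.
    """
    names = config.free_parameters
    if len(series) < 4 and names:
        raise ValueError("need >= 4 observations to fit parameters")
    if not names:
        result = FitResult(
            estimates={},
            nll=negative_log_likelihood((), series, config),
            converged=True,
        )
        result.r0 = _safe_r0(config.base_params)
        return result

    lo, hi = _optimization_bounds(config)
    starts = _multistart_points(config)

    best_x = None
    best_obj = np.inf
    n_ok = 0
    w = _weights(series, config)
    for x0 in starts:
        try:
            if config.noise_model in ("gaussian", "gaussian_constant"):

                def residuals(x):
                    try:
                        pred = _predicted_counts(x, series, config)
                    except ValueError:
                        return np.full(len(series), 1e9)
                    if not np.all(np.isfinite(pred)):
                        return np.full(len(series), 1e9)
                    return w * (pred - series.observed)

                sol = optimize.least_squares(
                    residuals,
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                    x_scale="jac",
                    max_nfev=config.max_nfev,
                )
                ok = sol.status > 0
                x, obj = sol.x, float(np.sum(sol.fun**2))
            else:
                sol = optimize.minimize(
                    lambda x: negative_log_likelihood(x, series, config),
                    x0,
                    bounds=list(zip(lo, hi)),
                    method="L-BFGS-B",
                    options={} if config.max_nfev is None else {"maxfun": config.max_nfev},
                )
                ok = bool(sol.success)
                x, obj = sol.x, float(sol.fun)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("optimizer start failed: %s", exc)
            continue
        if ok:
            n_ok += 1
        if ok and obj < best_obj:
            best_obj, best_x = obj, x

    if best_x is None:
        return FitResult(estimates={}, nll=np.inf, converged=False)

    values, multiplier = _split_free(best_x, config)
    estimates = dict(zip(names, (float(v) for v in values)))
    result = FitResult(
        estimates=estimates,
        nll=negative_log_likelihood(best_x, series, config),
        converged=True,
        n_starts_converged=n_ok,
        provenance={
            "free_parameters": list(names),
            "observable": config.observable,
            "noise_model": config.noise_model,
            "depressed_split": config.depressed_split,
            "saboteur_fraction": config.saboteur_fraction,
            "initial_multiplier": multiplier,
            "n_starts": config.n_starts,
            "seed": config.seed,
        },
    )
    result.r0 = _safe_r0(config.params_with(values))
    return result


def _safe_r0(params: ModelParameters) -> float | None:
    try:
        return r0_closed_form(params)
    except ValueError:
        return None


def _fd_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def wald_from_nll(
    nll_fn,
    estimates: dict[str, float],
    bounds: dict[str, tuple[float, float]] | None = None,
    rel_step: float = 1e-4,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Wald standard errors and 95% CIs from a generic NLL callable.

    The observed information is the FD Hessian of ``nll_fn`` at the
    estimate, inverted through its eigendecomposition.  Directions with
    non-positive (or numerically negligible) curvature carry no Fisher
    information: parameters loading on them get an infinite standard error
    and an interval spanning their feasible box (NaN when the box is
    unbounded).  All CIs are truncated at the supplied bounds.
    """
    names = list(estimates)
    x = np.array([estimates[n] for n in names])
    H = _fd_hessian(nll_fn, x, rel_step=rel_step)
    eigval, eigvec = np.linalg.eigh(H)
    tol = 1e-10 * max(1.0, float(np.max(np.abs(eigval))))
    informative = eigval > tol
    se = {}
    lower = {}
    upper = {}
    for i, name in enumerate(names):
        loads_flat = bool(np.any(np.abs(eigvec[i, ~informative]) > 1e-8))
        if loads_flat:
            var = np.inf
        else:
            var = float(np.sum(eigvec[i, informative] ** 2 / eigval[informative]))
        lo_b, hi_b = (-np.inf, np.inf)
        if bounds and name in bounds:
            lo_b, hi_b = bounds[name]
        if not np.isfinite(var):
            se[name] = np.inf
            lower[name] = lo_b if np.isfinite(lo_b) else np.nan
            upper[name] = hi_b if np.isfinite(hi_b) else np.nan
            continue
        if var <= 0:
            se[name] = np.nan
            lower[name] = np.nan
            upper[name] = np.nan
            continue
        s = float(np.sqrt(var))
        se[name] = s
        lower[name] = max(float(x[i] - 1.959963984540054 * s), lo_b)
        upper[name] = min(float(x[i] + 1.959963984540054 * s), hi_b)
    return se, lower, upper


def wald_confidence_intervals(
    fit: FitResult, series: PrevalenceSeries, config: FitConfig
) -> FitResult:
    """Attach Wald 95% confidence intervals to a converged fit.

    When the initial depressed mass was co-estimated, the observed
    information is taken over the full parameter vector including that
    nuisance multiplier, so the reported standard errors are properly
    marginal.
    """
    if not fit.converged or not fit.estimates:
        raise ValueError("confidence intervals need a converged fit with free parameters")
    names = list(fit.estimates)
    estimates = dict(fit.estimates)
    bounds = {n: config.bounds_for(n) for n in names}
    if config.estimate_initial:
        estimates["__initial_multiplier__"] = fit.provenance.get(
            "initial_multiplier", 1.0
        )
        bounds["__initial_multiplier__"] = config.initial_multiplier_bounds

    def nll_of(x):
        return negative_log_likelihood(x, series, config)

    se, lower, upper = wald_from_nll(nll_of, estimates, bounds=bounds)
    for table in (se, lower, upper):
        table.pop("__initial_multiplier__", None)
    return replace(fit, standard_errors=se, ci95_lower=lower, ci95_upper=upper)
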