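"""CSV and config I/O.

All CSVs are UTF-8 with '.' decimal separator and a required header;
provenance (config echo, package version, seed) is embedded as
``# key: value`` comment lines above the header, so every output is
reproducible from the file alone.  Numerics are written with 12
significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import FitConfig, FitResult, PrevalenceSeries
from .model import COMPARTMENTS, ModelParameters, Trajectory

__all__ = [
    "read_prevalence_csv",
    "write_prevalence_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "load_config",
    "parameters_from_config",
    "fit_result_frame",
]

_FLOAT_FMT = "%.12g"


def _provenance_lines(provenance: dict | None) -> str:
    lines = [f"# depdyn_version: {__version__}"]
    for key, value in (provenance or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_prevalence_csv(series: PrevalenceSeries, path, provenance: dict | None = None) -> None:
    path = Path(path)
    body = pd.DataFrame({"year": series.years, "cases": series.observed})
    prov = dict(provenance or {})
    prov.setdefault("scale", series.scale)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance_lines(prov))
        # shortest-repr floats: the read-back series is bit-identical
        body.to_csv(fh, index=False, lineterminator="\n")


def read_prevalence_csv(path) -> PrevalenceSeries:
    """Parse and validate a ``year,cases`` CSV (comment lines start '#').

    Malformed rows and non-increasing years raise with the offending line
    number in the message.
    """
    path = Path(path)
    scale = 1.0
    years: list[int] = []
    cases: list[float] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line[1:].strip().startswith("scale:"):
                    scale = float(line.split("scale:")[1])
                continue
            if not header_seen:
                cols = [c.strip().lower() for c in line.split(",")]
                if cols[:2] != ["year", "cases"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'year,cases', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                year = int(parts[0])
                count = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
            if years and year <= years[-1]:
                raise ValueError(
                    f"{path}:{lineno}: years must be strictly increasing "
                    f"({year} after {years[-1]})"
                )
            years.append(year)
            cases.append(count)
    if not header_seen:
        raise ValueError(f"{path}: missing 'year,cases' header")
    return PrevalenceSeries(years=np.array(years), observed=np.array(cases), scale=scale)


def write_trajectory_csv(trajectory: Trajectory, path, provenance: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance_lines(provenance))
        trajectory.to_frame().to_csv(
            fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
        )


def read_trajectory_csv(path) -> Trajectory:
    frame = pd.read_csv(path, comment="#")
    expected = ["time", *COMPARTMENTS]
    if list(frame.columns[: len(expected)]) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, got {list(frame.columns)}"
        )
    return Trajectory(
        times=frame["time"].to_numpy(),
        states=frame[list(COMPARTMENTS)].to_numpy(),
    )


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config


def parameters_from_config(config: dict) -> ModelParameters:
    """Build :class:`ModelParameters` from the ``parameters`` config block.

    Exactly the twelve model parameters are accepted (either naming
    convention); unknown keys are rejected.  ``recruitment`` may be a
    scalar or a ``{per_capita, reference_population}`` mapping.
    """
    block = config.get("parameters")
    if block is None:
        raise ValueError("config is missing the 'parameters' block")
    block = dict(block)
    recruitment = block.get("recruitment", block.get("Lambda"))
    if isinstance(recruitment, dict):
        extra = set(recruitment) - {"per_capita", "reference_population"}
        if extra:
            raise ValueError(f"unknown recruitment keys: {sorted(extra)}")
        value = float(recruitment["per_capita"]) * float(
            recruitment["reference_population"]
        )
        block.pop("recruitment", None)
        block.pop("Lambda", None)
        block["recruitment"] = value
    try:
        return ModelParameters.from_dict(block)
    except KeyError as exc:
        raise ValueError(f"unknown parameter key in config: {exc}") from exc


def fit_result_frame(fit: FitResult) -> pd.DataFrame:
    """Flat estimate/SE/CI table, one row per free parameter."""
    rows = []
    for name, est in fit.estimates.items():
        rows.append(
            {
                "parameter": name,
                "estimate": est,
                "standard_error": fit.standard_errors.get(name, np.nan),
                "ci95_lower": fit.ci95_lower.get(name, np.nan),
                "ci95_upper": fit.ci95_upper.get(name, np.nan),
            }
        )
    return pd.DataFrame(rows)


def fit_config_from_config(config: dict, params: ModelParameters) -> FitConfig:
    block = dict(config.get("fit", {}))
    kwargs = {}
    if "free" in block:
        kwargs["free_parameters"] = tuple(block.pop("free"))
    for key in (
        "population",
        "depressed_split",
        "saboteur_fraction",
        "observable",
        "noise_model",
        "n_starts",
        "seed",
        "max_nfev",
        "integration_step",
    ):
        if key in block:
            kwargs[key] = block.pop(key)
    if "bounds" in block:
        kwargs["bounds"] = {k: tuple(v) for k, v in block.pop("bounds").items()}
    if block:
        raise ValueError(f"unknown fit config keys: {sorted(block)}")
    return FitConfig(base_params=params, **kwargs)
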