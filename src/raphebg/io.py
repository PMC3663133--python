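"""Configuration loading and result serialization.

Parameter files are flat key → value maps in JSON or TOML; keys are the
parameter names of the model (``a1c`` … ``d8``, ``G``).  Results are written
as CSV data plus a JSON sidecar holding everything needed to reproduce the
run (full parameter set, scenario/protocol/clamp, solver settings, package
version, timestamp).  Numbers are serialized at full double precision
(``%.17g``) so a reload reproduces them bit for bit.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import tomllib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .experiments import ScenarioResult
from .model import (
    PARAM_NAMES,
    STATE_NAMES,
    ClampSpec,
    ConfigurationError,
    ParameterSet,
    State,
)
from .simulate import Protocol, Pulse, Trajectory
from .steady_state import Equilibrium

logger = logging.getLogger(__name__)

__all__ = [
    "default_parameter_file",
    "load_parameters",
    "save_parameters",
    "write_result",
    "read_equilibrium",
    "read_trajectory",
]

_FLOAT_FMT = "%.17g"


def default_parameter_file() -> Path:
    """Path of the bundled default parameter file."""
    return Path(__file__).parent / "data" / "default_parameters.json"


def _parse_config(path: Path) -> dict[str, Any]:
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a parameter set from a JSON or TOML file.

    Keys absent from the file are filled from the defaults (logged); unknown
    keys and non-numeric values are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    raw = _parse_config(path)
    unknown = sorted(set(raw) - set(PARAM_NAMES))
    if unknown:
        raise ConfigurationError(
            f"unknown parameter key(s) in {path}: {', '.join(unknown)}; "
            f"valid names: {', '.join(PARAM_NAMES)}"
        )
    for key, value in raw.items():
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise TypeError(f"parameter {key} in {path} must be numeric, got {value!r}")
    missing = sorted(set(PARAM_NAMES) - set(raw))
    if missing:
        logger.info("parameter file %s omits %s; using defaults", path, ", ".join(missing))
    return ParameterSet(**{k: float(v) for k, v in raw.items()})


def save_parameters(params: ParameterSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(params.as_dict(), indent=1) + "\n", encoding="utf-8")
    return path


def _sidecar(params: ParameterSet, **extra: Any) -> dict[str, Any]:
    meta: dict[str, Any] = {
        "package": "raphebg",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "parameters": params.as_dict(),
    }
    meta.update(extra)
    return meta


def _clamp_dict(clamp: ClampSpec | None) -> dict[str, Any] | None:
    if clamp is None:
        return None
    return {"variable": clamp.variable, "value": clamp.value, "scope": clamp.scope}


def _protocol_dict(protocol: Protocol | None) -> list[dict[str, Any]] | None:
    if protocol is None:
        return None
    return [dataclasses.asdict(p) for p in protocol.pulses]


def clamp_from_dict(data: dict[str, Any] | None) -> ClampSpec | None:
    return None if data is None else ClampSpec(**data)


def protocol_from_dict(data: list[dict[str, Any]] | None) -> Protocol | None:
    return None if data is None else Protocol(tuple(Pulse(**p) for p in data))


def _equilibrium_frame(eq: Equilibrium) -> pd.DataFrame:
    row: dict[str, Any] = dict(eq.state.as_dict())
    row["residual"] = eq.residual_norm
    row["stable"] = eq.stable
    row["leading_eigenvalue_real"] = eq.leading_eigenvalue.real
    row["leading_eigenvalue_imag"] = eq.leading_eigenvalue.imag
    return pd.DataFrame([row])


def write_result(
    result: ScenarioResult | Trajectory | Equilibrium,
    out_dir: str | Path,
    stem: str | None = None,
) -> list[Path]:
    """Write a result as CSV data plus a JSON metadata sidecar.

    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    if isinstance(result, Equilibrium):
        stem = stem or "equilibrium"
        csv_path = out / f"{stem}.csv"
        _equilibrium_frame(result).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
        meta = _sidecar(ParameterSet(), kind="equilibrium",
                        eigenvalues=[[z.real, z.imag] for z in result.eigenvalues])
        meta.pop("parameters")  # an Equilibrium does not carry its parameters
        paths.append(csv_path)
    elif isinstance(result, Trajectory):
        stem = stem or "trajectory"
        csv_path = out / f"{stem}.csv"
        result.to_frame().to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
        meta = _sidecar(result.params, kind="trajectory",
                        protocol=_protocol_dict(result.protocol),
                        clamp=_clamp_dict(result.clamp),
                        solver=dict(result.solver))
        paths.append(csv_path)
    elif isinstance(result, ScenarioResult):
        stem = stem or f"scenario_{result.scenario_id}"
        csv_path = out / f"{stem}.csv"
        rows = {
            "baseline": result.baseline_state.as_dict(),
            "perturbed": result.perturbed_state.as_dict(),
            "percent_change": dict(result.percent_change),
        }
        pd.DataFrame(rows).T.to_csv(csv_path, float_format=_FLOAT_FMT)
        meta = _sidecar(result.params, kind="scenario",
                        scenario=result.scenario_id,
                        description=result.description,
                        stable={"baseline": result.baseline.stable,
                                "perturbed": result.perturbed.stable})
        paths.append(csv_path)
    else:
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")

    json_path = out / f"{stem}.json"
    json_path.write_text(json.dumps(meta, indent=1) + "\n", encoding="utf-8")
    paths.append(json_path)
    return paths


def read_equilibrium(csv_path: str | Path) -> State:
    """Reload the state of a written equilibrium at full precision."""
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    return State.from_dict({name: float(frame[name].iloc[0]) for name in STATE_NAMES})


def read_trajectory(csv_path: str | Path, params: ParameterSet | None = None) -> Trajectory:
    """Reload a written trajectory at full precision."""
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    return Trajectory(
        t=frame["t"].to_numpy(),
        y=frame[list(STATE_NAMES)].to_numpy(),
        params=params if params is not None else ParameterSet(),
    )
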