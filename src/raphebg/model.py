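"""Core data types and the right-hand side of the circuit equations.

The model is a firing-rate description of the loop through which the dorsal
raphe nucleus (DRN) regulates the balance between the direct and indirect
pathways of the basal ganglia.  Eight state variables evolve in time: the
firing rates (Hz) of indirect-pathway medium spiny neurons (MI),
direct-pathway medium spiny neurons (MD), thalamus (TH), cortex (CX), dorsal
raphe (DRN) and substantia nigra pars compacta (SN), plus the striatal
concentrations (nM) of dopamine (DA) and serotonin (5HT).

All couplings are linear except dopamine release, which is the product
``G * 5HT * SN``: each SNc action potential releases striatal dopamine in
proportion to the local serotonin concentration.  Time is measured in
seconds; every decay constant ``d1 ... d8`` is per second.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "ParameterSet",
    "State",
    "ClampSpec",
    "ConfigurationError",
    "default_parameters",
    "apply_overrides",
    "rhs",
    "rhs_array",
]

#: Parameter names, grouped by the equation they appear in.
PARAM_NAMES: tuple[str, ...] = (
    "a1c", "a1da", "d1",          # indirect-pathway MSN
    "a2c", "a2da", "d2",          # direct-pathway MSN
    "a3", "a3md", "a3mi", "d3",   # thalamus
    "a4th", "d4",                 # cortex
    "a5", "a5sn", "a5cx", "d5",   # dorsal raphe
    "G", "d6",                    # striatal dopamine
    "a7", "d7",                   # striatal serotonin
    "a8", "a8drn", "d8",          # substantia nigra pars compacta
)

#: Canonical state-variable names and ordering used throughout the package.
STATE_NAMES: tuple[str, ...] = ("MI", "MD", "TH", "CX", "DRN", "DA", "5HT", "SN")

# "5HT" is not a valid Python identifier; the State attribute is named HT.
_STATE_ATTRS: tuple[str, ...] = ("MI", "MD", "TH", "CX", "DRN", "DA", "HT", "SN")

_DECAY_NAMES = ("d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8")


class ConfigurationError(ValueError):
    """Invalid parameter name, state name, or clamp specification."""


def _canonical_state_name(name: str) -> str:
    if name in ("HT", "5HT", "FiveHT"):
        return "5HT"
    if name in STATE_NAMES:
        return name
    raise ConfigurationError(
        f"unknown state variable {name!r}; valid names: {', '.join(STATE_NAMES)}"
    )


@dataclass(frozen=True)
class ParameterSet:
    """The 23 rate/gain constants of the circuit equations.

    Defaults are the published calibration, chosen so that the baseline
    steady state matches experimentally observed firing rates and
    concentrations (e.g. striatal DA 2.72 nM, DRN firing 1.41 Hz).
    """

    a1c: float = 2.333
    a1da: float = 0.167
    d1: float = 1.0
    a2c: float = 1.167
    a2da: float = 0.250
    d2: float = 1.0
    a3: float = 1.667
    a3md: float = 3.5
    a3mi: float = 2.0
    d3: float = 0.25
    a4th: float = 1.5
    d4: float = 1.0
    a5: float = 6.667
    a5sn: float = 0.01
    a5cx: float = 0.175
    d5: float = 1.5
    G: float = 0.72
    d6: float = 1.0
    a7: float = 1.2
    d7: float = 2.0
    a8: float = 58.833
    a8drn: float = 10.0
    d8: float = 10.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ConfigurationError(f"parameter {name} must be finite, got {value!r}")
        for name in _DECAY_NAMES:
            if getattr(self, name) <= 0:
                raise ConfigurationError(
                    f"decay constant {name} must be strictly positive, got {getattr(self, name)}"
                )

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "ParameterSet":
        unknown = sorted(set(values) - set(PARAM_NAMES))
        if unknown:
            raise ConfigurationError(
                f"unknown parameter(s) {', '.join(unknown)}; "
                f"valid names: {', '.join(PARAM_NAMES)}"
            )
        return cls(**{k: float(v) for k, v in values.items()})


@dataclass(frozen=True)
class State:
    """One point in the model's 8-dimensional state space.

    Attributes follow the canonical variable order; ``HT`` holds the striatal
    serotonin concentration (serialized under the key ``"5HT"``).  Firing
    rates are in Hz, concentrations in nM.
    """

    MI: float
    MD: float
    TH: float
    CX: float
    DRN: float
    DA: float
    HT: float
    SN: float

    def __post_init__(self) -> None:
        for attr in _STATE_ATTRS:
            if not math.isfinite(getattr(self, attr)):
                raise ValueError(f"state component {attr} must be finite")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, a) for a in _STATE_ATTRS], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "State":
        arr = np.asarray(list(values), dtype=float)
        if arr.shape != (8,):
            raise ValueError(f"expected 8 state components, got shape {arr.shape}")
        return cls(*(float(v) for v in arr))

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, attr))
                for name, attr in zip(STATE_NAMES, _STATE_ATTRS)}

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "State":
        data = {}
        for key, value in values.items():
            name = _canonical_state_name(key)
            attr = _STATE_ATTRS[STATE_NAMES.index(name)]
            data[attr] = float(value)
        missing = sorted(set(_STATE_ATTRS) - set(data))
        if missing:
            raise ValueError(f"missing state component(s): {', '.join(missing)}")
        return cls(**data)

    def __getitem__(self, name: str) -> float:
        attr = _STATE_ATTRS[STATE_NAMES.index(_canonical_state_name(name))]
        return float(getattr(self, attr))


@dataclass(frozen=True)
class ClampSpec:
    """Hold one state variable at a fixed value.

    ``scope="gain_term"`` substitutes the clamped value only inside the
    dopamine-release product ``G * 5HT * SN`` while the variable's own
    equation continues to evolve — the open-loop control used to demonstrate
    that serotonergic feedback, not the rest of the circuit, provides the
    compensation.  ``scope="global"`` freezes the variable everywhere.
    """

    variable: str
    value: float
    scope: str = "gain_term"

    def __post_init__(self) -> None:
        name = _canonical_state_name(self.variable)
        object.__setattr__(self, "variable", name)
        if self.scope not in ("gain_term", "global"):
            raise ConfigurationError(
                f"clamp scope must be 'gain_term' or 'global', got {self.scope!r}"
            )
        if self.scope == "gain_term" and name not in ("5HT", "SN"):
            raise ConfigurationError(
                "gain_term clamps apply only to the variables in the dopamine "
                f"release term (5HT, SN), got {name!r}"
            )
        if not math.isfinite(self.value) or self.value < 0:
            raise ConfigurationError(
                f"clamp value must be finite and non-negative, got {self.value!r}"
            )

    @property
    def index(self) -> int:
        return STATE_NAMES.index(self.variable)


def default_parameters() -> ParameterSet:
    """Return the bundled default calibration."""
    return ParameterSet()


def apply_overrides(params: ParameterSet, overrides: Mapping[str, float]) -> ParameterSet:
    """Return a copy of ``params`` with the named fields replaced.

    Raises
    ------
    ConfigurationError
        If any override key is not a parameter name.
    """
    unknown = sorted(set(overrides) - set(PARAM_NAMES))
    if unknown:
        raise ConfigurationError(
            f"unknown parameter(s) {', '.join(unknown)}; "
            f"valid names: {', '.join(PARAM_NAMES)}"
        )
    if not overrides:
        return params
    return dataclasses.replace(params, **{k: float(v) for k, v in overrides.items()})


def rhs_array(
    y: np.ndarray,
    p: ParameterSet,
    clamp: ClampSpec | None = None,
    rectify: bool = False,
) -> np.ndarray:
    """Time derivative of the state vector (canonical ordering), per second.

    ``rectify`` clips negative state components to zero before evaluation;
    it is off by default because the published steady states are those of
    the raw linear system.
    """
    y = np.asarray(y, dtype=float)
    if rectify:
        y = np.maximum(y, 0.0)
    mi, md, th, cx, drn, da, ht, sn = y

    ht_gain, sn_gain = ht, sn
    if clamp is not None:
        if clamp.scope == "global":
            # frozen variable: substitute its value everywhere
            y = y.copy()
            y[clamp.index] = clamp.value
            mi, md, th, cx, drn, da, ht, sn = y
            ht_gain, sn_gain = ht, sn
        elif clamp.variable == "5HT":
            ht_gain = clamp.value
        else:  # SN gain-term clamp
            sn_gain = clamp.value

    dy = np.array([
        p.a1c - p.a1da * da - p.d1 * mi,
        p.a2c + p.a2da * da - p.d2 * md,
        p.a3 + p.a3md * md - p.a3mi * mi - p.d3 * th,
        p.a4th * th - p.d4 * cx,
        p.a5 - p.a5cx * cx + p.a5sn * sn - p.d5 * drn,
        p.G * ht_gain * sn_gain - p.d6 * da,
        p.a7 * drn - p.d7 * ht,
        p.a8 - p.a8drn * drn - p.d8 * sn,
    ])
    if clamp is not None and clamp.scope == "global":
        dy[clamp.index] = 0.0
    return dy


def rhs(state: State, params: ParameterSet, clamp: ClampSpec | None = None,
        rectify: bool = False) -> State:
    """Evaluate the circuit equations at ``state`` and return the derivative."""
    return State.from_array(rhs_array(state.to_array(), params, clamp, rectify))
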