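"""Forward integration of the circuit, with timed parameter pulses.

Pulses model transient inputs — e.g. doubling the cortical drive to the
direct pathway (``a2c``) for one second to represent action selection.  A
pulse is active on the half-open interval ``[t_on, t_off)``, so a one-second
pulse lasts exactly one second and back-to-back pulses compose without
overlap.  Integration restarts at every pulse boundary so the discontinuity
in the parameters is never smoothed across by the adaptive stepper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.integrate

from .model import (
    PARAM_NAMES,
    STATE_NAMES,
    ClampSpec,
    ConfigurationError,
    ParameterSet,
    State,
    apply_overrides,
    rhs_array,
)
from .steady_state import ConvergenceError

logger = logging.getLogger(__name__)

__all__ = ["Pulse", "Protocol", "Trajectory", "integrate", "settle", "plot_trajectory"]

#: Default integrator tolerances (well below the 3-digit reporting precision).
RTOL = 1e-8
ATOL = 1e-10


@dataclass(frozen=True)
class Pulse:
    """A timed modification of one parameter on ``[t_on, t_off)``."""

    parameter: str
    mode: str  # "multiply" | "replace" | "add"
    value: float
    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ConfigurationError(
                f"unknown parameter {self.parameter!r}; "
                f"valid names: {', '.join(PARAM_NAMES)}"
            )
        if self.mode not in ("multiply", "replace", "add"):
            raise ConfigurationError(
                f"pulse mode must be multiply, replace or add, got {self.mode!r}"
            )
        if not self.t_on < self.t_off:
            raise ConfigurationError(
                f"pulse requires t_on < t_off, got [{self.t_on}, {self.t_off})"
            )

    def active(self, t: float) -> bool:
        return self.t_on <= t < self.t_off

    def apply(self, value: float) -> float:
        if self.mode == "multiply":
            return value * self.value
        if self.mode == "add":
            return value + self.value
        return self.value


@dataclass(frozen=True)
class Protocol:
    """An ordered collection of pulses applied on top of a base parameter set."""

    pulses: tuple[Pulse, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pulses", tuple(self.pulses))

    def params_at(self, t: float, base: ParameterSet) -> ParameterSet:
        """Effective parameters at time ``t`` (half-open pulse convention)."""
        overrides: dict[str, float] = {}
        for pulse in self.pulses:
            if pulse.active(t):
                current = overrides.get(pulse.parameter, getattr(base, pulse.parameter))
                overrides[pulse.parameter] = pulse.apply(current)
        return apply_overrides(base, overrides)

    def boundaries(self, t_end: float) -> list[float]:
        times = {0.0, float(t_end)}
        for pulse in self.pulses:
            for t in (pulse.t_on, pulse.t_off):
                if 0.0 < t < t_end:
                    times.add(float(t))
        return sorted(times)


@dataclass(frozen=True)
class Trajectory:
    """A sampled solution of the circuit equations.

    ``y`` has one row per time point, columns in the canonical state order.
    """

    t: np.ndarray
    y: np.ndarray
    params: ParameterSet
    protocol: Protocol | None = None
    clamp: ClampSpec | None = None
    solver: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.y.shape != (self.t.size, 8):
            raise ValueError(f"trajectory shape mismatch: {self.y.shape} vs {self.t.size} times")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.y))):
            raise ValueError("trajectory contains non-finite values")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def series(self, name: str) -> np.ndarray:
        return self.y[:, STATE_NAMES.index("5HT" if name == "HT" else name)]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series(name)

    @property
    def final_state(self) -> State:
        return State.from_array(self.y[-1])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.y, columns=list(STATE_NAMES))
        frame.insert(0, "t", self.t)
        return frame


def integrate(
    params: ParameterSet,
    initial: State,
    t_end: float,
    protocol: Protocol | None = None,
    clamp: ClampSpec | None = None,
    output_step: float = 0.01,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the circuit from ``initial`` for ``t_end`` seconds.

    The solution is sampled on the uniform grid ``0, output_step, ...,
    t_end``; pulse boundaries restart the integrator so parameter steps are
    sharp.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if output_step <= 0:
        raise ValueError("output_step must be positive")

    n_steps = int(round(t_end / output_step))
    grid = np.linspace(0.0, n_steps * output_step, n_steps + 1)
    if grid[-1] < t_end - 1e-12:
        grid = np.append(grid, t_end)

    proto = protocol if protocol is not None else Protocol()
    boundaries = proto.boundaries(t_end)

    times = [0.0]
    states = [initial.to_array()]
    y = initial.to_array()
    for seg_start, seg_end in zip(boundaries[:-1], boundaries[1:]):
        # parameters are constant inside a segment; sample them mid-segment
        p_seg = proto.params_at(0.5 * (seg_start + seg_end), params)
        t_eval = grid[(grid > seg_start + 1e-12) & (grid <= seg_end + 1e-12)]
        sol = scipy.integrate.solve_ivp(
            lambda t, y: rhs_array(y, p_seg, clamp),
            (seg_start, seg_end),
            y,
            method=method,
            t_eval=None if t_eval.size == 0 else np.unique(np.append(t_eval, seg_end)),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise ConvergenceError(
                f"integrator failed near t = {sol.t[-1]:.6g} s: {sol.message}",
                float(np.max(np.abs(rhs_array(sol.y[:, -1], p_seg, clamp)))),
            )
        y = sol.y[:, -1]
        keep = sol.t <= seg_end + 1e-12
        for ti, yi in zip(sol.t[keep], sol.y[:, keep].T):
            if np.isclose(grid, ti, atol=1e-9).any() and ti > times[-1] + 1e-12:
                times.append(float(ti))
                states.append(yi)

    t_arr = np.array(times)
    y_arr = np.array(states)
    if np.any(y_arr < -atol):
        worst = STATE_NAMES[int(np.argmin(y_arr.min(axis=0)))]
        logger.warning("negative excursion during integration (most negative: %s = %.4g)",
                       worst, float(y_arr.min()))
    return Trajectory(
        t=t_arr, y=y_arr, params=params, protocol=protocol, clamp=clamp,
        solver={"method": method, "rtol": rtol, "atol": atol, "output_step": output_step},
    )


def settle(
    params: ParameterSet,
    initial: State,
    clamp: ClampSpec | None = None,
    residual_tol: float = 1e-9,
    t_cap: float = 2000.0,
    chunk: float = 50.0,
) -> State:
    """Integrate until the system is stationary and return the final state.

    Serves as the independent long-time oracle for the algebraic steady-state
    solvers: it knows nothing about the quadratic reduction.

    Raises
    ------
    ConvergenceError
        If max |dy/dt| has not fallen below ``residual_tol`` by ``t_cap``.
    """
    y = initial.to_array()
    t = 0.0
    while t < t_cap:
        span = min(chunk, t_cap - t)
        sol = scipy.integrate.solve_ivp(
            lambda tt, yy: rhs_array(yy, params, clamp),
            (0.0, span), y, method="LSODA", rtol=1e-11, atol=1e-12,
        )
        if not sol.success:
            raise ConvergenceError(
                f"integrator failed near t = {t + sol.t[-1]:.6g} s: {sol.message}",
                float(np.max(np.abs(rhs_array(sol.y[:, -1], params, clamp)))),
            )
        y = sol.y[:, -1]
        t += span
        residual = float(np.max(np.abs(rhs_array(y, params, clamp))))
        if residual < residual_tol:
            return State.from_array(y)
    raise ConvergenceError(
        f"system did not settle within {t_cap:.0f} s", residual, State.from_array(y)
    )


def plot_trajectory(
    trajectory: Trajectory,
    path: str | None = None,
    variables: Sequence[str] = ("MD", "MI"),
):
    """Plot selected state series against time (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    colors = {"MD": "tab:red", "MI": "tab:blue"}
    for name in variables:
        ax.plot(trajectory.t, trajectory.series(name), label=name,
                color=colors.get(name))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("firing rate (Hz) / concentration (nM)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
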