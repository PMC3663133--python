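"""Named perturbation scenarios and their steady-state comparisons.

Each scenario perturbs the circuit the way a physiological or
pharmacological intervention would and asks how far the equilibrium moves:

* ``A1`` — SNc cell loss (Parkinsonian degeneration): raise ``d8`` 10 → 17.
* ``A2`` — the A1 lesion with the serotonergic compensation disabled: the
  5-HT value inside the dopamine-release gain term is clamped at its normal
  0.846 nM while the 5-HT equation itself still evolves.
* ``B``  — loss of 5-HT receptors on DA terminals: halve the gain ``G``.
* ``C``  — reduced 5-HT release per raphe spike: halve ``a7``.
* ``D``  — SSRI-like slowed 5-HT clearance: lower ``d7`` 2 → 1.
* ``E``  — deep brain stimulation of the SNc: lower ``d8`` 10 → 5.
* ``F1``/``F2`` — an external nucleus driving the DRN: scale ``a5`` by
  1.5 / 0.5 to deliberately unbalance the pathways.
* ``FIG2`` — phasic action-selection input: double the cortical drive to the
  direct pathway (``a2c``) between t = 1 s and t = 2 s and record the
  transient (returns a trajectory, not a steady state).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    STATE_NAMES,
    ClampSpec,
    ConfigurationError,
    ParameterSet,
    State,
    apply_overrides,
    default_parameters,
)
from .simulate import Protocol, Pulse, Trajectory, integrate, settle
from .steady_state import Equilibrium, steady_state_closed_form

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "SCENARIOS",
    "scenario_parameters",
    "run_scenario",
    "run_all",
    "percent_change_table",
    "results_table",
]

#: Relative agreement demanded between the algebraic equilibrium and the
#: long-time integration cross-check.
CROSS_CHECK_RTOL = 1e-6


@dataclass(frozen=True)
class Scenario:
    """A named perturbation: absolute overrides, multiplicative factors,
    an optional clamp, and an optional pulse protocol."""

    id: str
    description: str
    overrides: Mapping[str, float] = field(default_factory=dict)
    factors: Mapping[str, float] = field(default_factory=dict)
    clamp: ClampSpec | None = None
    protocol: Protocol | None = None

    def parameters(self, base: ParameterSet) -> ParameterSet:
        changed = dict(self.overrides)
        for name, factor in self.factors.items():
            changed[name] = getattr(base, name) * factor
        return apply_overrides(base, changed)


#: The bundled scenario catalogue.
SCENARIOS: dict[str, Scenario] = {
    "A1": Scenario("A1", "SNc cell loss: d8 raised from 10 to 17",
                   overrides={"d8": 17.0}),
    "A2": Scenario("A2", "SNc cell loss with the 5-HT gain-term feedback disabled "
                         "(clamped at the normal 0.846 nM)",
                   overrides={"d8": 17.0},
                   clamp=ClampSpec("5HT", 0.846, scope="gain_term")),
    "B": Scenario("B", "5-HT -> DA release gain G halved (0.72 to 0.36)",
                  overrides={"G": 0.36}),
    "C": Scenario("C", "5-HT release per DRN spike halved (a7 1.2 to 0.6)",
                  overrides={"a7": 0.6}),
    "D": Scenario("D", "SSRI-like slowed 5-HT clearance (d7 2 to 1)",
                  overrides={"d7": 1.0}),
    "E": Scenario("E", "Deep brain stimulation of the SNc (d8 10 to 5)",
                  overrides={"d8": 5.0}),
    "F1": Scenario("F1", "External DRN drive a5 increased by 50%",
                   factors={"a5": 1.5}),
    "F2": Scenario("F2", "External DRN drive a5 decreased by 50%",
                   factors={"a5": 0.5}),
    "FIG2": Scenario("FIG2", "Phasic cortical input: a2c doubled on [1 s, 2 s)",
                     protocol=Protocol((Pulse("a2c", "multiply", 2.0, 1.0, 2.0),))),
}


@dataclass(frozen=True)
class ScenarioResult:
    """Baseline vs perturbed equilibria with per-variable percent changes."""

    scenario_id: str
    description: str
    baseline: Equilibrium
    perturbed: Equilibrium
    percent_change: Mapping[str, float]
    params: ParameterSet = ParameterSet()  # base (unperturbed) parameters

    @property
    def baseline_state(self) -> State:
        return self.baseline.state

    @property
    def perturbed_state(self) -> State:
        return self.perturbed.state


def scenario_parameters(scenario_id: str, params: ParameterSet | None = None) -> ParameterSet:
    """Parameter set of a catalogue scenario relative to ``params``."""
    scenario = _lookup(scenario_id)
    base = params if params is not None else default_parameters()
    return scenario.parameters(base)


def _lookup(scenario_id: str) -> Scenario:
    try:
        return SCENARIOS[scenario_id.upper()]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {scenario_id!r}; catalogue: {', '.join(SCENARIOS)}"
        ) from None


def percent_change_table(baseline: State, perturbed: State) -> dict[str, float]:
    """Signed percent change of every state variable, perturbed vs baseline.

    Requires nonzero baseline components.
    """
    table = {}
    for name in STATE_NAMES:
        b, p = baseline[name], perturbed[name]
        if b == 0:
            raise ValueError(f"baseline component {name} is zero; percent change undefined")
        table[name] = 100.0 * (p - b) / b
    return table


def run_scenario(
    scenario: str | Scenario,
    params: ParameterSet | None = None,
    cross_check: bool = True,
) -> ScenarioResult | Trajectory:
    """Run one catalogue scenario (or a custom :class:`Scenario`).

    Steady-state scenarios return a :class:`ScenarioResult` whose equilibria
    are solved algebraically and, when ``cross_check`` is on, verified
    against a long-time integration to 1e-6 relative agreement.  The phasic
    scenario (``FIG2``) returns the 12 s :class:`Trajectory` instead and logs
    its summary statistics.
    """
    spec = scenario if isinstance(scenario, Scenario) else _lookup(scenario)
    base = params if params is not None else default_parameters()

    baseline = steady_state_closed_form(base)
    if spec.protocol is not None:
        trajectory = integrate(
            base, baseline.state, t_end=12.0, protocol=spec.protocol,
            clamp=spec.clamp, output_step=0.01,
        )
        _log_phasic_summary(trajectory, baseline.state)
        return trajectory

    perturbed_params = spec.parameters(base)
    perturbed = steady_state_closed_form(perturbed_params, clamp=spec.clamp)
    if cross_check:
        _verify_against_settle(perturbed_params, spec.clamp, perturbed)
    return ScenarioResult(
        scenario_id=spec.id,
        description=spec.description,
        baseline=baseline,
        perturbed=perturbed,
        percent_change=percent_change_table(baseline.state, perturbed.state),
        params=base,
    )


def _verify_against_settle(params: ParameterSet, clamp: ClampSpec | None,
                           equilibrium: Equilibrium) -> None:
    settled = settle(params, equilibrium.state, clamp=clamp).to_array()
    target = equilibrium.state.to_array()
    scale = np.maximum(np.abs(target), 1.0)
    err = float(np.max(np.abs(settled - target) / scale))
    if err > CROSS_CHECK_RTOL:
        raise RuntimeError(
            f"algebraic equilibrium disagrees with long-time integration "
            f"(relative error {err:.3e})"
        )


def _log_phasic_summary(trajectory: Trajectory, baseline: State) -> None:
    md = trajectory.series("MD")
    t = trajectory.t
    peak = float(md.max())
    undershoot = float(md.min())
    after_peak = t[int(np.argmax(md)):][np.abs(md[int(np.argmax(md)):] - baseline.MD)
                                        < 0.01 * baseline.MD]
    t_return = float(after_peak[0]) if after_peak.size else float("nan")
    logger.info(
        "phasic input: peak MD %.3f Hz, return within 1%% of baseline at t = %.2f s, "
        "undershoot minimum %.3f Hz", peak, t_return, undershoot,
    )


def run_all(
    params: ParameterSet | None = None, cross_check: bool = True
) -> dict[str, ScenarioResult | Trajectory]:
    """Run the whole catalogue, continuing past per-scenario failures."""
    results: dict[str, ScenarioResult | Trajectory] = {}
    failures: dict[str, Exception] = {}
    for scenario_id in SCENARIOS:
        try:
            results[scenario_id] = run_scenario(scenario_id, params, cross_check)
        except Exception as exc:  # noqa: BLE001 - collected and re-raised below
            logger.error("scenario %s failed: %s", scenario_id, exc)
            failures[scenario_id] = exc
    if failures and not results:
        raise RuntimeError(f"all scenarios failed: {failures}")
    return results


def results_table(
    results: Mapping[str, ScenarioResult | Trajectory],
    scenario_ids: tuple[str, ...],
) -> pd.DataFrame:
    """Steady-state comparison table: rows = variables, columns = Normal + scenarios."""
    first = next(r for r in results.values() if isinstance(r, ScenarioResult))
    data = {"Normal": [first.baseline_state[n] for n in STATE_NAMES]}
    for sid in scenario_ids:
        result = results[sid]
        if not isinstance(result, ScenarioResult):
            raise ValueError(f"scenario {sid} has no steady state to tabulate")
        data[sid] = [result.perturbed_state[n] for n in STATE_NAMES]
    return pd.DataFrame(data, index=list(STATE_NAMES))
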