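"""Closed-form and numerical equilibria, Jacobian, and stability."""

import numpy as np
import pytest

from raphebg import (
    STATE_NAMES,
    ClampSpec,
    NoPhysicalEquilibriumError,
    ParameterSet,
    State,
    apply_overrides,
    assess_stability,
    default_parameters,
    jacobian,
    rhs_array,
    steady_state_closed_form,
    steady_state_numeric,
)

from reference import BASELINE, half_unit


def relative_gap(a: State, b: State) -> float:
    x, y = a.to_array(), b.to_array()
    return float(np.max(np.abs(x - y) / np.maximum(np.abs(x), 1.0)))


class TestClosedForm:
    def test_baseline_matches_reference(self, baseline):
        for name, printed in BASELINE.items():
            assert baseline.state[name] == pytest.approx(
                float(printed), abs=half_unit(printed)), name
        assert baseline.residual_norm < 1e-8
        assert baseline.stable

    def test_snc_degeneration_equilibrium(self, defaults):
        eq = steady_state_closed_form(apply_overrides(defaults, {"d8": 17}))
        assert eq.state.DA == pytest.approx(1.98, abs=0.005)
        assert eq.state.SN == pytest.approx(2.271, abs=0.001)
        assert eq.state.DRN == pytest.approx(2.02, abs=0.005)

    def test_gain_term_clamp_equilibrium(self, defaults):
        """With serotonergic feedback to DA release disabled, the same lesion
        bites much harder and free 5-HT rises further."""
        eq = steady_state_closed_form(
            apply_overrides(defaults, {"d8": 17}),
            clamp=ClampSpec("5HT", 0.846),
        )
        assert eq.state.DA == pytest.approx(1.124, abs=0.0005)
        assert eq.state.DRN == pytest.approx(2.75, abs=0.005)
        assert eq.state.HT == pytest.approx(1.648, abs=0.001)

    def test_zero_gain_is_linear_with_zero_da(self, defaults):
        eq = steady_state_closed_form(apply_overrides(defaults, {"G": 0.0}))
        assert eq.state.DA == 0.0
        assert eq.state.MI == pytest.approx(defaults.a1c / defaults.d1)
        assert eq.residual_norm < 1e-10

    def test_clamp_at_equilibrium_value_is_neutral(self, defaults, baseline_state):
        """Clamping the gain-term 5-HT at its own equilibrium value must not
        move the equilibrium."""
        eq = steady_state_closed_form(
            defaults, clamp=ClampSpec("5HT", baseline_state.HT))
        assert relative_gap(eq.state, baseline_state) < 1e-9

    def test_no_physical_root_reports_both_roots(self):
        # overwhelming cortical inhibition of the DRN drives both roots negative
        params = apply_overrides(default_parameters(), {"a5": -80.0})
        with pytest.raises(NoPhysicalEquilibriumError) as err:
            steady_state_closed_form(params)
        assert len(err.value.roots) == 2

    def test_global_drn_clamp_solved_directly(self, defaults, baseline_state):
        eq = steady_state_closed_form(
            defaults, clamp=ClampSpec("DRN", baseline_state.DRN, scope="global"))
        assert relative_gap(eq.state, baseline_state) < 1e-9


class TestNumericSolver:
    def test_agrees_with_closed_form_at_baseline(self, defaults, baseline_state):
        guess = State.from_dict({k: float(v) for k, v in BASELINE.items()})
        eq = steady_state_numeric(defaults, initial_guess=guess)
        assert eq.residual_norm < 1e-10
        assert relative_gap(eq.state, baseline_state) < 1e-8

    def test_ssri_scenario(self, defaults, baseline_state):
        eq = steady_state_numeric(apply_overrides(defaults, {"d7": 1}),
                                  initial_guess=baseline_state)
        assert eq.state.DRN == pytest.approx(0.787, abs=0.0005)
        assert eq.state.HT == pytest.approx(0.944, abs=0.0005)
        assert eq.state.DA == pytest.approx(3.47, abs=0.01)

    def test_dbs_scenario(self, defaults, baseline_state):
        eq = steady_state_numeric(apply_overrides(defaults, {"d8": 5}),
                                  initial_guess=baseline_state)
        assert eq.state.SN == pytest.approx(10.176, abs=0.001)
        assert eq.state.DRN == pytest.approx(0.795, abs=0.0005)

    def test_gain_term_clamp_agrees_with_closed_form(self, defaults, baseline_state):
        params = apply_overrides(defaults, {"d8": 17})
        clamp = ClampSpec("5HT", 0.846)
        cf = steady_state_closed_form(params, clamp=clamp)
        num = steady_state_numeric(params, clamp=clamp, initial_guess=baseline_state)
        assert relative_gap(cf.state, num.state) < 1e-8


class TestJacobian:
    def test_constant_entries(self, defaults, baseline_state):
        J = jacobian(defaults, baseline_state)
        i = STATE_NAMES.index
        assert J[i("CX"), i("TH")] == 1.5          # thalamic drive of cortex
        assert J[i("MI"), i("DA")] == -0.167       # DA inhibits indirect MSNs
        assert J[i("SN"), i("DRN")] == -10.0       # raphe inhibits SNc
        assert J[i("DRN"), i("CX")] == -0.175

    def test_da_row_is_state_dependent(self, defaults, baseline_state):
        J = jacobian(defaults, baseline_state)
        i = STATE_NAMES.index
        assert J[i("DA"), i("5HT")] == pytest.approx(0.72 * baseline_state.SN)
        assert J[i("DA"), i("SN")] == pytest.approx(0.72 * baseline_state.HT)
        assert J[i("DA"), i("5HT")] == pytest.approx(3.218, abs=0.01)

    def test_matches_finite_differences(self, defaults, baseline_state):
        J = jacobian(defaults, baseline_state)
        y0 = baseline_state.to_array()
        eps = 1e-6
        for j in range(8):
            step = np.zeros(8)
            step[j] = eps
            col = (rhs_array(y0 + step, defaults) - rhs_array(y0 - step, defaults)) / (2 * eps)
            np.testing.assert_allclose(J[:, j], col, atol=1e-6)

    def test_global_clamp_zeroes_row_and_column(self, defaults, baseline_state):
        clamp = ClampSpec("5HT", 0.846, scope="global")
        J = jacobian(defaults, baseline_state, clamp)
        i = STATE_NAMES.index("5HT")
        assert np.all(J[i, :] == 0)
        assert np.all(J[:, i] == 0)


class TestStability:
    def test_baseline_is_stable(self, defaults, baseline):
        eq = assess_stability(defaults, baseline.state)
        assert eq.stable
        assert np.all(eq.eigenvalues.real < 0)
        assert eq.leading_eigenvalue.real == max(eq.eigenvalues.real)

    def test_decoupled_system_has_decay_eigenvalues(self):
        # zero every cross-coupling: eigenvalues must be the decay constants
        zeros = {name: 0.0 for name in
                 ("a1da", "a2da", "a3md", "a3mi", "a4th", "a5sn", "a5cx",
                  "G", "a7", "a8drn")}
        params = apply_overrides(default_parameters(), zeros)
        state = State(1, 1, 1, 1, 1, 1, 1, 1)
        eigs = np.sort(assess_stability(params, state).eigenvalues.real)
        expected = np.sort([-params.d1, -params.d2, -params.d3, -params.d4,
                            -params.d5, -params.d6, -params.d7, -params.d8])
        np.testing.assert_allclose(eigs, expected, atol=1e-12)


class TestHomeostasisSweep:
    def test_snc_decay_sweep_is_monotone(self, defaults):
        """As SNc firing is progressively lost (d8 from 10 to 17), SN and DA
        fall monotonically while the compensating DRN and 5-HT rise."""
        d8_values = np.linspace(10.0, 17.0, 15)
        states = [steady_state_closed_form(apply_overrides(defaults, {"d8": v})).state
                  for v in d8_values]
        sn = np.array([s.SN for s in states])
        da = np.array([s.DA for s in states])
        drn = np.array([s.DRN for s in states])
        ht = np.array([s.HT for s in states])
        assert np.all(np.diff(sn) < 0)
        assert np.all(np.diff(da) < 0)
        assert np.all(np.diff(drn) > 0)
        assert np.all(np.diff(ht) > 0)
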