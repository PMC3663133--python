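"""Equilibria of the circuit: closed-form reduction, root finding, stability.

At steady state every equation except the dorsal-raphe balance can be solved
by forward substitution: 5HT and SN are affine in DRN, striatal DA is their
product (times the gain ``G``) and hence quadratic in DRN, and MI, MD, TH,
CX are affine in DA.  Substituting everything into the DRN balance leaves a
single quadratic in DRN; with the serotonin gain-term clamp the DA term is
affine and the balance is linear.  The closed-form solver extracts that
polynomial exactly and selects the physical root (DRN > 0, SN >= 0,
preferring the locally stable one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.optimize

from .model import (
    STATE_NAMES,
    ClampSpec,
    ParameterSet,
    State,
    rhs_array,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Equilibrium",
    "NoPhysicalEquilibriumError",
    "ConvergenceError",
    "steady_state_closed_form",
    "steady_state_numeric",
    "jacobian",
    "assess_stability",
]

RESIDUAL_TOL = 1e-8         # any returned equilibrium satisfies max|rhs| below this
NUMERIC_RESIDUAL_TOL = 1e-10


class NoPhysicalEquilibriumError(RuntimeError):
    """No equilibrium with DRN > 0 and SN >= 0 exists for these parameters."""

    def __init__(self, roots):
        self.roots = tuple(roots)
        super().__init__(
            "no physical equilibrium (DRN > 0, SN >= 0); "
            f"DRN roots of the reduced polynomial: {self.roots}"
        )


class ConvergenceError(RuntimeError):
    """A numerical solver failed to reach the requested residual."""

    def __init__(self, message: str, residual: float, state: State | None = None):
        self.residual = residual
        self.state = state
        super().__init__(f"{message} (final residual {residual:.3e})")


@dataclass(frozen=True)
class Equilibrium:
    """A steady state together with its local stability diagnosis.

    ``residual_norm`` is max |dy/dt| over the eight components; ``stable``
    is true iff every Jacobian eigenvalue has negative real part (for a
    globally clamped variable the structurally zero mode is excluded).
    """

    state: State
    residual_norm: float
    stable: bool
    eigenvalues: np.ndarray

    @property
    def leading_eigenvalue(self) -> complex:
        return complex(self.eigenvalues[int(np.argmax(self.eigenvalues.real))])


def _forward(drn: float, p: ParameterSet, clamp: ClampSpec | None) -> np.ndarray:
    """State implied by the non-DRN balances for a given DRN value."""

    def clamped(name: str, expr: float) -> float:
        if clamp is not None and clamp.scope == "global" and clamp.variable == name:
            return clamp.value
        return expr

    ht = clamped("5HT", p.a7 * drn / p.d7)
    sn = clamped("SN", (p.a8 - p.a8drn * drn) / p.d8)
    ht_gain, sn_gain = ht, sn
    if clamp is not None and clamp.scope == "gain_term":
        if clamp.variable == "5HT":
            ht_gain = clamp.value
        else:
            sn_gain = clamp.value
    da = clamped("DA", p.G * ht_gain * sn_gain / p.d6)
    mi = clamped("MI", (p.a1c - p.a1da * da) / p.d1)
    md = clamped("MD", (p.a2c + p.a2da * da) / p.d2)
    th = clamped("TH", (p.a3 + p.a3md * md - p.a3mi * mi) / p.d3)
    cx = clamped("CX", p.a4th * th / p.d4)
    return np.array([mi, md, th, cx, drn, da, ht, sn])


def _drn_residual(drn: float, p: ParameterSet, clamp: ClampSpec | None) -> float:
    y = _forward(drn, p, clamp)
    return p.a5 - p.a5cx * y[3] + p.a5sn * y[7] - p.d5 * drn


def _drn_polynomial(p: ParameterSet, clamp: ClampSpec | None) -> np.ndarray:
    # The residual is a polynomial of degree <= 2 in DRN (one bilinear term,
    # everything else affine), so three evaluations determine it exactly.
    r0 = _drn_residual(0.0, p, clamp)
    r1 = _drn_residual(1.0, p, clamp)
    r2 = _drn_residual(2.0, p, clamp)
    a = (r2 - 2.0 * r1 + r0) / 2.0
    b = r1 - r0 - a
    return np.array([a, b, r0])


@lru_cache(maxsize=1)
def _reference_drn() -> float:
    """Baseline DRN of the default calibration, used only to break ties."""
    poly = _drn_polynomial(ParameterSet(), None)
    roots = [r.real for r in np.roots(poly) if abs(r.imag) < 1e-12 and r.real > 0]
    return min(roots, key=lambda r: abs(r - 1.41))


def _finish(p: ParameterSet, y: np.ndarray, clamp: ClampSpec | None) -> Equilibrium:
    residual = float(np.max(np.abs(rhs_array(y, p, clamp))))
    state = State.from_array(y)
    if np.any(y < 0):
        negative = [n for n, v in zip(STATE_NAMES, y) if v < 0]
        logger.warning("equilibrium has negative component(s): %s", ", ".join(negative))
    eq = assess_stability(p, state, clamp)
    return Equilibrium(state=state, residual_norm=residual,
                       stable=eq.stable, eigenvalues=eq.eigenvalues)


def steady_state_closed_form(
    params: ParameterSet, clamp: ClampSpec | None = None
) -> Equilibrium:
    """Solve the steady state by algebraic reduction to a quadratic in DRN.

    Returns the physical root (DRN > 0, SN >= 0).  If two roots qualify the
    locally stable one is kept; if both are stable the one closest to the
    baseline DRN is returned with a warning.

    Raises
    ------
    NoPhysicalEquilibriumError
        If no root lies in the physical region (both roots are reported).
    """
    if clamp is not None and clamp.scope == "global" and clamp.variable == "DRN":
        return _finish(params, _forward(clamp.value, params, clamp), clamp)

    poly = _drn_polynomial(params, clamp)
    if abs(poly[0]) < 1e-14 * max(1.0, abs(poly[1]), abs(poly[2])):
        if poly[1] == 0:
            raise NoPhysicalEquilibriumError(())
        roots = [-poly[2] / poly[1]]
    else:
        roots = list(np.roots(poly))

    real_roots = [float(r.real) for r in np.atleast_1d(roots) if abs(np.imag(r)) < 1e-10]
    candidates = []
    for drn in real_roots:
        y = _forward(drn, params, clamp)
        if drn > 0 and y[7] >= 0:
            candidates.append(_finish(params, y, clamp))
    if not candidates:
        raise NoPhysicalEquilibriumError(real_roots)
    if len(candidates) > 1:
        stable = [c for c in candidates if c.stable]
        if len(stable) == 1:
            return stable[0]
        pool = stable if stable else candidates
        if len(stable) > 1:
            logger.warning(
                "multiple stable physical equilibria; returning the one closest "
                "to the baseline DRN"
            )
        ref = _reference_drn()
        return min(pool, key=lambda c: abs(c.state.DRN - ref))
    return candidates[0]


def steady_state_numeric(
    params: ParameterSet,
    clamp: ClampSpec | None = None,
    initial_guess: State | None = None,
) -> Equilibrium:
    """Solve the steady state by multidimensional root finding on the RHS.

    Independent numerical cross-check of :func:`steady_state_closed_form`;
    the two agree to well below the solvers' residual tolerances whenever
    they converge to the same basin.
    """
    if initial_guess is None:
        y0 = np.ones(8)
    else:
        y0 = initial_guess.to_array()

    if clamp is not None and clamp.scope == "global":
        frozen = clamp.index
        free = [i for i in range(8) if i != frozen]

        def fun(z: np.ndarray) -> np.ndarray:
            y = np.empty(8)
            y[free] = z
            y[frozen] = clamp.value
            return rhs_array(y, params, clamp)[free]

        sol = scipy.optimize.root(fun, y0[free], method="hybr", tol=1e-13)
        y = np.empty(8)
        y[free] = sol.x
        y[frozen] = clamp.value
    else:
        def fun(y: np.ndarray) -> np.ndarray:
            return rhs_array(y, params, clamp)

        def jac(y: np.ndarray) -> np.ndarray:
            return jacobian(params, State.from_array(y), clamp)

        sol = scipy.optimize.root(fun, y0, jac=jac, method="hybr", tol=1e-13)
        y = sol.x

    residual = float(np.max(np.abs(rhs_array(y, params, clamp))))
    if residual >= NUMERIC_RESIDUAL_TOL:
        raise ConvergenceError(
            "root finder did not reach the residual tolerance",
            residual, State.from_array(y),
        )
    return _finish(params, y, clamp)


def jacobian(
    params: ParameterSet, state: State, clamp: ClampSpec | None = None
) -> np.ndarray:
    """Analytic 8x8 Jacobian of the RHS at ``state`` (per second).

    Only the dopamine row depends on the state (through the bilinear release
    term); every other row is constant in the state.
    """
    p = params
    ht_gain, sn_gain = state.HT, state.SN
    dda_dht, dda_dsn = p.G * sn_gain, p.G * ht_gain
    if clamp is not None and clamp.scope == "gain_term":
        if clamp.variable == "5HT":
            dda_dht, dda_dsn = 0.0, p.G * clamp.value
        else:
            dda_dht, dda_dsn = p.G * clamp.value, 0.0

    J = np.array([
        # MI      MD     TH      CX       DRN      DA       5HT      SN
        [-p.d1,   0,     0,      0,       0,      -p.a1da,  0,       0],
        [0,      -p.d2,  0,      0,       0,       p.a2da,  0,       0],
        [-p.a3mi, p.a3md, -p.d3, 0,       0,       0,       0,       0],
        [0,       0,     p.a4th, -p.d4,   0,       0,       0,       0],
        [0,       0,     0,      -p.a5cx, -p.d5,   0,       0,       p.a5sn],
        [0,       0,     0,      0,       0,      -p.d6,    dda_dht, dda_dsn],
        [0,       0,     0,      0,       p.a7,    0,      -p.d7,    0],
        [0,       0,     0,      0,      -p.a8drn, 0,       0,      -p.d8],
    ], dtype=float)
    if clamp is not None and clamp.scope == "global":
        J[clamp.index, :] = 0.0
        J[:, clamp.index] = 0.0
    return J


def assess_stability(
    params: ParameterSet, eq_state: State, clamp: ClampSpec | None = None
) -> Equilibrium:
    """Eigenvalue stability analysis of the linearization at ``eq_state``."""
    J = jacobian(params, eq_state, clamp)
    eigenvalues = np.linalg.eigvals(J)
    real_parts = eigenvalues.real
    if clamp is not None and clamp.scope == "global":
        # the frozen variable contributes a structurally zero mode
        keep = np.ones(8, dtype=bool)
        keep[int(np.argmin(np.abs(eigenvalues)))] = False
        stable = bool(np.all(real_parts[keep] < 0))
    else:
        stable = bool(np.all(real_parts < 0))
    residual = float(np.max(np.abs(rhs_array(eq_state.to_array(), params, clamp))))
    return Equilibrium(state=eq_state, residual_norm=residual,
                       stable=stable, eigenvalues=eigenvalues)
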