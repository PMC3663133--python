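# Methods

## Model

The package implements a deterministic firing-rate model of the circuit by
which the dorsal raphe nucleus (DRN) stabilizes the balance between the
direct and indirect pathways of the basal ganglia. Eight state variables
evolve under coupled ordinary differential equations: the firing rates (Hz)
of indirect-pathway MSNs (`MI`), direct-pathway MSNs (`MD`), thalamus
(`TH`), cortex (`CX`), DRN (`DRN`) and SNc (`SN`), plus striatal dopamine
(`DA`) and serotonin (`5HT`) concentrations (nM). Time is in seconds.

Every interaction is an affine rate law with a first-order decay, except
dopamine release, which is the bilinear term `G·5HT·SN`: dopamine enters the
striatum in proportion to SNc firing, scaled by the local serotonin
concentration. This single nonlinearity carries the circuit's homeostatic
mechanism — when anything depresses thalamo-cortical activity, cortical
inhibition of the DRN is withdrawn, striatal 5-HT rises, and dopamine
release per SNc spike increases.

### Assumptions and simplifications

- Firing rates are population (or task-specific single-neuron) averages; no
  spiking, bursting, conductances, or within-nucleus dynamics.
- The indirect pathway's GPe/STN subcircuit, the hyperdirect loop, synaptic
  plasticity, and receptor-level pharmacology are not represented; the
  indirect pathway's net inhibitory and the direct pathway's net excitatory
  effect on thalamus appear as single signed coefficients (`a3mi`, `a3md`).
- State variables are **not** clipped at zero during evaluation. The linear
  rate laws admit negative excursions under extreme perturbations; all
  reference equilibria are positive, so rectification would not change any
  validated number. An optional `rectify` flag exists (off by default) and
  negative excursions are logged as warnings.

## Parameters

The 23 constants (defaults bundled in
`src/raphebg/data/default_parameters.json`, stored at full published
precision) were calibrated upstream so the baseline equilibrium sits at
experimentally observed values: striatal DA 2.72 nM, striatal 5-HT 0.846 nM,
DRN 1.41 Hz, SNc 4.47 Hz, MSNs ≈ 1.9 Hz, thalamus 17.5 Hz. Decay constants
`d1…d8` (per second) set each variable's intrinsic relaxation; `G` scales
dopamine release per nM of striatal 5-HT per Hz of SNc firing; the `a·`
coefficients are synaptic-influence gains. The package deliberately does not re-derive the
calibration — parameters are data, replaceable by JSON/TOML file.

## Steady states

Setting every derivative to zero lets all variables be eliminated by forward
substitution: `5HT` and `SN` are affine in `DRN`; `DA = G·5HT·SN/d6` is then
quadratic in `DRN`; `MI`, `MD`, `TH`, `CX` are affine in `DA`. Substituting
into the DRN balance leaves one quadratic in `DRN`. The implementation
extracts the exact polynomial coefficients by evaluating the residual at
three `DRN` values (exact for a degree-2 polynomial — no symbolic algebra,
and every clamp configuration is handled by the same three evaluations).
With the 5-HT gain-term clamp the DA term is affine and the balance is
linear, with a unique root.

**Root selection.** Of up to two real roots, those with `DRN > 0` and
`SN ≥ 0` are physical. If both qualify, the locally stable one is returned;
if both are stable (not observed with the default calibration) the one
closest to the baseline DRN is returned with a warning. No physical root
raises an error reporting both roots.

**Cross-checks.** Three independent routes to the equilibrium are kept
separate throughout: the quadratic reduction, Powell-hybrid root finding on
the raw right-hand side (`scipy.optimize.root`, residual < 1e-10), and
residual-based long-time integration (`settle`, max |dy/dt| < 1e-9 by
default). Scenario runs verify the algebraic result against `settle` to
1e-6 relative. All tolerances sit far below the 3-digit precision of the
reference values.

**Stability** is assessed from the analytic Jacobian (only the DA row is
state-dependent: ∂DA′/∂5HT = G·SN, ∂DA′/∂SN = G·5HT). An equilibrium is
stable iff every eigenvalue has negative real part; with a globally clamped
variable the structurally zero mode is excluded.

### Weakly damped parameterizations

Some parameter sets place a Jacobian eigenpair very close to the imaginary
axis. The SSRI scenario (`d7` = 1) has modes at −0.0012 ± 0.454j — a damped
oscillation with an ~830 s envelope — so finite-horizon integration from a
distant start cannot certify its equilibrium: 500 s of integration from the
baseline state still leaves an O(0.1) residual. The solver-equivalence test
therefore settles from the baseline where that converges and otherwise
verifies local attraction from a 1% kick off the equilibrium on a horizon
long enough for the slow mode to decay. Near such modes the integrator's
accumulated-error floor sits above the usual 1e-10 stopping residual, so the
stopping criterion there is 1e-7 while the asserted state agreement stays at
1e-6 relative.

## Time-dependent simulation

`integrate` uses `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
rtol 1e-8 / atol 1e-10, sampling on a uniform grid (default 0.01 s for
plots, 0.1 s for bulk runs). Pulses modify parameters on **half-open**
intervals `[t_on, t_off)` — a 1-s pulse lasts exactly 1 s and adjacent
pulses compose unambiguously — and the integrator restarts at every pulse
boundary so the parameter step is never smoothed across. Halving the
tolerances changes the phasic-input trajectory by < 1e-6 in sup-norm (tested).

The phasic experiment (`FIG2`) starts at the baseline equilibrium (the
natural choice: pre-pulse traces are flat), doubles `a2c` on [1 s, 2 s), and
records 12 s — the visible transient plus the return to baseline. Its
summary statistics (peak MD, time of return to within 1% of baseline, depth
of the MD undershoot) are logged, not asserted: there are no reference
numbers for them, so tests assert only sign/ordering structure (overshoot
during the pulse, ~4 s return, later MD undershoot with simultaneous MI
overshoot, decay to baseline).

## Scenario catalogue

`A1` d8 = 17; `A2` d8 = 17 with the gain-term 5-HT clamp at 0.846 nM; `B`
G = 0.36; `C` a7 = 0.6; `D` d7 = 1; `E` d8 = 5; `F1`/`F2` a5 × 1.5 / × 0.5
(stored as factors so edits to `a5` propagate); `FIG2` a2c × 2 on [1, 2) s.
Percent changes are computed from full-precision equilibria and rounded only
for display. The gain-term clamp substitutes a fixed 5-HT value *only*
inside `G·5HT·SN` while the 5-HT equation evolves freely — the open-loop
control demonstrating that it is specifically the serotonergic action on DA
terminals that provides compensation. `A2` clamps at the printed normal
value 0.846 nM; clamping at the full-precision baseline (0.84562 nM) moves
every cell by < 0.001.

## Reference-table comparisons

Validation compares each equilibrium against reference steady-state tables
printed at 3–4 significant figures, with a default tolerance of half a unit
in the last printed digit. Exhaustive comparison shows the reference tables
themselves are not uniformly rounded, and the model's own algebra exposes
the discrepancies (`tests/reference.py` encodes all of this per cell):

- **Truncated or double-rounded cells** (nine): e.g. SN 2.27183 printed as
  2.271, SN 10.17670 printed as 10.176, DRN 2.77444 printed as 2.78.
  Tolerance: one unit in the last printed digit.
- **Internally inconsistent cells** (five): scenarios `B` and `C` must agree
  in everything except 5-HT, because only the product `G·a7` (identical in
  the two scenarios, 0.432) enters the other balances — yet the tables print
  different MD and DRN values for them. Likewise three cells contradict
  *other cells of their own column* under the model equations (column D's
  printed DA forces MI = 1.7535, not the printed 1.745; column E's printed
  5HT·SN product forces DA = 3.4949, not 3.496; column A2's printed MI/MD
  force TH = 9.78, not 9.772). These five cells are asserted against the
  value implied by their printed neighbor cells, which serves as an
  independent per-cell oracle.

## Serialization

Parameter files are flat JSON/TOML maps keyed by parameter name; unknown
keys are rejected with the list of valid names, missing keys fall back to
defaults with a logged notice. Results are CSV (numbers at `%.17g`, which
round-trips float64 bit-for-bit; verified by reload tests using pandas'
round-trip parser) plus a JSON sidecar carrying the full parameter set,
protocol/clamp, solver settings, package version and timestamp — replaying a
sidecar reproduces the trajectory exactly.

## Known limitations

- Validity is local to the calibrated operating point; large perturbations
  can drive rates negative, which the model reports but does not prevent.
- A single lumped "cortex" both receives thalamic drive and inhibits the
  DRN; regional heterogeneity of cortico-raphe projections is out of scope.
- The equilibrium structure (one physical root of a quadratic) is a property
  of this rate-law form; the package does not do bifurcation continuation,
  and multistable regimes outside the ±30% neighbourhood explored by the
  property tests are uncharacterized.
- The phasic experiment's quantitative features (peak height, undershoot
  depth) depend on the calibration and have no reference values; only their
  qualitative structure is validated.
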