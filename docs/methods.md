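# Methods

## Scope and model families

`navkit` models the macroscopic sodium current of NaV1.5 under two
phenomenological formalisms and measures both with the same virtual
voltage-clamp battery.

**Hodgkin–Huxley (HH).** Independent gates x ∈ {m, h, s} with
first-order kinetics `dx/dt = α(V)(1−x) − β(V)x` and conductance
`ḡ·m³h` (`ḡ·m³hs` once the slow-inactivation gate is added). Rate laws
follow the conventional functional forms (all voltages mV, rates ms⁻¹):

| form | expression |
|---|---|
| linoid | `A (V−V½) / (1 − e^(−(V−V½)/k))` |
| exponential | `A e^((V−V½)/k)` |
| sigmoid | `A / (1 + e^((V−V½)/k))` |

The linoid is implemented in the sign convention that makes it positive
and increasing for positive `k` (the printed literal form with the sign
inside the exponent inverted is algebraically identical up to the sign
of `k`; the convention used here reproduces the classic α_m shapes with
the tabulated positive `k`). At `V = V½` it takes its removable-
singularity limit `A·k`.

**Markov kinetic scheme.** Five states C1 ⇌ C2 ⇌ O1 → I1 ⇌ I2 with
I1 ⇌ C1 and a negligible I1→O1 backward rate (≤ 10⁻⁴ of the forward
rate at every voltage in [−150, +80] mV — effectively irreversible open-
state inactivation). Occupancies obey `dx/dt = Q(V)x` with the
conservative generator Q (columns sum to zero), and the current is
Ohmic in the open-state occupancy. Every transition rate is a double
sigmoid — a hyperpolarized branch with positive slope factor plus a
depolarized branch with negative slope factor, either possibly absent.
The O1→I1 rate carries a shallow depolarized branch (k = −100 mV)
realizing its non-zero minimum. An offset-sigmoid rate form (minimum +
maximum asymptotes) is supported for completeness but unused by the
bundled presets.

**Temperature.** Every rate is multiplied by `Q10 = 3^((T−T_base)/10)`.
The kinetic preset defines its rates at `T_base = 20 °C`; the HH presets
keep the original HH convention `T_base = 6.3 °C` (their ancestor rate
equations were measured at that temperature, and the published HH
kinetic features — repriming and slow-onset time constants — are
consistent with that base, not with 20 °C). This is a preset field, not
a code constant: steady-state features (activation and availability
midpoints and slopes) are mathematically independent of the base, since
a uniform rescaling of all rates is a pure rescaling of time.

## Exact propagation

Voltage-clamp commands are piecewise constant, so each epoch is a
constant-coefficient linear system with a closed-form solution:

* HH gates: `x(t) = x∞ + (x0 − x∞) e^(−t/τ)` with `x∞ = α/(α+β)`,
  `τ = 1/((α+β)·Q10)`;
* Markov occupancies: `x(t) = R e^(Λt) R⁻¹ x0` from the
  eigendecomposition `Q = R Λ R⁻¹`, evaluated directly at each sample
  (no step-to-step error accumulation). Decompositions are cached per
  (voltage, Q10). A dense `expm` fallback guards the (never observed)
  defective case, triggered at an eigenbasis condition number above 1e10.

Consequences relied on by the tests: occupancy conservation to 10⁻¹⁰
over arbitrary epoch concatenations, the semigroup property, agreement
with a stiff ODE integration of the raw kinetic equations to 10⁻⁶, and
exact Q10 time-rescaling (trajectories at Q10 = c sampled at t equal
trajectories at Q10 = 1 sampled at c·t).

Sampling: epochs up to 50 ms are recorded on the 0.025 ms grid; longer
epochs keep that fine grid over their first 50 ms (where every measured
peak lives) and continue with 400 uniform samples. Because propagation
is exact, sampling density affects only the recorded trace and peak
localization, never the solution: peak times are resolved to one dt.

## Protocols

Holding potential −120 mV; every sweep starts from the equilibrium state
at holding (HH gates at x∞, Markov at the normalized null vector of Q,
which is unique for the connected scheme). The clamp is ideal: commanded
V is imposed exactly, hence no capacitive transient (equivalent to
capacitive-current subtraction) and no leak.

* activation: 2 ms at −120, test 14 ms swept −90…+60 mV in 5 mV steps;
* deactivation: 0.5 ms at −120, 0.5 ms at −10, tail 5 ms swept
  −100…−30 mV in 10 mV steps;
* availability: conditioning 500 ms swept −120…0 mV in 5 mV steps,
  test 20 ms at −10 mV;
* fast repriming: P1 30 ms at −20 mV, recovery interval at −120 mV
  (override for −110/−100/−90 mV) swept 0.1–1000 ms, P2 20 ms at −20 mV;
* slow repriming: as above with P1 = 1000 ms and intervals to 7000 ms;
* slow-inactivation onset: P1 at −20 mV swept 10 ms–10 s, 30 ms at
  −120 mV, test 20 ms at −20 mV.

Swept interval/duration grids are logarithmic with 8 points per decade,
endpoints included — matching the logarithmic presentation of recovery
data and giving stable exponential fits. The fitted recovery time
constants are moderately sensitive to this choice (see Limitations).
The fast-repriming conditioning duration is 30 ms by default with a
100 ms override (both appear in the source descriptions of the
protocol). Peak measurement takes the extremum of largest magnitude
within an epoch, excluding the first sample after the step
(discontinuity guard); inward currents are negative, and double-pulse
ratios use peak magnitudes (P2/P1 per sweep, both peaks from the same
sweep).

## Fitting

All reductions are nonlinear least squares (`scipy.optimize.least_squares`,
trust-region-reflective, bounds keeping time constants positive) with a
fixed, deterministic multi-start grid: decade-spaced time-constant
starts spanning the abscissa range, amplitude starts from the data
extremes, midpoint starts bracketing the median voltage. The best
converged start by squared-residual norm (`ssr`, reported with every
fit) wins; non-convergence flags the result rather than raising. For the
double-exponential recovery the two time constants are reported in
ascending order with amplitudes permuted accordingly.

Feature conventions:

* Activation: peaks → conductance `G = I/(V − E_Na)` (sweeps within 1 mV
  of E_Na excluded — driving-force singularity), normalized by the
  empirical maximum, fitted to the two-parameter Boltzmann. `k` is
  negative for activation and positive for availability, as produced by
  the fitted equations.
* Activation transients: the full test epoch (step onset to epoch end)
  is fitted to `A(1−e^(−t/τm))³ e^(−t/τh)` with A, τm, τh free — the
  single-fit variant, which has the minimum fitting error, rather than
  manually splitting rise and decay. Sweeps with peaks below 1 % of the
  family maximum are skipped (no transient to fit).
* Availability: normalized test-pulse peaks fitted to the offset
  Boltzmann `A + (1−A)/(1 + e^((V−V½)/k))` with the non-inactivating
  fraction A bounded to [0, 1]. A flat curve (inactivation pathways
  removed) is flagged instead of fitted.
* Deactivation: mono-exponential per tail level, starting one sample
  after the step.
* Repriming and onset: P2/P1 vs interval/duration fitted to
  `A1(1−e^(−t/τ1))` (fast), `A1(1−e^(−t/τ1)) + A2(1−e^(−t/τ2))` (slow;
  fractional recoveries `A1/(A1+A2)`, `A2/(A1+A2)`), and
  `A1 + A2 e^(−t/τ)` (onset; A1 is the plateau).

## Benchmark and the α_h conflict

The benchmark regenerates the model-vs-experiment table at 24 °C,
E_Na = 65 mV, ḡ = 0.1 S/cm²: the kinetic preset answers every row; the
HH rows use the staged presets (final `row_h` for activation and the
slow protocols with m³hs; the three α_h variants for availability and
fast repriming with m³h, the s gate being introduced only for the slow
protocols). Agreement is |sim − mean| ≤ 2·SD, boundary inclusive; rows
published without an SD use a documented 25 % relative tolerance and are
marked `no-SD`.

`hh_alpha_h_conflict_scan` rebuilds the m³h model over a grid of α_h
triples spanning the availability-optimized (0.0005, −67, −7),
repriming-optimized (0.0035, −65, −25) and trade-off (0.004, −75, −16)
tunings and records both agreement flags per triple. The scan shows each
objective attainable alone and never jointly — the operational statement
of the formalism's one-parameter/two-behaviours limitation. The Markov
scheme needs no such compromise: availability is governed by C1→I1,
repriming by I1→C1, decay from activation by O1→I1, independently.

## Membrane demo

A single isopotential compartment (1 µF/cm², 10,000 µm², leak
0.0003 S/cm² with E_L = resting −100 mV, generic n⁴ delayed-rectifier
potassium conductance with squid-era rates, 0.036 S/cm², E_K = −77 mV)
demonstrates qualitatively that both NaV1.5 models sustain action
potentials. Integration is operator splitting with exponential updates
on both halves: channel states take one exact constant-voltage step per
dt, then V follows the exact solution of the linear membrane equation at
frozen conductances. Halving dt from 0.025 ms moves spike onsets by less
than 0.1 ms. The compartment's input resistance is far higher than a
motoneuron's, so its rheobase is well below the ~150 nA scale of
multicompartment models; spike counts and shapes here are a qualitative
suitability check only.

## Synthetic inputs and what the tests show

There are no external data: inputs are the bundled parameter presets
(the original squid rates, the staged NaV1.5 HH tunings a–h, the
ten-transition kinetic rate table) and the experimental reference means
± SDs. Synthetic traces used in tests (pure Boltzmann conductance
families, known-eigenvalue schemes, constant-rate pairs) exercise
identifiability of the fitting layer with zero-noise data; they do not
emulate recording noise, series-resistance or liquid-junction artifacts,
so passing tests validate the simulation/fitting pipeline, not
robustness to experimental non-idealities.

## Numerical choices and limitations

* dt defaults to 0.025 ms everywhere (recording grid and membrane
  integration step).
* Boltzmann slope tolerance aside, the fitted *kinetic* time constants
  (repriming, slow recovery) depend at the 10–20 % level on the interval
  grid and on fit weighting; the published simulation values for these
  quantities were produced by a different fitter and solver and differ
  from the exact-propagation values here by about that margin. They are
  therefore compared by the two-standard-deviation rule, not by exact
  matching. The slow-onset time constant, which is insensitive to the
  grid, matches to three figures.
* The activation conductance–voltage curve declines slightly above
  +5 mV (open-state occupancy drains into I1 faster at depolarized
  voltages); the two-parameter Boltzmann cannot represent that decline,
  which makes the fitted midpoint sensitive to the top-of-curve values
  at the few-tenths-of-a-mV level. The exact-propagation kinetic G–V
  midpoint is about 0.8 mV depolarized relative to a simulation of the
  same scheme with an implicit fixed-step solver at dt = 0.025 ms, whose
  fast depolarized-voltage peaks are slightly depressed.
* The availability fit bounds A ∈ [0, 1]; for channels without any
  non-inactivating fraction the fitted A sits at the boundary
  harmlessly.
* Degenerate inputs: disconnected Markov schemes are rejected at load
  time; α+β = 0 raises a degenerate-gate error; all-zero traces return
  flagged (0, 0) peaks; |V| blow-up beyond 500 mV aborts the membrane
  integration with an explicit error.
* Not modelled: stochastic single-channel gating, gating currents,
  amplifier artifacts, multicompartment morphology, and the four-state
  scheme variant (the scheme container supports arbitrary state counts,
  but no such preset is shipped).
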