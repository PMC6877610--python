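# navkit

Side-by-side phenomenological modelling of the cardiac voltage-gated
sodium channel **NaV1.5**: a tuned Hodgkin–Huxley (HH) gate model and a
five-state Markov kinetic scheme, the standard voltage-clamp protocol
battery, and nonlinear least-squares extraction of the published
electrophysiological features.

`navkit` is written for computational neuro/cardiac electrophysiologists
who build conductance-based cell models and need channel models that are
validated against whole-cell patch-clamp data — and who want to see
precisely where the venerable HH formalism stops being enough.

## The models

**Hodgkin–Huxley.** Gating particles `m` (activation), `h` (fast
inactivation) and optionally `s` (slow inactivation) relax independently
by first-order kinetics,

    dx/dt = αₓ(V) (1 − x) − βₓ(V) x,        g_Na = ḡ · m³ h (· s)

with voltage-dependent rates in linoid / exponential / sigmoid form
(parameters A, V½, k per rate).

**Markov kinetic scheme.** Five coupled states — two closed (C1, C2),
one open (O1), a fast-inactivated (I1) and a deep slow-inactivated (I2):

    C1 ⇌ C2 ⇌ O1 → I1 ⇌ I2,   I1 ⇌ C1   (and a tiny I1→O1 backward rate)

    d**x**/dt = Q(V) **x**,   Σ states = 1,   I_Na = ḡ · O1 · (V − E_Na)

Every transition rate is a double sigmoid
`B_hyp/(1+e^((V−V_hyp)/k_hyp)) + B_dep/(1+e^((V−V_dep)/k_dep))`.
All rates scale with temperature as `Q10 = 3^((T−T_base)/10)`.

Because voltage-clamp commands are piecewise constant, both families are
propagated **exactly** per epoch (mono-exponential gate relaxation;
matrix exponential via eigendecomposition of the conservative generator
Q). There is no ODE-solver truncation error anywhere in the pipeline.

Six protocols are bundled (activation, deactivation, steady-state
availability, fast/slow repriming, slow-inactivation onset) together
with the standard fitted reductions: Boltzmann conductance–voltage and
availability curves, m³h transients, tail-current and recovery
exponentials. A benchmark module regenerates the published
model-vs-experiment comparison, flagging each feature by the
two-standard-deviation agreement rule, and a minimal single-compartment
current-clamp membrane shows that both channel models support spiking.

## Worked example

```python
from navkit import (load_channel, make_protocol, run_protocol,
                    availability_features, repriming_features)

nav = load_channel("nav15_markov")          # Table-4 rates, 24 °C, E_Na = 65 mV

avail = availability_features(
    run_protocol(nav, make_protocol("availability")))
print(avail.features)

rec = repriming_features(
    run_protocol(nav, make_protocol("fast_repriming")), kind="fast")
print(rec.features)
```

prints

```
{'availability_v_half': -89.553, 'availability_k': 5.434, 'availability_offset': 0.001}
{'recovery_tau': 4.1451, 'recovery_plateau': 0.9945}
```

i.e. half the channels are unavailable after conditioning at −89.6 mV
with a 5.4 mV slope (experimental reference: −89.1 ± 1.6 mV, 5.5 ± 0.4),
essentially no non-inactivating fraction, and availability recovers at
−120 mV with a ~4 ms time constant to a ~99 % plateau (reference
5.1 ± 0.9 ms).

The same is available from the shell:

```sh
navkit simulate --channel nav15_markov --protocol activation --out traces.csv
navkit fit      --channel nav15_markov --protocol slow_onset
navkit benchmark --out table_report.csv
navkit spike-demo --channel nav15_markov --amp-na 160
```

`navkit benchmark` prints every feature for the kinetic scheme and the
staged HH tunings next to the experimental mean ± SD with agreement
flags. The HH rows demonstrate the structural conflict of that
formalism: a single rate function (α_h) must encode both steady-state
availability and repriming, so the availability-optimized tuning
(`nav15_hh_variant_b`) fails the recovery row, the repriming-optimized
one (`nav15_hh_variant_a`) fails the availability slope, and
`navkit.hh_alpha_h_conflict_scan()` shows that no α_h setting in between
rescues both.

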