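# Five-state Markov kinetic scheme for NaV1.5 (C1, C2 closed; O1 open;
# I1 fast-inactivated; I2 slow/deep-inactivated).  Every transition rate is a
# double sigmoid (one or both branches); units mV, ms^-1.  Rates are defined
# at 20 C and scaled by Q10 = 3^((T-20)/10).
name: nav15_markov
family: markov
gbar: 0.1        # S/cm2
E_rev: 65.0      # mV, sodium reversal potential
temperature: {T: 24.0, T_base: 20.0, q10_base: 3.0}
states: [C1, C2, O1, I1, I2]
open_state: O1
transitions:
  - from: C1
    to: C2
    rate: {form: double_sigmoid, params: {B_dep: 8.0, V_dep: -16.0, k_dep: -9.0}}
  - from: C2
    to: C1
    rate: {form: double_sigmoid, params: {B_hyp: 2.0, V_hyp: -82.0, k_hyp: 5.0,
                                          B_dep: 8.0, V_dep: -16.0, k_dep: -9.0}}
  - from: C2
    to: O1
    rate: {form: double_sigmoid, params: {B_dep: 8.0, V_dep: -26.0, k_dep: -9.0}}
  - from: O1
    to: C2
    rate: {form: double_sigmoid, params: {B_hyp: 3.0, V_hyp: -92.0, k_hyp: 5.0,
                                          B_dep: 8.0, V_dep: -26.0, k_dep: -9.0}}
  # the shallow depolarized branch realizes the non-zero minimum asymptote
  # of the open->inactivated rate
  - from: O1
    to: I1
    rate: {form: double_sigmoid, params: {B_hyp: 8.0, V_hyp: -50.0, k_hyp: 4.0,
                                          B_dep: 6.0, V_dep: 10.0, k_dep: -100.0}}
  # effectively irreversible: backward rate 5 orders of magnitude smaller
  - from: I1
    to: O1
    rate: {form: double_sigmoid, params: {B_hyp: 0.00001, V_hyp: -20.0, k_hyp: 10.0}}
  - from: I1
    to: C1
    rate: {form: double_sigmoid, params: {B_hyp: 0.35, V_hyp: -122.0, k_hyp: 9.0}}
  - from: C1
    to: I1
    rate: {form: double_sigmoid, params: {B_dep: 0.04, V_dep: -78.0, k_dep: -10.0}}
  - from: I1
    to: I2
    rate: {form: double_sigmoid, params: {B_dep: 0.00018, V_dep: -60.0, k_dep: -5.0}}
  - from: I2
    to: I1
    rate: {form: double_sigmoid, params: {B_hyp: 0.001825, V_hyp: -88.0, k_hyp: 31.0}}
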