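# Stage b: rate amplitudes reduced (and alpha_h/beta_h slopes adjusted) to
# slow activation/inactivation kinetics toward NaV1.5 at room temperature.
name: nav15_hh_row_b
family: hh
gbar: 0.1
E_rev: 65.0
temperature:
  T: 24.0
  T_base: 6.3
  q10_base: 3.0
gates:
- name: m
  exponent: 3
  alpha:
    form: linoid
    params:
      A: 0.03
      V_half: -40
      k: 10
  beta:
    form: exponential
    params:
      A: 0.3
      V_half: -65
      k: -18
- name: h
  exponent: 1
  alpha:
    form: exponential
    params:
      A: 0.002
      V_half: -65
      k: -10
  beta:
    form: sigmoid
    params:
      A: 0.5
      V_half: -25
      k: -15
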